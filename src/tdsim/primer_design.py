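"""TE-specific forward primer design from LTR 3'-end windows.

Candidates are every k-mer of the window at the 3' end of an element's
3' LTR, oriented outward (the primer's 3' end points across the LTR
boundary into flanking DNA).  Filtering applies GC and melting-
temperature bounds to the core primer; the universal 5' tail — the
landing site of the fluorescent primer used in the labeled PCR — is
added afterwards and only its Tm is reported.  Final selection keeps
candidates whose in-silico amplicon count falls inside the configured
acceptance band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio.SeqUtils import MeltingTemp as _mt

from .restriction import revcomp
from .seqio import Genome, TEAnnotation

#: universal 20-nt tail recognized by the fluorescently labeled primer
DEFAULT_TAIL = "TGTATACTGGAGCTGAGCTT"


@dataclass(frozen=True)
class DesignParameters:
    """Tunable knobs of the primer-design stage.

    Defaults encode the published protocol: 20-mers from the terminal
    100 bp of the 3' LTR, 40-60% GC, core Tm 55-60 C, and an acceptance
    band of 19-60 predicted amplicons below 5 kb.
    """

    window_bp: int = 100
    primer_len: int = 20
    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 55.0
    tm_max: float = 60.0
    tail: str = DEFAULT_TAIL
    amp_count_min: int = 19
    amp_count_max: int = 60
    amp_size_max: int = 5000
    tm_method: str = "nearest_neighbor"
    max_mismatches: int = 0
    anchor_len: int = 3
    salt_mM: float = 50.0
    primer_nM: float = 250.0
    strict: bool = True

    def __post_init__(self) -> None:
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        if not self.tm_min < self.tm_max:
            raise ValueError("tm_min must be < tm_max")
        if not self.amp_count_min < self.amp_count_max:
            raise ValueError("amp_count_min must be < amp_count_max")
        if set(self.tail) - set("ACGT"):
            raise ValueError("tail must contain only ACGT")


@dataclass
class PrimerCandidate:
    """A candidate forward primer and its evaluation statistics."""

    name: str
    core_seq: str
    source_element: str = ""
    offset_in_ltr: int = 0
    orientation: str = "outward"
    tailed_seq: str | None = None
    gc_percent: float | None = None
    tm_core: float | None = None
    tm_tailed: float | None = None
    n_amplicons_fw: int | None = None
    n_amplicons_rv: int | None = None
    amp_size_min: int | None = None
    amp_size_max: int | None = None

    @property
    def total_amplicons(self) -> int | None:
        if self.n_amplicons_fw is None or self.n_amplicons_rv is None:
            return None
        return self.n_amplicons_fw + self.n_amplicons_rv


@dataclass
class LTRWindow:
    """A design window with the frame metadata to map hits back to the genome."""

    sequence: str
    element_id: str
    contig: str
    genomic_span: tuple[int, int]
    strand: str


def extract_ltr_window(
    te: TEAnnotation, genome: Genome, params: DesignParameters = DesignParameters()
) -> LTRWindow:
    """Window of ``window_bp`` ending at the 3' end of the element's 3' LTR.

    Returned in the element's reading orientation (reverse-complemented
    for strand ``-``); truncated with a warning when the LTR is shorter
    than the window.
    """
    if te.ltr3 is None:
        raise ValueError(f"{te.element_id}: no 3' LTR sub-feature")
    seq = genome.contigs[te.contig]
    s, e = te.ltr3
    w = params.window_bp
    if e - s < w:
        warnings.warn(
            f"{te.element_id}: 3' LTR length {e - s} < window {w}; truncated",
            stacklevel=2,
        )
        w = e - s
    if te.strand == "+":
        span = (e - w, e)
        window = seq[span[0]: span[1]]
    else:
        # leftmost interval is the 3' LTR; its 3' end (in element reading
        # direction) is the left genomic boundary
        span = (s, s + w)
        window = revcomp(seq[span[0]: span[1]])
    return LTRWindow(window, te.element_id, te.contig, span, te.strand)


def enumerate_candidates(
    window: LTRWindow | str, params: DesignParameters = DesignParameters()
) -> list[PrimerCandidate]:
    """All ``primer_len``-mers of the window, outward-oriented.

    ``offset_in_ltr`` is the distance from the primer 3' end to the LTR
    3' end (0 = primer flush with the element boundary).  k-mers
    overlapping N are skipped.
    """
    seq = window.sequence if isinstance(window, LTRWindow) else window
    eid = window.element_id if isinstance(window, LTRWindow) else "window"
    k = params.primer_len
    if len(seq) < k:
        raise ValueError(f"window length {len(seq)} < primer length {k}")
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        offset = len(seq) - (i + k)
        out.append(
            PrimerCandidate(
                name=f"{eid}:-{offset}",
                core_seq=kmer,
                source_element=eid,
                offset_in_ltr=offset,
            )
        )
    return out


def gc_content(seq: str) -> float:
    """GC percentage of an ACGT sequence."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be ACGT only")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str,
    method: str = "nearest_neighbor",
    salt_mM: float = 50.0,
    primer_nM: float = 250.0,
) -> float:
    """Duplex melting temperature in Celsius.

    ``wallace`` is the 2(A+T)+4(G+C) rule-of-thumb (exact, deterministic;
    used as a test oracle); ``nearest_neighbor`` is the SantaLucia
    thermodynamic model at the given monovalent-salt and primer
    concentrations.
    """
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence must be ACGT only")
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        return float(2 * at + 4 * (len(seq) - at))
    if method == "nearest_neighbor":
        return float(_mt.Tm_NN(seq, Na=salt_mM, dnac1=primer_nM, dnac2=0))
    raise ValueError(f"unknown Tm method {method!r}")


def score_candidates(
    candidates: list[PrimerCandidate], params: DesignParameters = DesignParameters()
) -> list[PrimerCandidate]:
    """Fill gc_percent and tm_core for every candidate (in place, returned)."""
    for c in candidates:
        c.gc_percent = gc_content(c.core_seq)
        c.tm_core = melting_temperature(
            c.core_seq, params.tm_method, params.salt_mM, params.primer_nM
        )
    return candidates


def filter_candidates(
    candidates: list[PrimerCandidate], params: DesignParameters = DesignParameters()
) -> list[PrimerCandidate]:
    """Keep candidates inside the GC and core-Tm bounds (inclusive).

    With ``strict=False`` out-of-band candidates are kept and warned
    about instead — useful for reproducing published primers that sit
    outside their own stated bounds.
    """
    kept = []
    for c in candidates:
        ok = (
            params.gc_min <= c.gc_percent <= params.gc_max
            and params.tm_min <= c.tm_core <= params.tm_max
        )
        if ok:
            kept.append(c)
        elif not params.strict:
            warnings.warn(
                f"{c.name}: GC {c.gc_percent:.1f}% / Tm {c.tm_core:.1f}C outside "
                "bounds, kept (strict=False)",
                stacklevel=2,
            )
            kept.append(c)
    return kept


def add_tail(
    candidate: PrimerCandidate, params: DesignParameters = DesignParameters()
) -> PrimerCandidate:
    """Prepend the universal tail and record the tailed Tm."""
    tailed = params.tail + candidate.core_seq
    return replace(
        candidate,
        tailed_seq=tailed,
        tm_tailed=melting_temperature(
            tailed, params.tm_method, params.salt_mM, params.primer_nM
        ),
    )


def check_tail_absent(genome: Genome, tail: str = DEFAULT_TAIL) -> bool:
    """True iff neither the tail nor its reverse complement occurs anywhere."""
    rc = revcomp(tail)
    return not any(tail in s or rc in s for s in genome.contigs.values())


def select_primers(
    candidates: list[PrimerCandidate], params: DesignParameters = DesignParameters()
) -> list[PrimerCandidate]:
    """Keep evaluated candidates whose joint fw+rv amplicon count is in band.

    All predicted amplicons must respect the size cap.  Survivors are
    ranked by distance of the count from the band midpoint, then by core
    Tm distance from the Tm-band midpoint, then lexicographically.
    """
    count_mid = (params.amp_count_min + params.amp_count_max) / 2
    tm_mid = (params.tm_min + params.tm_max) / 2
    kept = []
    for c in candidates:
        total = c.total_amplicons
        if total is None:
            raise ValueError(f"{c.name}: not evaluated (no amplicon counts)")
        if not params.amp_count_min <= total <= params.amp_count_max:
            continue
        if c.amp_size_max is not None and c.amp_size_max > params.amp_size_max:
            continue
        kept.append(c)
    return sorted(
        kept,
        key=lambda c: (
            abs(c.total_amplicons - count_mid),
            abs((c.tm_core if c.tm_core is not None else tm_mid) - tm_mid),
            c.core_seq,
        ),
    )
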