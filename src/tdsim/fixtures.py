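"""Deterministic synthetic genomes with planted LTR retrotransposons.

The generator stands in for a multi-population study design: a shared
random background genome, one LTR element family (5'LTR-internal-3'LTR,
identical LTRs as in a fresh insertion), copies planted at chosen loci,
and a per-sample presence/absence table describing which insertions
segregate.  Restriction sites are planted at known distances so every
expected amplicon length is available in closed form, and backgrounds
can be generated site-free so the expected band set is exactly the
planted one.

Ground truth (expected products, expected polymorphic bands) is computed
by direct arithmetic on the construction parameters, independently of
the digestion/PCR pipeline, which makes it usable as an end-to-end
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .restriction import ECORI, ECORI_ADAPTOR, revcomp
from .seqio import Genome, TEAnnotation

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 100.0
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


def _strip_sites(seq: str, motif: str = "GAATTC") -> str:
    """Remove every motif occurrence by point substitution; rescans until clean."""
    s = list(seq)
    while True:
        text = "".join(s)
        i = text.find(motif)
        if i == -1:
            return text
        # break the site without being able to recreate it in place
        s[i + 2] = "C" if s[i + 2] != "C" else "G"


def make_genome(
    length: int,
    gc: float = 50.0,
    seed: int = 0,
    site_free: bool = False,
    contig_name: str = "chr1",
    sample_label: str = "synthetic",
    enzyme=ECORI,
) -> Genome:
    """Reproducible random background genome.

    ``site_free=True`` strips chance occurrences of the enzyme's
    recognition motif so that planted sites are the only cut sites.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 100:
        raise ValueError("gc must be in (0, 100)")
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, length, gc)
    if site_free:
        seq = _strip_sites(seq, enzyme.recognition)
        seq = _strip_sites(seq, revcomp(enzyme.recognition))
    return Genome(sample_label, {contig_name: seq})


@dataclass(frozen=True)
class ElementSpec:
    """One LTR retrotransposon family: identical terminal repeats flanking
    an internal region that carries a single recognition site at a fixed
    offset (every full-length copy then yields one constant-length
    internal amplicon, and each insertion one locus-specific one)."""

    ltr: str
    internal: str
    internal_site_offset: int | None = None

    @property
    def sequence(self) -> str:
        return self.ltr + self.internal + self.ltr

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def core_primer(self) -> str:
        """The outward primer flush with the LTR 3' end (offset 0)."""
        return self.ltr[-20:]


def make_element(
    seed: int = 0,
    ltr_len: int = 300,
    internal_len: int = 2000,
    internal_site_offset: int | None = 400,
    gc: float = 50.0,
    enzyme=ECORI,
) -> ElementSpec:
    """Random element with site-free LTRs/internal plus one planted
    internal recognition site."""
    rng = np.random.default_rng(seed)
    ltr = _strip_sites(_random_seq(rng, ltr_len, gc), enzyme.recognition)
    internal = _strip_sites(_random_seq(rng, internal_len, gc), enzyme.recognition)
    if internal_site_offset is not None:
        m = enzyme.recognition
        if internal_site_offset + len(m) > internal_len:
            raise ValueError("internal_site_offset outside internal region")
        internal = (
            internal[:internal_site_offset]
            + m
            + internal[internal_site_offset + len(m):]
        )
    return ElementSpec(ltr, internal, internal_site_offset)


def plant_element(
    genome: Genome,
    element: ElementSpec,
    position: int,
    with_site_at: int | None = None,
    element_id: str = "te1",
    family: str = "synthFam",
    contig: str | None = None,
    annotations: list[TEAnnotation] | None = None,
    enzyme=ECORI,
) -> tuple[Genome, TEAnnotation, list[TEAnnotation]]:
    """Insert one element copy; optionally plant a recognition site
    ``with_site_at`` bases downstream of its 3' end (overwriting flank
    bases, so coordinates beyond the insertion shift only by the element
    length).  Prior annotations are shifted accordingly.
    """
    contig = contig or next(iter(genome.contigs))
    seq = genome.contigs[contig]
    if not 0 <= position <= len(seq):
        raise ValueError("plant position outside contig")
    annotations = list(annotations or [])
    for a in annotations:
        if a.contig == contig and a.span[0] <= position < a.span[1]:
            raise ValueError(
                f"plant position {position} overlaps element {a.element_id}"
            )
    elem = element.sequence
    L = len(elem)
    new_seq = seq[:position] + elem + seq[position:]
    if with_site_at is not None:
        m = enzyme.recognition
        s = position + L + with_site_at
        if s + len(m) > len(new_seq):
            raise ValueError("planted site outside contig")
        new_seq = new_seq[:s] + m + new_seq[s + len(m):]
    shifted = [
        a
        if a.contig != contig or a.span[0] < position
        else TEAnnotation(
            a.element_id,
            a.family,
            a.contig,
            (a.span[0] + L, a.span[1] + L),
            a.strand,
            (a.ltr5[0] + L, a.ltr5[1] + L) if a.ltr5 else None,
            (a.ltr3[0] + L, a.ltr3[1] + L) if a.ltr3 else None,
        )
        for a in annotations
    ]
    lt = len(element.ltr)
    te = TEAnnotation(
        element_id,
        family,
        contig,
        (position, position + L),
        "+",
        (position, position + lt),
        (position + L - lt, position + L),
    )
    contigs = dict(genome.contigs)
    contigs[contig] = new_seq
    return Genome(genome.sample_label, contigs), te, shifted + [te]


@dataclass
class SyntheticTruth:
    """Closed-form ground truth for a synthetic population.

    ``expected_products[sample]`` are labeled-PCR product lengths under
    the default junction arithmetic (tail + overhang-inclusive genomic
    span + adaptor extension); ``expected_polymorphic`` are the product
    sizes whose presence differs between samples.
    """

    samples: list[str]
    locus_positions: list[int]
    site_offsets: list[int]
    presence: np.ndarray  # loci x samples
    element: ElementSpec
    primer_core: str
    expected_spans: dict[str, list[int]] = field(default_factory=dict)
    expected_products: dict[str, list[int]] = field(default_factory=dict)
    expected_polymorphic: list[int] = field(default_factory=list)
    n_polymorphic: int = 0

    def to_dict(self) -> dict:
        return {
            "samples": self.samples,
            "locus_positions": self.locus_positions,
            "site_offsets": self.site_offsets,
            "presence": self.presence.astype(int).tolist(),
            "primer_core": self.primer_core,
            "expected_spans": self.expected_spans,
            "expected_products": self.expected_products,
            "expected_polymorphic": self.expected_polymorphic,
            "n_polymorphic": self.n_polymorphic,
        }


def expected_amplicon_span(site_offset: int, primer_offset_in_ltr: int = 0) -> int:
    """Genomic span of the outward product: primer 5' end through the
    bottom-strand cut of the planted site (the strand a + primer copies).

    The primer 5' end sits ``20 + primer_offset_in_ltr`` inside the LTR
    3' end; the template is severed ``site_offset + cut_bottom`` beyond
    the element end.
    """
    return site_offset + ECORI.cut_bottom + 20 + primer_offset_in_ltr


def expected_product_length(span: int, tail_len: int = 20) -> int:
    """Labeled product length: the span already includes the regenerated
    overhang, so only the tail and the adaptor extension are added."""
    return tail_len + span + ECORI_ADAPTOR.extension_beyond_overhang


def make_population(
    n_samples: int | None = None,
    presence: np.ndarray | list | None = None,
    locus_positions: list[int] | None = None,
    site_offsets: list[int] | None = None,
    base_length: int = 200_000,
    gc: float = 50.0,
    seed: int = 0,
    element: ElementSpec | None = None,
    sample_labels: list[str] | None = None,
) -> tuple[list[Genome], SyntheticTruth]:
    """Build one genome per sample from a shared background.

    ``presence`` has one row per locus and one column per sample; sample
    genomes differ only by which insertions they carry.  Ground truth —
    expected product lengths per sample and the expected polymorphic
    bands — is derived arithmetically from the construction.
    """
    presence = np.asarray(presence, dtype=int)
    if presence.ndim != 2:
        raise ValueError("presence must be a loci x samples matrix")
    n_loci, n_cols = presence.shape
    if n_samples is not None and n_samples != n_cols:
        raise ValueError("presence column count != n_samples")
    labels = sample_labels or [f"S{j + 1}" for j in range(n_cols)]
    if len(labels) != n_cols:
        raise ValueError("sample_labels length != number of samples")
    if element is None:
        element = make_element(seed=seed + 1)
    if locus_positions is None:
        step = base_length // (n_loci + 1)
        locus_positions = [step * (i + 1) for i in range(n_loci)]
    if site_offsets is None:
        site_offsets = [300 + 150 * i for i in range(n_loci)]
    if not (len(locus_positions) == len(site_offsets) == n_loci):
        raise ValueError("locus_positions/site_offsets length != number of loci")

    base = make_genome(base_length, gc=gc, seed=seed, site_free=True)
    base_seq = next(iter(base.contigs.values()))

    genomes: list[Genome] = []
    for j, label in enumerate(labels):
        g = Genome(label, {"chr1": base_seq})
        anns: list[TEAnnotation] = []
        # plant right-to-left so earlier positions stay valid
        for i in sorted(range(n_loci), key=lambda i: -locus_positions[i]):
            if presence[i, j]:
                g, _, anns = plant_element(
                    g,
                    element,
                    locus_positions[i],
                    with_site_at=site_offsets[i],
                    element_id=f"locus{i + 1}",
                    annotations=anns,
                )
        genomes.append(g)

    truth = SyntheticTruth(
        samples=labels,
        locus_positions=list(locus_positions),
        site_offsets=list(site_offsets),
        presence=presence,
        element=element,
        primer_core=element.core_primer,
    )
    internal_prod = None
    if element.internal_site_offset is not None:
        internal_span = element.internal_site_offset + ECORI.cut_bottom + 20
        internal_prod = expected_product_length(internal_span)
    for j, label in enumerate(labels):
        spans = [
            expected_amplicon_span(site_offsets[i])
            for i in range(n_loci)
            if presence[i, j]
        ]
        prods = [expected_product_length(s) for s in spans]
        if internal_prod is not None and presence[:, j].any():
            prods.append(internal_prod)
        truth.expected_spans[label] = sorted(spans)
        truth.expected_products[label] = sorted(prods)
    all_products = sorted({p for ps in truth.expected_products.values() for p in ps})
    poly = [
        p
        for p in all_products
        if 0
        < sum(p in truth.expected_products[s] for s in labels)
        < len(labels)
    ]
    truth.expected_polymorphic = poly
    truth.n_polymorphic = len(poly)
    return genomes, truth
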