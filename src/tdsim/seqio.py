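"""Input/output for genomes, TE annotations, primer tables and fingerprints.

Internal coordinates are 0-based half-open everywhere. GFF3 (1-based
inclusive) and BED (0-based half-open) are converted on the way in;
human-facing reports are 1-based inclusive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO

# IUPAC nucleotide codes. Ambiguity codes other than N are collapsed to N
# (no primer or restriction match across them); anything else is rejected.
_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
_VALID = set("ACGTN") | _IUPAC_AMBIGUOUS

PRIMER_TABLE_COLUMNS = [
    "name",
    "type",
    "sequence",
    "length_bp",
    "tm_C",
    "n_amplicons_fw",
    "n_amplicons_rv",
    "amp_size_min",
    "amp_size_max",
]


class InputError(ValueError):
    """Malformed or inconsistent external input."""


@dataclass
class Genome:
    """A sample's assembly: ordered contigs of uppercase A/C/G/T/N."""

    sample_label: str
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise InputError(f"contig {name!r} is empty")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise InputError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class TEAnnotation:
    """One annotated LTR retrotransposon copy with its paired LTRs.

    ``span``, ``ltr5`` and ``ltr3`` are 0-based half-open intervals on
    ``contig``.  On strand ``-`` the 3' LTR is the leftmost interval.
    """

    element_id: str
    family: str
    contig: str
    span: tuple[int, int]
    strand: str
    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"{self.element_id}: strand must be + or -")
        s, e = self.span
        if not 0 <= s < e:
            raise InputError(f"{self.element_id}: invalid span {self.span}")
        for name, iv in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
            if iv is None:
                continue
            if not (s <= iv[0] < iv[1] <= e):
                raise InputError(
                    f"{self.element_id}: {name} {iv} outside element span {self.span}"
                )
        if self.ltr5 and self.ltr3:
            a, b = sorted([self.ltr5, self.ltr3])
            if a[1] > b[0]:
                raise InputError(f"{self.element_id}: LTR sub-features overlap")
            # strand bookkeeping: for + the 5' LTR is leftmost, for - rightmost
            left_is_5 = self.ltr5 < self.ltr3
            if self.strand == "+" and not left_is_5:
                raise InputError(f"{self.element_id}: 5' LTR must be leftmost on +")
            if self.strand == "-" and left_is_5:
                raise InputError(f"{self.element_id}: 3' LTR must be leftmost on -")


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and collapse IUPAC ambiguity codes (except N) to N."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise InputError(f"{context}: non-IUPAC characters {sorted(bad)}")
    amb = set(seq) & _IUPAC_AMBIGUOUS
    if amb:
        warnings.warn(
            f"{context}: IUPAC ambiguity codes {sorted(amb)} converted to N",
            stacklevel=2,
        )
        seq = "".join("N" if c in _IUPAC_AMBIGUOUS else c for c in seq)
    return seq


def read_fasta(path: str | Path, sample_label: str | None = None) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    One contig per record, in file order; sequences normalized to
    uppercase ACGTN. ``sample_label`` defaults to the file stem.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise InputError(f"duplicate contig name {rec.id!r} in {path}")
        contigs[rec.id] = normalize_sequence(str(rec.seq), context=f"contig {rec.id}")
    if not contigs:
        raise InputError(f"no FASTA records in {path}")
    return Genome(sample_label or path.stem, contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_LTR_TYPES = {"long_terminal_repeat", "LTR", "ltr"}


def read_te_annotations(
    path: str | Path,
    format: str = "gff3",
    allow_single_ltr: bool = False,
    genome: Genome | None = None,
) -> list[TEAnnotation]:
    """Read TE annotations with LTR sub-features from GFF3 or BED.

    GFF3 parents are any feature with ``long_terminal_repeat`` children
    (linked by ``Parent``). BED uses a name-suffix convention: rows named
    ``<id>`` give the element span and ``<id>/ltr5`` / ``<id>/ltr3`` its
    LTRs (plain BED has no feature hierarchy).
    """
    if format == "gff3":
        tes = _read_gff3(Path(path), allow_single_ltr)
    elif format == "bed":
        tes = _read_bed(Path(path), allow_single_ltr)
    else:
        raise InputError(f"unknown annotation format {format!r}")
    if genome is not None:
        for te in tes:
            if te.contig not in genome.contigs:
                raise InputError(f"{te.element_id}: contig {te.contig!r} not in genome")
            if te.span[1] > len(genome.contigs[te.contig]):
                raise InputError(f"{te.element_id}: span exceeds contig bounds")
    return tes


def _require_paired(
    element_id: str, ltr5, ltr3, allow_single: bool
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    n = sum(x is not None for x in (ltr5, ltr3))
    if n < 2 and not allow_single:
        raise InputError(f"element {element_id!r} lacks paired LTRs")
    return ltr5, ltr3


def _read_gff3(path: Path, allow_single_ltr: bool) -> list[TEAnnotation]:
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    out: list[TEAnnotation] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        kids = list(db.children(feat))
        if feat.featuretype in _LTR_TYPES or not any(
            k.featuretype in _LTR_TYPES for k in kids
        ):
            continue
        # GFF3 is 1-based inclusive -> 0-based half-open
        span = (feat.start - 1, feat.end)
        strand = feat.strand if feat.strand in "+-" else "+"
        ltrs = sorted(
            ((k.start - 1, k.end) for k in kids if k.featuretype in _LTR_TYPES)
        )
        for iv in ltrs:
            if not (span[0] <= iv[0] < iv[1] <= span[1]):
                raise InputError(f"element {feat.id!r}: LTR {iv} outside parent span")
        if len(ltrs) == 1:
            ltr5, ltr3 = (ltrs[0], None) if strand == "+" else (None, ltrs[0])
        elif len(ltrs) >= 2:
            left, right = ltrs[0], ltrs[-1]
            ltr5, ltr3 = (left, right) if strand == "+" else (right, left)
        else:
            ltr5 = ltr3 = None
        ltr5, ltr3 = _require_paired(feat.id, ltr5, ltr3, allow_single_ltr)
        fam = feat.attributes.get("family", [feat.id])[0]
        out.append(TEAnnotation(feat.id, fam, feat.seqid, span, strand, ltr5, ltr3))
    return out


def _read_bed(path: Path, allow_single_ltr: bool) -> list[TEAnnotation]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"contig": str, "name": str, "strand": str},
    )
    parents: dict[str, dict] = {}
    ltrs: dict[str, dict[str, tuple[int, int]]] = {}
    for row in df.itertuples():
        iv = (int(row.start), int(row.end))
        if "/" in row.name:
            eid, kind = row.name.rsplit("/", 1)
            if kind not in ("ltr5", "ltr3"):
                raise InputError(f"BED sub-feature {row.name!r}: expected /ltr5 or /ltr3")
            ltrs.setdefault(eid, {})[kind] = iv
        else:
            parents[row.name] = dict(contig=row.contig, span=iv, strand=row.strand)
    missing = set(ltrs) - set(parents)
    if missing:
        raise InputError(f"LTR sub-features without parent element: {sorted(missing)}")
    out = []
    for eid, p in parents.items():
        sub = ltrs.get(eid, {})
        ltr5, ltr3 = _require_paired(
            eid, sub.get("ltr5"), sub.get("ltr3"), allow_single_ltr
        )
        out.append(
            TEAnnotation(eid, eid, p["contig"], p["span"], p["strand"], ltr5, ltr3)
        )
    return out


def write_te_annotations_gff3(tes: Iterable[TEAnnotation], path: str | Path) -> None:
    """Write annotations as GFF3 (1-based inclusive printed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for te in tes:
            s, e = te.span
            fh.write(
                f"{te.contig}\ttdsim\tLTR_retrotransposon\t{s + 1}\t{e}\t.\t"
                f"{te.strand}\t.\tID={te.element_id};family={te.family}\n"
            )
            for kind, iv in (("ltr5", te.ltr5), ("ltr3", te.ltr3)):
                if iv is None:
                    continue
                fh.write(
                    f"{te.contig}\ttdsim\tlong_terminal_repeat\t{iv[0] + 1}\t{iv[1]}"
                    f"\t.\t{te.strand}\t.\tID={te.element_id}.{kind};"
                    f"Parent={te.element_id}\n"
                )


def write_primer_table(candidates, path: str | Path) -> None:
    """Write evaluated primer candidates as a TSV.

    Columns mirror the standard design report: name, type, sequence,
    length, Tm, per-strand in-silico amplicon counts and size range.
    Unevaluated statistics are serialized as ``NA``.
    """
    rows = []
    for c in candidates:
        seq = c.tailed_seq or c.core_seq
        rows.append(
            {
                "name": c.name,
                "type": "fw",
                "sequence": seq,
                "length_bp": len(seq),
                "tm_C": round(c.tm_core, 1) if c.tm_core is not None else "NA",
                "n_amplicons_fw": _na(c.n_amplicons_fw),
                "n_amplicons_rv": _na(c.n_amplicons_rv),
                "amp_size_min": _na(c.amp_size_min),
                "amp_size_max": _na(c.amp_size_max),
            }
        )
    pd.DataFrame(rows, columns=PRIMER_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_primer_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def _na(x):
    return x if x is not None else "NA"


# --- fingerprint / matrix JSON -------------------------------------------


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
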