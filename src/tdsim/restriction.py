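"""Restriction digestion and adaptor ligation.

Models complete digestion of linear contigs by a type-II enzyme, fragment
generation indexed by top-strand cut positions, and ligation of an
adaptor duplex onto the sticky ends.  Ligation regenerates the overhang
bases but not the full recognition motif, so ligated junctions cannot be
re-cut — the property the SSAP protocol relies on to stop re-digestion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable

from .seqio import Genome

CHROMOSOME_END = "chromosome_end"
CUT_OVERHANG = "cut_overhang"

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# IUPAC -> regex character class (N in the *sequence* never matches: the
# expansion below only applies to motif letters, and sequences are ACGTN
# with N absent from every class).
_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Recognition motif plus top/bottom cut offsets (bases from motif start)."""

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition motif")
        m = len(self.recognition)
        if not (0 <= self.cut_top <= m and 0 <= self.cut_bottom <= m):
            raise ValueError(f"{self.name}: cut offsets outside motif")

    @property
    def overhang(self) -> str:
        """Single-stranded 5' extension left at each cut end."""
        lo, hi = sorted((self.cut_top, self.cut_bottom))
        return self.recognition[lo:hi]


ECORI = RestrictionEnzyme("EcoRI", "GAATTC", 1, 5)


@dataclass(frozen=True)
class AdaptorDuplex:
    """Double-stranded adaptor with a 5' overhang matching the enzyme's ends.

    ``strand_a`` is the strand read 5'->3' across a left-end junction into
    the genome; ``strand_b`` (carrying the overhang at its 5' end) continues
    the top strand at a right-end junction.
    """

    strand_a: str
    strand_b: str
    overhang: str

    def __post_init__(self) -> None:
        if not self.strand_b.startswith(self.overhang):
            raise ValueError("strand_b must begin with the overhang")
        core_b = self.strand_b[len(self.overhang):]
        # double-stranded core must be perfectly complementary; strand_a may
        # carry an extra unpaired 5' tip
        if not revcomp(core_b) == self.strand_a[-len(core_b):]:
            raise ValueError("adaptor core strands are not complementary")

    @property
    def extension_beyond_overhang(self) -> int:
        """Bases the ligated adaptor adds to a product beyond the overhang."""
        return len(self.strand_b) - len(self.overhang)

    def compatible_with(self, enzyme: RestrictionEnzyme) -> bool:
        # a 5' overhang ligates onto its reverse complement; AATT is
        # self-complementary so equality holds for EcoRI
        return self.overhang == revcomp(enzyme.overhang)


ECORI_ADAPTOR = AdaptorDuplex(
    strand_a="CTCGTAGACTGCGTACC",
    strand_b="AATTGGTACGCAGTCTAC",
    overhang="AATT",
)


@dataclass
class Fragment:
    """A restriction fragment; ``span`` runs top-strand cut to top-strand cut."""

    contig: str
    span: tuple[int, int]
    sequence: str
    left_end: str = CHROMOSOME_END
    right_end: str = CHROMOSOME_END
    left_adaptor: bool = False
    right_adaptor: bool = False

    def __len__(self) -> int:
        return self.span[1] - self.span[0]


def motif_regex(motif: str) -> re.Pattern:
    if not motif:
        raise ValueError("empty motif")
    try:
        return re.compile("".join(_IUPAC_RE[c] for c in motif.upper()))
    except KeyError as e:
        raise ValueError(f"non-IUPAC motif character {e.args[0]!r}") from None


def scan_sites(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """0-based start positions of every top-strand motif occurrence.

    Overlapping occurrences are all reported; palindromic motifs (EcoRI)
    appear once per duplex site by construction.
    """
    pat = motif_regex(enzyme.recognition)
    pos, out = 0, []
    while (m := pat.search(sequence, pos)) is not None:
        out.append(m.start())
        pos = m.start() + 1
    return out


def digest(genome: Genome, enzyme: RestrictionEnzyme = ECORI) -> list[Fragment]:
    """Completely digest every contig; fragments tile each contig exactly."""
    frags: list[Fragment] = []
    for contig, seq in genome.contigs.items():
        cuts = [s + enzyme.cut_top for s in scan_sites(seq, enzyme)]
        bounds = [0] + cuts + [len(seq)]
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            frags.append(
                Fragment(
                    contig=contig,
                    span=(a, b),
                    sequence=seq[a:b],
                    left_end=CHROMOSOME_END if i == 0 else CUT_OVERHANG,
                    right_end=CHROMOSOME_END if b == len(seq) else CUT_OVERHANG,
                )
            )
    return frags


def ligate_adaptors(
    fragments: Iterable[Fragment], adaptor: AdaptorDuplex = ECORI_ADAPTOR,
    enzyme: RestrictionEnzyme = ECORI,
) -> list[Fragment]:
    """Mark every cut end as adaptor-ligated; chromosome ends are untouched."""
    if not adaptor.compatible_with(enzyme):
        raise ValueError(
            f"adaptor overhang {adaptor.overhang} incompatible with "
            f"{enzyme.name} overhang {enzyme.overhang}"
        )
    return [
        replace(
            f,
            left_adaptor=f.left_end == CUT_OVERHANG,
            right_adaptor=f.right_end == CUT_OVERHANG,
        )
        for f in fragments
    ]


def junction_sequence(
    fragment: Fragment, side: str, adaptor: AdaptorDuplex = ECORI_ADAPTOR,
    genomic_bases: int = 30,
) -> str:
    """Top-strand sequence reading across the adaptor-genome junction.

    At a right-end junction the top strand continues into ``strand_b``;
    at a left-end junction it enters the genome from ``strand_a``.
    """
    n = max(genomic_bases, 10)
    if side == "right":
        if not fragment.right_adaptor:
            raise ValueError("right side is not ligated")
        return fragment.sequence[-n:] + adaptor.strand_b
    if side == "left":
        if not fragment.left_adaptor:
            raise ValueError("left side is not ligated")
        return adaptor.strand_a + fragment.sequence[:n]
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")
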