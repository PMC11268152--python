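"""Virtual gel electrophoresis: band binning and lane rendering.

A gel cannot resolve arbitrarily close product lengths, so amplicons are
merged into bands by single-linkage clustering under a size-dependent
tolerance emulating agarose resolution.  Intensity is the number of
co-migrating amplicons (several identical-length products from multiple
element copies make one strong band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

from .insilico_pcr import Amplicon


@dataclass(frozen=True)
class ToleranceModel:
    """Merge tolerance at size s: ``max(abs_bp, rel_frac * s)``."""

    abs_bp: float = 5.0
    rel_frac: float = 0.02

    def __call__(self, size: float) -> float:
        return max(self.abs_bp, self.rel_frac * size)


@dataclass
class Band:
    size: float
    intensity: int
    members: list = field(default_factory=list)


@dataclass
class Fingerprint:
    """Per-sample, per-primer multiset of gel bands (sorted large to small)."""

    sample_label: str
    primer: str
    bands: list[Band] = field(default_factory=list)

    def sizes(self) -> list[float]:
        return [b.size for b in self.bands]

    def to_dict(self) -> dict:
        return {
            "sample_label": self.sample_label,
            "primer": self.primer,
            "bands": [{"size": b.size, "intensity": b.intensity} for b in self.bands],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Fingerprint":
        return cls(
            d["sample_label"],
            d["primer"],
            [Band(b["size"], b["intensity"]) for b in d["bands"]],
        )


def _single_linkage(values: Sequence[float], tolerance: ToleranceModel) -> list[list[int]]:
    """Cluster indices of ``values`` by single linkage on sorted order."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    clusters: list[list[int]] = []
    for idx in order:
        if clusters:
            prev = values[clusters[-1][-1]]
            cur = values[idx]
            if cur - prev <= tolerance((prev + cur) / 2):
                clusters[-1].append(idx)
                continue
        clusters.append([idx])
    return clusters


def bin_bands(
    amplicons: Sequence[Amplicon],
    tolerance: ToleranceModel = ToleranceModel(),
    sample_label: str = "",
    primer: str = "",
) -> Fingerprint:
    """Merge amplicon product lengths into gel bands.

    Band size is the median member length (robust to asymmetric merges);
    intensity counts members, so intensities over a fingerprint sum to
    the number of input amplicons.
    """
    if not primer and amplicons:
        primer = amplicons[0].source_primer
    lengths = [a.product_length for a in amplicons]
    bands = [
        Band(
            size=float(median(lengths[i] for i in cl)),
            intensity=len(cl),
            members=[amplicons[i] for i in cl],
        )
        for cl in _single_linkage(lengths, tolerance)
    ]
    bands.sort(key=lambda b: -b.size)
    return Fingerprint(sample_label, primer, bands)


def render_gel(
    fingerprints: Sequence[Fingerprint],
    ladder_step: int = 100,
    rows: int = 30,
) -> str:
    """Deterministic text rendering of lanes between two 100-bp ladders.

    Migration distance follows log10(size) — a display convention only.
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    sizes = [b.size for fp in fingerprints for b in fp.bands]
    if not sizes:
        return "(no bands)"
    lo = min(min(sizes), ladder_step)
    hi = max(max(sizes), ladder_step)
    ladder = [
        s for s in range(ladder_step, int(hi) + ladder_step, ladder_step) if s >= lo / 2
    ]
    lo, hi = min(lo, ladder[0]), max(hi, ladder[-1])
    log_lo, log_hi = math.log10(lo), math.log10(hi)

    def row_of(size: float) -> int:
        if log_hi == log_lo:
            return 0
        # larger products migrate less: row 0 = top of the gel
        return round((log_hi - math.log10(size)) / (log_hi - log_lo) * (rows - 1))

    lanes = ["M"] + [fp.sample_label or f"L{i + 1}" for i, fp in enumerate(fingerprints)] + ["M"]
    width = max(6, max(len(x) for x in lanes) + 2)
    grid = [[" " * width for _ in lanes] for _ in range(rows)]
    for s in ladder:
        mark = f"{s:>5}"
        for col in (0, len(lanes) - 1):
            grid[row_of(s)][col] = mark.center(width)
    for i, fp in enumerate(fingerprints, start=1):
        for band in fp.bands:
            mark = "=" * min(3 + band.intensity, 6)
            grid[row_of(band.size)][i] = mark.center(width)
    header = "".join(x.center(width) for x in lanes)
    return "\n".join([header] + ["".join(r) for r in grid])
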