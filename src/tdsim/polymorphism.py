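"""Cross-sample fingerprint comparison and polymorphic-band calling.

Bands from all samples are aligned into consensus size bins (the
computational analogue of reading lanes against shared ladders), turned
into a band x sample presence/absence matrix, and bands present in some
but not all samples are called polymorphic — each such band is read as a
segregating TE insertion.  Co-migration is treated as identity: two loci
producing same-binned product sizes merge, a known AFLP-class
limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gel import Fingerprint, ToleranceModel, _single_linkage


@dataclass
class PolymorphismMatrix:
    """Consensus band x sample presence/absence with polymorphism flags."""

    consensus_bands: list[float]
    samples: list[str]
    presence: np.ndarray  # shape (n_bands, n_samples), dtype int
    primer: str = ""

    @property
    def polymorphic(self) -> np.ndarray:
        """Per-band flag: row contains both presence and absence."""
        if self.presence.size == 0:
            return np.zeros(0, dtype=bool)
        return (self.presence.min(axis=1) == 0) & (self.presence.max(axis=1) == 1)

    def to_dict(self) -> dict:
        return {
            "primer": self.primer,
            "consensus_bands": list(map(float, self.consensus_bands)),
            "samples": list(self.samples),
            "presence": self.presence.astype(int).tolist(),
            "polymorphic": self.polymorphic.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolymorphismMatrix":
        return cls(
            consensus_bands=list(d["consensus_bands"]),
            samples=list(d["samples"]),
            presence=np.asarray(d["presence"], dtype=int).reshape(
                len(d["consensus_bands"]), len(d["samples"])
            ),
            primer=d.get("primer", ""),
        )


def align_patterns(
    fingerprints: list[Fingerprint],
    tolerance: ToleranceModel = ToleranceModel(),
) -> PolymorphismMatrix:
    """Cluster all samples' band sizes into consensus bins.

    All fingerprints must come from the same primer; presence[i][j] = 1
    iff sample j contributed a band to bin i.
    """
    primers = {fp.primer for fp in fingerprints}
    if len(primers) > 1:
        raise ValueError(f"fingerprints from different primers: {sorted(primers)}")
    samples = [fp.sample_label for fp in fingerprints]
    sizes: list[float] = []
    owner: list[int] = []
    for j, fp in enumerate(fingerprints):
        for b in fp.bands:
            sizes.append(b.size)
            owner.append(j)
    clusters = _single_linkage(sizes, tolerance)
    consensus = [float(np.median([sizes[i] for i in cl])) for cl in clusters]
    presence = np.zeros((len(clusters), len(samples)), dtype=int)
    for row, cl in enumerate(clusters):
        for i in cl:
            presence[row, owner[i]] = 1
    order = np.argsort(consensus)
    return PolymorphismMatrix(
        consensus_bands=[consensus[i] for i in order],
        samples=samples,
        presence=presence[order],
        primer=primers.pop() if primers else "",
    )


def call_polymorphisms(matrix: PolymorphismMatrix) -> dict:
    """Summary: polymorphic band count plus per-pair band differences.

    Pair differences are Hamming distances between presence columns,
    computed on consensus rows so the size tolerance is applied once
    globally.
    """
    poly = matrix.polymorphic
    pair_diffs = {}
    for j in range(len(matrix.samples)):
        for k in range(j + 1, len(matrix.samples)):
            d = int(np.sum(matrix.presence[:, j] != matrix.presence[:, k]))
            pair_diffs[f"{matrix.samples[j]}|{matrix.samples[k]}"] = d
    return {
        "primer": matrix.primer,
        "n_consensus_bands": len(matrix.consensus_bands),
        "n_polymorphic_bands": int(poly.sum()),
        "polymorphic_band_sizes": [
            float(s) for s, p in zip(matrix.consensus_bands, poly) if p
        ],
        "pairwise_differences": pair_diffs,
    }


def pairwise_distance(matrix: PolymorphismMatrix, metric: str = "jaccard") -> np.ndarray:
    """Band-sharing distance matrix (symmetric, zero diagonal).

    jaccard: 1 - |A∩B| / |A∪B|; dice: 1 - 2|A∩B| / (|A|+|B|).
    Pairs involving a zero-band sample are undefined and returned NaN.
    """
    if metric not in ("jaccard", "dice"):
        raise ValueError(f"unknown metric {metric!r}")
    P = matrix.presence.astype(bool)
    n = P.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    D = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            a, b = P[:, j], P[:, k]
            if a.sum() == 0 or b.sum() == 0:
                D[j, k] = D[k, j] = np.nan
                continue
            inter = int(np.sum(a & b))
            if metric == "jaccard":
                union = int(np.sum(a | b))
                d = 1.0 - inter / union
            else:
                d = 1.0 - 2 * inter / (int(a.sum()) + int(b.sum()))
            D[j, k] = D[k, j] = d
    return D
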