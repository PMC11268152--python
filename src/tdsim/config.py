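"""Declarative run configuration (YAML).

Every published protocol constant ships as the default, so an empty
config reproduces the reference assay: EcoRI digestion, the standard
adaptor pair, 20-mer primers from 100 bp LTR windows, 40-60% GC, core
Tm 55-60 C, the 19-60 amplicon acceptance band and the 5 kb size cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .gel import ToleranceModel
from .primer_design import DesignParameters
from .restriction import AdaptorDuplex, ECORI, ECORI_ADAPTOR, RestrictionEnzyme


@dataclass
class RunConfig:
    enzyme: RestrictionEnzyme = ECORI
    adaptor: AdaptorDuplex = ECORI_ADAPTOR
    design: DesignParameters = field(default_factory=DesignParameters)
    tolerance: ToleranceModel = field(default_factory=ToleranceModel)
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig; missing keys fall back to protocol defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    enzyme = ECORI
    if "enzyme" in raw:
        e = raw["enzyme"]
        enzyme = RestrictionEnzyme(
            e.get("name", "custom"),
            e["recognition"].upper(),
            int(e["cut_top"]),
            int(e["cut_bottom"]),
        )
    adaptor = ECORI_ADAPTOR
    if "adaptor" in raw:
        a = raw["adaptor"]
        adaptor = AdaptorDuplex(
            a["strand_a"].upper(), a["strand_b"].upper(), a["overhang"].upper()
        )
    design = DesignParameters(**raw.get("design", {}))
    tol = raw.get("tolerance", {})
    tolerance = ToleranceModel(
        abs_bp=float(tol.get("abs_bp", 5.0)), rel_frac=float(tol.get("rel_frac", 0.02))
    )
    return RunConfig(
        enzyme=enzyme,
        adaptor=adaptor,
        design=design,
        tolerance=tolerance,
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
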