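"""Analysis configuration: every printed cut-off of the study in one place.

The defaults are the acceptance filters and differential thresholds of the
original MudPIT/SEQUEST workflow: charge-tiered Xcorr minima (1.5/2.0/2.5 for
1+/2+/≥3+ peptide ions, strict ``>``), peptide probability ≤ 0.001, protein
consensus score ≥ 10, the dual DAve/DCI significance thresholds (|DAve| > 0.4
AND |DCI| > 400, both strict), the heavy-inner-membrane membership rule
(score > 30) and the virtual-map score-class bounds (low ≤ 15 < mid < 35 ≤
high).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

try:  # py3.11+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None

from pydantic import BaseModel, Field, field_validator, model_validator

MergePolicy = Literal["max", "mean", "sum"]


class AnalysisConfig(BaseModel):
    """Thresholds and policies for the full filtering/comparison pipeline."""

    xcorr_min_by_charge: dict[int, float] = Field(
        default_factory=lambda: {1: 1.5, 2: 2.0, 3: 2.5},
        description="Strict Xcorr minimum per precursor charge; the highest "
        "listed charge tier applies to all larger charges.",
    )
    probability_max: float = 0.001
    consensus_min: float = 10.0
    dave_threshold: float = 0.4
    dci_threshold: float = 400.0
    him_score_threshold: float = 30.0
    sc_class_bounds: tuple[float, float] = (15.0, 35.0)
    merge_policy: MergePolicy = "max"
    pka_table_id: str = "emboss"
    mass_table_id: Literal["average", "monoisotopic"] = "average"
    seed: int = 0

    model_config = {"validate_assignment": True}

    @field_validator(
        "probability_max",
        "consensus_min",
        "dave_threshold",
        "dci_threshold",
        "him_score_threshold",
    )
    @classmethod
    def _nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("thresholds must be >= 0")
        return v

    @field_validator("xcorr_min_by_charge")
    @classmethod
    def _valid_tiers(cls, v: dict[int, float]) -> dict[int, float]:
        if not v:
            raise ValueError("at least one charge tier required")
        if any(z < 1 for z in v) or any(x < 0 for x in v.values()):
            raise ValueError("charges must be >= 1 and Xcorr minima >= 0")
        return v

    @model_validator(mode="after")
    def _bounds_increasing(self) -> "AnalysisConfig":
        lo, hi = self.sc_class_bounds
        if not lo < hi:
            raise ValueError("sc_class_bounds must be strictly increasing")
        return self

    def xcorr_min(self, charge: int) -> float:
        """Xcorr minimum for a charge; charges above the top tier reuse it."""
        if charge in self.xcorr_min_by_charge:
            return self.xcorr_min_by_charge[charge]
        top = max(self.xcorr_min_by_charge)
        if charge > top:
            return self.xcorr_min_by_charge[top]
        raise KeyError(f"no Xcorr tier for charge {charge}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from TOML (preferred) or JSON, keyed by file extension."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".toml":
            if tomllib is None:  # pragma: no cover
                raise RuntimeError("tomllib unavailable; use JSON config")
            data = tomllib.loads(text)
        else:
            data = json.loads(text)
        raw = data.get("analysis", data)
        if "xcorr_min_by_charge" in raw:
            raw["xcorr_min_by_charge"] = {
                int(k): float(v) for k, v in raw["xcorr_min_by_charge"].items()
            }
        return cls(**raw)
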