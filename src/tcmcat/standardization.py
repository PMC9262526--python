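"""Min-max standardization of raw CAT element scores onto a 0-100 scale.

standardized = (raw - min) / (max - min) * 100, with the per-element extremes
fitted on the full calibration sample (baseline and follow-up scores pooled,
so both timepoints share one scale). Out-of-range scores seen later are
clamped to [0, 100] with a logged warning rather than rejected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["StandardizationParams", "fit_standardizer", "standardize", "standardize_frame"]


@dataclass(frozen=True)
class StandardizationParams:
    """Per-element (score_min, score_max) pairs plus fit provenance."""

    extremes: dict[str, tuple[float, float]]
    provenance: str = ""

    def __post_init__(self):
        for element, (lo, hi) in self.extremes.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError(f"score_max must exceed score_min for {element!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "provenance": self.provenance,
                "extremes": {e: {"min": lo, "max": hi} for e, (lo, hi) in self.extremes.items()},
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "StandardizationParams":
        obj = json.loads(s)
        return cls(
            extremes={e: (v["min"], v["max"]) for e, v in obj["extremes"].items()},
            provenance=obj.get("provenance", ""),
        )


def fit_standardizer(
    raw_scores: Mapping[str, np.ndarray] | pd.DataFrame, provenance: str = ""
) -> StandardizationParams:
    """Fit per-element min/max on the supplied calibration sample."""
    if isinstance(raw_scores, pd.DataFrame):
        raw_scores = {c: raw_scores[c].to_numpy() for c in raw_scores.columns}
    extremes = {}
    for element, scores in raw_scores.items():
        x = np.asarray(scores, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2 or np.unique(x).size < 2:
            raise ValueError(f"need >= 2 distinct scores to fit element {element!r}")
        extremes[element] = (float(x.min()), float(x.max()))
    return StandardizationParams(extremes=extremes, provenance=provenance)


def standardize(raw, element: str, params: StandardizationParams):
    """Map raw score(s) for one element to the 0-100 standardized scale."""
    if element not in params.extremes:
        raise KeyError(f"no fitted extremes for element {element!r}")
    lo, hi = params.extremes[element]
    x = np.asarray(raw, dtype=float)
    out = (x - lo) / (hi - lo) * 100.0
    clipped = np.clip(out, 0.0, 100.0)
    n = int(np.sum(clipped != out))
    if n:
        logger.warning("clamped %d standardized %s scores to [0, 100]", n, element)
    return float(clipped) if clipped.ndim == 0 else clipped


def standardize_frame(df: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    """Standardize every column of a per-element raw-score frame."""
    return pd.DataFrame(
        {c: standardize(df[c].to_numpy(), c, params) for c in df.columns}, index=df.index
    )
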