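"""Normalized DARC apoptosis counts.

DARC (detection of apoptosing retinal cells) images yield one spot
count per observer per animal.  Counts are aggregated across masked
observers and expressed relative to the untreated-lesion and naive
group means:

    DC% = 100 * (DC - mean_DC_naive) / (mean_DC_lesion - mean_DC_naive)

so an animal at the naive mean scores 0, one at the lesion-only mean
scores 100, and values outside [0, 100] are legitimate for extreme
animals.  The two group means are computed once per experiment and
reused for every animal (no leave-one-out), so the normalized group
means of the lesion-only and naive groups are exactly 100 and 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DarcRecord",
    "aggregate_observers",
    "normalized_darc_count",
    "normalize_darc_table",
]


class DegenerateNormalizationError(ValueError):
    """Lesion and naive group mean counts coincide; DC% is undefined."""


@dataclass
class DarcRecord:
    """Per-animal observer counts with the aggregated count DC."""

    animal_id: str
    group: str
    observer_counts: list[float]
    dc: float
    dc_percent: float | None = None


def aggregate_observers(counts, method: str = "mean") -> float:
    """Collapse the masked observers' spot counts for one animal into a
    single DC (arithmetic mean by default; median switch)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one observer count")
    if np.any(counts < 0):
        raise ValueError("observer counts must be non-negative")
    if method == "mean":
        return float(np.mean(counts))
    if method == "median":
        return float(np.median(counts))
    raise ValueError(f"unknown aggregation method {method!r}")


def normalized_darc_count(dc: float, mean_dc_p: float, mean_dc_c: float) -> float:
    """DC% = 100 * (DC - mean_DC_c) / (mean_DC_p - mean_DC_c)."""
    if mean_dc_p == mean_dc_c:
        raise DegenerateNormalizationError(
            "lesion-only and naive mean DARC counts are equal "
            f"({mean_dc_p}); the percentage scale is undefined"
        )
    # ratio first: keeps the endpoints exact (DC = mean_p -> 100.0)
    return 100.0 * ((dc - mean_dc_c) / (mean_dc_p - mean_dc_c))


def normalize_darc_table(
    df: pd.DataFrame,
    lesion_group: str = "pONT",
    control_group: str = "naive",
    method: str = "mean",
) -> pd.DataFrame:
    """Normalize a tidy observer-count table.

    Expects columns ``animal_id``, ``group`` and one or more
    ``observer_*`` count columns; returns a copy with ``dc`` and
    ``dc_percent`` added.  The reference means are taken over the
    ``lesion_group`` and ``control_group`` rows.
    """
    obs_cols = [c for c in df.columns if c.startswith("observer")]
    if not obs_cols:
        raise ValueError("no observer_* columns found")
    for g in (lesion_group, control_group):
        if not (df["group"] == g).any():
            raise ValueError(f"group {g!r} absent from table")
    out = df.copy()
    out["dc"] = [
        aggregate_observers(row[obs_cols].dropna().to_numpy(), method)
        for _, row in df.iterrows()
    ]
    mean_p = float(out.loc[out["group"] == lesion_group, "dc"].mean())
    mean_c = float(out.loc[out["group"] == control_group, "dc"].mean())
    out["dc_percent"] = [
        normalized_darc_count(dc, mean_p, mean_c) for dc in out["dc"]
    ]
    return out
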