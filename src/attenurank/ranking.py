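"""Performance-attenuation ranking and binary labeling.

The ranking system turns the raw monitoring data into one binary
classification target per response variable (perceptual response, creatine
kinase, countermovement jump, drop jump, drop-jump contact time, reactive
strength index):

1. *pre/post difference* — post-match minus pre-match value, in the
   variable's own units (a CMJ drop from 50 to 45 cm is −5 cm);
2. *intra-match decline* — second-half minus first-half value for four GPS
   running metrics (total distance, accelerations, sprints, explosive
   distance);
3. the raw declines are min–max scaled cohort-wise to a 0–1 *severity*
   (worst decliner → 1, least decline → 0) and averaged with configurable
   weights (default 25% per metric) into an *overall decline score*;
4. each variable's pre/post difference is likewise min–max scaled to a
   0–1 *pre-existing ranking* oriented so that greater attenuation means a
   larger value (for jump metrics and perceptual response a decrease is
   worse; for contact time and creatine kinase an increase is worse);
5. *adjusted ranking* = pre-existing ranking × overall decline score;
6. a cohort *median split* on the adjusted rankings yields Group 0
   (minimal decline, ≤ median) and Group 1 (significant decline, > median),
   which is balanced by construction for tie-free inputs.

Degenerate constant inputs map to 0.5 everywhere (all athletes sit at the
median, so the split deterministically produces all-Group-0).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import HALF_METRICS, OUTPUT_VARIABLES, _PANEL_SUFFIX

__all__ = [
    "DEFAULT_ORIENTATION",
    "WeightVector",
    "DegenerateScalingError",
    "MissingDataError",
    "pre_post_difference",
    "intra_match_decline",
    "normalize_declines",
    "overall_decline_score",
    "pre_existing_ranking",
    "adjusted_ranking",
    "median_split",
    "compute_labels",
    "write_labels",
]

DECLINE_METRICS: tuple[str, ...] = HALF_METRICS

# Which sign of the pre/post difference indicates attenuation.  Contact time
# and creatine kinase worsen by increasing; the jump metrics worsen by
# decreasing.  Perceptual response defaults to "higher score = better
# wellbeing", so a decrease is worse; flip it if your questionnaire scores
# the other way round.
DEFAULT_ORIENTATION: dict[str, str] = {
    "pr": "decrease_worse",
    "ck": "increase_worse",
    "cmj": "decrease_worse",
    "dj": "decrease_worse",
    "djct": "increase_worse",
    "rsi": "decrease_worse",
}


class DegenerateScalingError(ValueError):
    """Min–max scaling requested on a cohort too small to define a range."""


class MissingDataError(KeyError):
    """A required time point or column is absent."""


@dataclasses.dataclass(frozen=True)
class WeightVector:
    """Per-metric weights for the overall decline score; must sum to 1."""

    weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if len(self.weights) != len(DECLINE_METRICS):
            raise ValueError(
                f"expected {len(DECLINE_METRICS)} weights, got {len(self.weights)}"
            )
        if any(not 0.0 <= w <= 1.0 for w in self.weights):
            raise ValueError(f"weights must lie in [0, 1], got {self.weights}")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got sum {sum(self.weights)!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _panel_cols(variable: str) -> tuple[str, str]:
    if variable not in OUTPUT_VARIABLES:
        raise MissingDataError(f"unknown output variable {variable!r}")
    suffix = _PANEL_SUFFIX[variable]
    return f"{variable}_pre{suffix}", f"{variable}_post{suffix}"


def pre_post_difference(table: pd.DataFrame, variable: str) -> pd.Series:
    """Post-match minus pre-match value per athlete, in output units."""
    pre_col, post_col = _panel_cols(variable)
    for col in (pre_col, post_col):
        if col not in table.columns:
            raise MissingDataError(f"missing time point column {col!r}")
    diff = table[post_col].astype(float) - table[pre_col].astype(float)
    diff.name = f"{variable}_diff"
    return diff


def intra_match_decline(table: pd.DataFrame) -> pd.DataFrame:
    """Second-half minus first-half value for the four GPS running metrics.

    Negative values are declines (the typical case); positive values are
    second-half improvements.
    """
    out = {}
    for metric in DECLINE_METRICS:
        suffix = "_m" if metric in ("distance", "explosive_distance") else ""
        h1, h2 = f"{metric}_h1{suffix}", f"{metric}_h2{suffix}"
        for col in (h1, h2):
            if col not in table.columns:
                raise MissingDataError(f"missing half column {col!r}")
        out[metric] = table[h2].astype(float) - table[h1].astype(float)
    return pd.DataFrame(out, index=table.index)


def _minmax_severity(severity: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Cohort min–max scaling; a zero range maps everyone to 0.5."""
    lo, hi = float(np.min(severity)), float(np.max(severity))
    if hi == lo:
        return np.full(severity.shape, 0.5), (lo, hi)
    return (severity - lo) / (hi - lo), (lo, hi)


def normalize_declines(
    raw: pd.DataFrame, clip_improvements: bool = False
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Min–max scale raw intra-match declines to 0–1 severity per metric.

    The athlete with the worst decline (most negative raw value) maps to 1,
    the athlete with the least decline (or biggest improvement) to 0.  With
    ``clip_improvements`` second-half improvements are floored at zero
    severity before scaling, so an outlier improver does not stretch the
    scale.  Returns the scaled frame and the (lo, hi) severity bounds used
    per metric.
    """
    if len(raw) < 2:
        raise DegenerateScalingError(
            "cohort min–max scaling needs at least 2 athletes"
        )
    scaled, bounds = {}, {}
    for metric in raw.columns:
        severity = -np.asarray(raw[metric], dtype=float)
        if clip_improvements:
            severity = np.maximum(severity, 0.0)
        scaled[metric], bounds[metric] = _minmax_severity(severity)
    return pd.DataFrame(scaled, index=raw.index), bounds


def overall_decline_score(normalized, weights: WeightVector | Sequence[float] | None = None):
    """Weighted mean of normalized declines; the in-match attenuation score.

    Accepts a single 4-vector (returns a float) or a per-athlete frame
    (returns a Series).  The worked example: normalized declines
    (0.4, 0.5, 0.6, 0.3) with equal weights give 0.45.
    """
    if weights is None:
        weights = WeightVector()
    elif not isinstance(weights, WeightVector):
        weights = WeightVector(tuple(float(w) for w in weights))
    w = weights.as_array()
    if isinstance(normalized, pd.DataFrame):
        values = normalized.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("normalized declines must lie in [0, 1]")
        return pd.Series(values @ w, index=normalized.index, name="overall_decline_score")
    values = np.asarray(normalized, dtype=float)
    if values.shape != w.shape:
        raise ValueError(f"expected {w.shape[0]} normalized values, got {values.shape}")
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("normalized declines must lie in [0, 1]")
    return float(values @ w)


def pre_existing_ranking(
    differences: pd.Series | Sequence[float],
    variable: str,
    orientation: Mapping[str, str] | None = None,
) -> pd.Series:
    """Min–max scaled attenuation severity of the pre/post differences.

    Oriented so that greater attenuation gives a larger value: for
    decrease-worse variables severity is the negated difference, for
    increase-worse variables the difference itself.  Constant input maps
    everyone to 0.5.
    """
    orientation = dict(DEFAULT_ORIENTATION, **(orientation or {}))
    diffs = pd.Series(differences, dtype=float)
    if len(diffs) < 2:
        raise DegenerateScalingError("pre-existing ranking needs >= 2 athletes")
    direction = orientation.get(variable)
    if direction not in ("decrease_worse", "increase_worse"):
        raise ValueError(f"no orientation configured for variable {variable!r}")
    severity = -diffs.to_numpy() if direction == "decrease_worse" else diffs.to_numpy()
    scaled, _ = _minmax_severity(severity)
    return pd.Series(scaled, index=diffs.index, name=f"{variable}_pre_rank")


def adjusted_ranking(pre_rank, overall_score):
    """Exact product of pre-existing ranking and overall decline score."""
    return pre_rank * overall_score


def median_split(adjusted) -> pd.Series | np.ndarray:
    """Binary group labels: 0 if adjusted ranking <= cohort median, else 1.

    The median is the standard mid-point of the two central order
    statistics for even cohorts, so tie-free continuous inputs split into
    near-equal groups.
    """
    values = np.asarray(adjusted, dtype=float)
    if values.size < 2:
        raise ValueError("median split needs >= 2 athletes")
    groups = (values > np.median(values)).astype(np.int64)
    if isinstance(adjusted, pd.Series):
        return pd.Series(groups, index=adjusted.index, name="group")
    return groups


def compute_labels(
    table: pd.DataFrame,
    weights: WeightVector | None = None,
    orientation: Mapping[str, str] | None = None,
    clip_improvements: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Run the full ranking pipeline on a cohort table.

    Returns a tidy labels frame (one row per athlete × output variable with
    columns ``athlete_id, variable, difference, pre_existing_ranking,
    overall_decline_score, adjusted_ranking, group``) and a ledger dict
    recording the scaling bounds and medians actually used, so any label
    can be audited back to the raw data.
    """
    raw = intra_match_decline(table)
    normalized, decline_bounds = normalize_declines(raw, clip_improvements)
    score = overall_decline_score(normalized, weights)

    rows = []
    ledger: dict = {
        "decline_severity_bounds": {k: list(v) for k, v in decline_bounds.items()},
        "variables": {},
    }
    for variable in OUTPUT_VARIABLES:
        diff = pre_post_difference(table, variable)
        pre_rank = pre_existing_ranking(diff, variable, orientation)
        adjusted = adjusted_ranking(pre_rank, score)
        groups = median_split(adjusted)
        ledger["variables"][variable] = {
            "median_adjusted_ranking": float(np.median(adjusted)),
            "group_counts": {
                "0": int((groups == 0).sum()),
                "1": int((groups == 1).sum()),
            },
        }
        rows.append(
            pd.DataFrame(
                {
                    "athlete_id": table["athlete_id"].to_numpy(),
                    "variable": variable,
                    "difference": diff.to_numpy(),
                    "pre_existing_ranking": pre_rank.to_numpy(),
                    "overall_decline_score": score.to_numpy(),
                    "adjusted_ranking": adjusted.to_numpy(),
                    "group": groups.to_numpy(),
                }
            )
        )
    labels = pd.concat(rows, ignore_index=True)
    return labels, ledger


def write_labels(labels: pd.DataFrame, ledger: dict, out_dir) -> None:
    """Persist the labels CSV and the JSON scaling ledger."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels.to_csv(out / "labels.csv", index=False)
    with open(out / "ranking_ledger.json", "w") as fh:
        json.dump(ledger, fh, indent=2)


def labels_wide(labels: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy labels frame to one 0/1 group column per variable."""
    wide = labels.pivot(index="athlete_id", columns="variable", values="group")
    wide = wide[[v for v in OUTPUT_VARIABLES if v in wide.columns]]
    wide.columns = [f"group_{v}" for v in wide.columns]
    return wide.astype(np.int64).reset_index()
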