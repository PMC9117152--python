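"""Predictor selection statistics: calibrated pass probabilities and ranking.

A rapid pre-screen computes cheap versions of the final design metrics.  On
a calibration subset that also went through full design, each filter (a goal
threshold on a final metric) yields a binary pass/fail label; binning the
calibration set by the rapid metric gives an empirical pass fraction per
bin, smoothed by a fitted four-parameter logistic sigmoid.  A candidate's
probability of passing *all* filters is the product of its per-filter
probabilities (filters treated as independent, an approximation), and
candidates are ranked by that product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class CalibrationError(ValueError):
    pass


def _sigmoid(x, floor, ceiling, x0, slope):
    return floor + (ceiling - floor) / (1.0 + np.exp(-(x - x0) / slope))


@dataclass
class FilterCalibration:
    """Binned pass fractions and a fitted sigmoid for one filter."""

    name: str
    goal_threshold: float
    pass_if: str  # "ge" or "le" on the final metric
    bin_centers: np.ndarray
    bin_fractions: np.ndarray
    bin_counts: np.ndarray
    params: tuple | None = None  # (floor, ceiling, x0, slope)
    constant: float | None = None

    def probability(self, rapid_values) -> np.ndarray:
        """Pass probability for rapid metric values, clipped to [0, 1]."""
        x = np.asarray(rapid_values, dtype=float)
        if self.constant is not None:
            return np.full(x.shape, self.constant)
        return np.clip(_sigmoid(x, *self.params), 0.0, 1.0)


def calibrate_filter(
    rapid_values,
    final_values,
    goal_threshold: float,
    pass_if: str = "ge",
    n_bins: int = 20,
    name: str = "filter",
) -> FilterCalibration:
    """Fit a pass-probability curve for one filter.

    Equal-count bins over the rapid metric (empty/duplicate-edge bins merge
    automatically via quantile edges); the sigmoid's floor and ceiling are
    free in [0, 1] and its direction is determined by the bin sequence.
    All-pass or all-fail calibrations yield a constant with a warning.
    """
    rapid = np.asarray(rapid_values, dtype=float)
    final = np.asarray(final_values, dtype=float)
    if rapid.shape != final.shape:
        raise CalibrationError("rapid and final values must align")
    if len(rapid) < 50:
        raise CalibrationError("need at least 50 calibration pairs")
    if pass_if not in ("ge", "le"):
        raise CalibrationError("pass_if must be 'ge' or 'le'")
    passed = final >= goal_threshold if pass_if == "ge" else final <= goal_threshold

    base_rate = float(passed.mean())
    if base_rate in (0.0, 1.0):
        warnings.warn(
            f"filter {name!r}: calibration is all-{'pass' if base_rate else 'fail'}; "
            "using a constant probability"
        )
        return FilterCalibration(
            name,
            goal_threshold,
            pass_if,
            np.array([]),
            np.array([]),
            np.array([]),
            constant=base_rate,
        )

    edges = np.unique(np.quantile(rapid, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise CalibrationError("rapid metric has too few distinct values to bin")
    idx = np.clip(np.searchsorted(edges, rapid, side="right") - 1, 0, len(edges) - 2)
    centers, fractions, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        centers.append(float(rapid[mask].mean()))
        fractions.append(float(passed[mask].mean()))
        counts.append(int(mask.sum()))
    centers = np.array(centers)
    fractions = np.array(fractions)
    counts = np.array(counts)

    increasing = fractions[-1] >= fractions[0]
    scale = max(np.std(rapid), 1e-9)
    p0 = [
        max(fractions.min(), 1e-3),
        min(fractions.max(), 1 - 1e-3),
        float(np.median(rapid)),
        scale if increasing else -scale,
    ]
    bounds = (
        [0.0, 0.0, rapid.min() - 10 * scale, -100 * scale],
        [1.0, 1.0, rapid.max() + 10 * scale, 100 * scale],
    )
    try:
        params, _ = curve_fit(
            _sigmoid,
            centers,
            fractions,
            p0=p0,
            bounds=bounds,
            sigma=1.0 / np.sqrt(counts),
            maxfev=20_000,
        )
    except RuntimeError:
        warnings.warn(f"filter {name!r}: sigmoid fit failed; using the base rate")
        return FilterCalibration(
            name, goal_threshold, pass_if, centers, fractions, counts,
            constant=base_rate,
        )
    return FilterCalibration(
        name, goal_threshold, pass_if, centers, fractions, counts,
        params=tuple(params),
    )


@dataclass
class CandidateScore:
    candidate_id: str
    per_filter: dict[str, float] = field(default_factory=dict)

    @property
    def combined(self) -> float:
        prob = 1.0
        for p in self.per_filter.values():
            prob *= p
        return prob


def rank_candidates(
    candidate_metrics: pd.DataFrame,
    calibrations: dict[str, FilterCalibration],
) -> tuple[pd.DataFrame, list[str]]:
    """Rank candidates by the product of per-filter pass probabilities.

    ``candidate_metrics`` is long format with columns candidate_id, filter,
    rapid_value; every calibrated filter must be present per candidate or
    the candidate is excluded (returned in the second element).  The sort is
    stable and descending, ties broken by candidate id.
    """
    required = set(calibrations)
    wide = candidate_metrics.pivot_table(
        index="candidate_id", columns="filter", values="rapid_value", aggfunc="first"
    )
    missing_cols = required - set(wide.columns)
    for col in missing_cols:
        wide[col] = np.nan
    complete = wide[sorted(required)].notna().all(axis=1)
    excluded = sorted(wide.index[~complete])
    wide = wide[complete]

    probs = pd.DataFrame(index=wide.index)
    for fname, cal in calibrations.items():
        probs[fname] = cal.probability(wide[fname].to_numpy())
    probs["combined"] = probs[sorted(required)].prod(axis=1)
    probs = (
        probs.reset_index()
        .sort_values(
            by=["combined", "candidate_id"], ascending=[False, True], kind="stable"
        )
        .set_index("candidate_id")
    )
    return probs, excluded
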