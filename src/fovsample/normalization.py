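"""Between-run score normalization via shared index arrays.

Quantitative-immunofluorescence scores drift between staining runs (bulb
hours, reagent lots).  The remedy implemented here assumes every run also
stained the same control array ("index array"):

1. quantile-normalize the matched index-array score vectors so all runs
   share one score distribution;
2. for each run, fit a smoothing spline mapping that run's original index
   scores to its quantile-normalized scores — the run's transfer function;
3. apply the transfer function to the run's subject scores, bringing them
   onto the scale of a designated baseline run.

Transfer functions are forced monotone (a higher raw score must never map
to a lower normalized score): the fitted spline is evaluated on a dense
grid and isotonized if it dips.  Outside the fitted score range the map
continues linearly with the boundary slope, and the number of extrapolated
points is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

from .data_model import FovScoreTable, IndexArraySet
from .errors import FittingError, ValidationError

__all__ = [
    "RunTransform",
    "quantile_normalize",
    "fit_run_transform",
    "apply_run_transform",
    "normalize_index_arrays",
    "fit_transforms_from_index",
    "normalize_table",
]

log = logging.getLogger(__name__)

_GRID_SIZE = 257  # dense evaluation grid for isotonization


@dataclass
class RunTransform:
    """Monotone piecewise-linear map from one run's score scale to the baseline scale.

    Stored as node values of the isotonized spline on a dense grid spanning
    the run's observed index-score range; evaluation interpolates between
    nodes and extrapolates linearly with the boundary slope.
    """

    run_id: str
    grid: np.ndarray
    values: np.ndarray
    input_range: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values) < -1e-9 * (np.ptp(self.values) + 1.0)):
            raise ValidationError("transform values must be non-decreasing")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _interp_linear_extrap(np.asarray(x, dtype=float), self.grid, self.values)

    def n_extrapolated(self, x: np.ndarray) -> int:
        x = np.asarray(x, dtype=float)
        return int(((x < self.input_range[0]) | (x > self.input_range[1])).sum())


def _interp_linear_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    y = np.interp(x, xp, fp)
    lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
    hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    below = x < xp[0]
    above = x > xp[-1]
    y = np.where(below, fp[0] + (x - xp[0]) * lo_slope, y)
    y = np.where(above, fp[-1] + (x - xp[-1]) * hi_slope, y)
    return y


def quantile_normalize(runs: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize matched score columns onto one common distribution.

    With complete data the common distribution is the vector of row means of
    the column-sorted matrix; every column then carries the identical sorted
    value multiset and keeps its within-column rank order.  Missing entries
    are allowed: a column's quantile function is computed on its non-missing
    values and interpolated to the common probability grid, so runs with
    lost cores still contribute.

    Ties within a column receive the mean of the target values at their
    tied ranks.

    Parameters
    ----------
    runs
        Cores x runs frame (NaN = missing core).

    Returns
    -------
    pandas.DataFrame of the same shape, NaN pattern preserved.
    """
    if runs.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least two runs")
    counts = runs.notna().sum(axis=0)
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValidationError(f"run {bad!r} has fewer than 2 non-missing index scores")

    n_max = int(counts.max())
    p_common = (np.arange(1, n_max + 1) - 0.5) / n_max

    # reference quantile function = mean of per-column quantile functions
    ref = np.zeros(n_max)
    for col in runs.columns:
        v = np.sort(runs[col].dropna().to_numpy())
        p_col = (np.arange(1, len(v) + 1) - 0.5) / len(v)
        ref += np.interp(p_common, p_col, v)
    ref /= runs.shape[1]

    out = runs.copy().astype(float)
    for col in runs.columns:
        mask = runs[col].notna().to_numpy()
        v = runs[col].to_numpy()[mask]
        n = len(v)
        order = np.argsort(v, kind="stable")
        p_col = (np.arange(1, n + 1) - 0.5) / n
        targets_sorted = np.interp(p_col, p_common, ref)
        targets = np.empty(n)
        targets[order] = targets_sorted
        # average targets over tied raw values
        uniq, cnt = np.unique(v, return_counts=True)
        for val in uniq[cnt > 1]:
            tie = v == val
            targets[tie] = targets[tie].mean()
        res = out[col].to_numpy()
        res[mask] = targets
        out[col] = res
    return out


def fit_run_transform(
    original: np.ndarray,
    normalized: np.ndarray,
    smoothing: float | None = None,
    run_id: str = "",
) -> RunTransform:
    """Fit a monotone smooth transfer map ``normalized ~ f(original)``.

    A cubic smoothing spline is fit with the penalty chosen by generalized
    cross-validation (override with ``smoothing``, the penalty weight
    ``lam``), then evaluated on a dense grid over the observed input range
    and isotonized so the final map never decreases.

    Raises
    ------
    FittingError
        With fewer than 4 complete (original, normalized) pairs.
    """
    original = np.asarray(original, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    keep = np.isfinite(original) & np.isfinite(normalized)
    x, y = original[keep], normalized[keep]
    if len(x) < 4:
        raise FittingError(f"need >= 4 complete pairs to fit a transfer spline, got {len(x)}")

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # smoothing splines need strictly increasing x: average y over duplicates
    xu, inverse = np.unique(x, return_inverse=True)
    if len(xu) < len(x):
        y = np.bincount(inverse, weights=y) / np.bincount(inverse)
        x = xu
    if len(x) < 4:
        raise FittingError("fewer than 4 distinct original scores; cannot fit a transfer spline")

    try:
        spline = make_smoothing_spline(x, y, lam=smoothing)
    except Exception as exc:  # GCV can fail on near-degenerate designs
        raise FittingError(f"smoothing-spline fit failed: {exc}") from exc

    grid = np.linspace(x[0], x[-1], _GRID_SIZE)
    vals = spline(grid)
    if np.any(np.diff(vals) < 0):
        vals = IsotonicRegression(increasing=True).fit_transform(grid, vals)
    return RunTransform(run_id=run_id, grid=grid, values=np.asarray(vals, dtype=float), input_range=(float(x[0]), float(x[-1])))


def apply_run_transform(transform: RunTransform, scores: np.ndarray) -> tuple[np.ndarray, int]:
    """Map scores through a fitted transfer function.

    Returns the transformed scores and the count of inputs that fell outside
    the fitted range (mapped by linear boundary-slope extrapolation — flagged,
    not fatal).
    """
    scores = np.asarray(scores, dtype=float)
    n_extra = transform.n_extrapolated(scores)
    if n_extra:
        log.warning("%d score(s) outside the fitted range of run %s; extrapolated linearly", n_extra, transform.run_id)
    return transform(scores), n_extra


def normalize_index_arrays(arrays: IndexArraySet) -> pd.DataFrame:
    """Quantile-normalized view of an index-array set."""
    return quantile_normalize(arrays.scores)


def fit_transforms_from_index(
    arrays: IndexArraySet,
    smoothing: float | None = None,
) -> dict[str, RunTransform]:
    """Learn one transfer function per run from a shared index-array set.

    Each run's map goes from its original index scores to the
    quantile-normalized common scale (the scale of the baseline run after
    normalization); the baseline run gets a transform too, which is close to
    identity when runs are similar.
    """
    normalized = normalize_index_arrays(arrays)
    out = {}
    for run in arrays.runs:
        out[run] = fit_run_transform(
            arrays.scores[run].to_numpy(), normalized[run].to_numpy(), smoothing=smoothing, run_id=run
        )
    return out


def normalize_table(
    table: FovScoreTable,
    arrays: IndexArraySet,
    run_id: str,
    smoothing: float | None = None,
) -> tuple[FovScoreTable, dict]:
    """Transform a run's subject scores onto the common (baseline) scale.

    Returns the transformed table and a report with the transform's input
    range and the number of extrapolated subject scores.
    """
    transforms = fit_transforms_from_index(arrays, smoothing=smoothing)
    if run_id not in transforms:
        raise ValidationError(f"run {run_id!r} not present in index arrays ({arrays.runs})")
    t = transforms[run_id]
    new_scores, n_extra = apply_run_transform(t, table.df["score"].to_numpy())
    df = table.df.copy()
    # the map can dip fractionally below zero at the low end; scores stay nonnegative
    df["score"] = np.maximum(new_scores, 0.0)
    out = FovScoreTable.from_frame(df, meta={**table.meta, "normalized_run": run_id})
    report = {
        "run_id": run_id,
        "baseline_run": arrays.baseline_run,
        "input_range": t.input_range,
        "n_extrapolated": n_extra,
        "grid": t.grid.tolist(),
        "values": t.values.tolist(),
    }
    return out, report
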