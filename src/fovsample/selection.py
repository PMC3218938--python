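"""Cross-validated selection of the optimal number of fields of view (FOVs).

The question: how many 20X fields must be sampled from a tissue section so
that their average score predicts the whole-section average (the subject's
"true" score)?  The procedure uses two layers of resampling:

* **outer layer** (prediction-error estimation): either 10-fold
  cross-validation over subjects (``kfold_mc``) or leave-one-out
  (``loo_boot``);
* **inner layer** (model selection inside each training set): Monte-Carlo
  90/10 learning/evaluation splits (``kfold_mc``) or bootstrap resampling
  with out-of-bag evaluation (``loo_boot``), repeated ``n_inner`` times.

For every candidate field count m, a simple linear regression of the
whole-section average on the m-field average is fit on the learning set and
scored on the evaluation set by the prediction error

    PE(m) = (1/N) * sum_i (yhat_i - ybar_i)^2 .

The first local minimum of the inner-averaged PE curve is recorded per
training set; across outer folds, the mean test-set PE curve and the
standard error of the test PE at the (rounded) average first local minimum
feed the one-standard-error parsimony rule: the smallest m whose mean test
PE is within one SE of the minimum model's is selected.  The whole
procedure is repeated ``n_repeats`` times and the selected m averaged.

Field subsets can be drawn two ways.  *Direct* sampling draws m observed
FOV scores without replacement (capped at a subject's field count K_i).
*Parametric* sampling draws m values from Normal(mean_i, sd_i) matched to
the subject — used when subjects have too few fields for direct subsampling
to be unbiased.

Accuracy at the selected m is additionally reported as the average absolute
standardized score: mean over subjects of |yhat_i - ybar_i| / sd_i, i.e.
the prediction's distance from the truth in units of that subject's own
field-to-field SD.

Each candidate m gets its own fresh draws within every inner iteration.
This matters: the first-local-minimum rule stops where the PE curve's
decrement drops below its Monte-Carlo noise, so the noise at adjacent m
must be independent — reusing one sample across m (e.g. nested prefixes of
a single permutation) would correlate it away and push the minimum toward
the largest m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import FovScoreTable, SubjectSummary, summarize_subjects
from .errors import FittingError, ValidationError

__all__ = [
    "SelectionConfig",
    "PeCurve",
    "SelectionResult",
    "ModeComparison",
    "sample_fov_mean",
    "fit_learning_regression",
    "prediction_error",
    "first_local_minimum",
    "one_se_select",
    "avg_abs_standardized_score",
    "run_selection",
    "run_selection_from_summaries",
    "validate_parametric_mode",
]

log = logging.getLogger(__name__)

_SXX_EPS = 1e-12  # learning sets with x-variance at/below this fall back to intercept-only


@dataclass
class SelectionConfig:
    """Tuning knobs of the two-layer resampling procedure.

    Defaults follow the canonical design: 10 outer folds, 1000 inner
    iterations with 90/10 learning/evaluation splits, candidate field
    counts 1..35, and 100 repetitions of the whole procedure.
    """

    design: str = "kfold_mc"  # or "loo_boot"
    m_range: tuple[int, int] = (1, 35)
    n_inner: int = 1000
    inner_eval_fraction: float = 0.10
    n_outer_folds: int = 10
    n_repeats: int = 100
    sampling_mode: str = "direct"  # or "parametric"
    seed: int = 0

    def validate(self) -> None:
        if self.design not in ("kfold_mc", "loo_boot"):
            raise ValidationError(f"unknown design {self.design!r}")
        if self.sampling_mode not in ("direct", "parametric"):
            raise ValidationError(f"unknown sampling mode {self.sampling_mode!r}")
        lo, hi = self.m_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"m_range must satisfy 1 <= lo <= hi, got {self.m_range}")
        if not (0.0 < self.inner_eval_fraction < 1.0):
            raise ValidationError("inner_eval_fraction must be in (0, 1)")
        for name in ("n_inner", "n_outer_folds", "n_repeats"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @property
    def ms(self) -> np.ndarray:
        return np.arange(self.m_range[0], self.m_range[1] + 1)


@dataclass
class PeCurve:
    """Prediction-error curve over candidate field counts."""

    m: np.ndarray
    mean_pe: np.ndarray
    se_pe: np.ndarray
    source: str = "test"


@dataclass
class SelectionResult:
    """Outcome of the full two-layer procedure.

    ``optimal_m`` is the mean of the per-repeat selected field counts;
    ``optimal_m_int`` rounds it half-up to an integer recommendation.  Two
    stability measures are reported, explicitly labeled: ``optimal_m_sd``
    is the SD of the selected m over the ``n_repeats`` repetitions, and
    ``se_outer_mean`` is the across-fold standard error of the test PE at
    the minimum model, averaged over repetitions (the quantity the one-SE
    rule consumed).
    """

    optimal_m: float
    optimal_m_int: int
    optimal_m_sd: float
    per_repeat_m: np.ndarray
    test_pe_curve: PeCurve
    avg_abs_std_score: float
    avg_first_local_min: float
    se_outer_mean: float
    config: SelectionConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# elemental operations (scalar reference forms)
# ---------------------------------------------------------------------------


def sample_fov_mean(
    subject: SubjectSummary | np.ndarray,
    m: int,
    mode: str,
    rng: np.random.Generator,
) -> float:
    """Average score of one simulated m-field sample for one subject.

    Direct mode takes the subject's raw FOV scores and averages
    ``min(m, K)`` of them drawn without replacement (the cap is logged).
    Parametric mode takes a :class:`SubjectSummary` and averages m i.i.d.
    Normal(mean, sd) draws.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    if mode == "direct":
        scores = np.asarray(subject, dtype=float)
        k = len(scores)
        if m > k:
            log.debug("m=%d exceeds subject's %d fields; capped", m, k)
        take = min(m, k)
        return float(rng.choice(scores, size=take, replace=False).mean())
    if mode == "parametric":
        if subject.sd_score < 0:
            raise ValidationError("parametric sampling needs a nonnegative SD")
        return float(rng.normal(subject.mean_score, subject.sd_score, size=m).mean())
    raise ValidationError(f"unknown sampling mode {mode!r}")


def fit_learning_regression(learning: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Ordinary least squares of the whole-section average on the m-field average.

    Returns (intercept, slope).  Raises :class:`FittingError` with fewer
    than 3 pairs or zero variance in x.
    """
    arr = np.asarray(learning, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise FittingError("need >= 3 (x, y) pairs to fit the learning regression")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= _SXX_EPS:
        raise FittingError("degenerate learning set: sampled means have zero variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    return intercept, slope


def prediction_error(model: tuple[float, float], eval_set: Sequence[tuple[float, float]]) -> float:
    """Mean squared prediction error over an evaluation set.

    ``(1/N) * sum_i (yhat_i - ybar_i)^2`` with ``yhat = intercept + slope*x``.
    """
    arr = np.asarray(eval_set, dtype=float)
    if arr.size == 0:
        raise ValidationError("evaluation set is empty")
    intercept, slope = model
    pred = intercept + slope * arr[:, 0]
    return float(np.mean((pred - arr[:, 1]) ** 2))


def first_local_minimum(curve: Sequence[float], ms: Sequence[int] | None = None) -> int:
    """First local minimum of a PE curve over m.

    The smallest m with ``PE(m) <= PE(m-1)`` (vacuous at the first point)
    and ``PE(m) < PE(m+1)``.  A monotone-decreasing curve or a terminal
    plateau has no interior minimum and returns the global-minimum m
    (smallest index on ties) — the conservative, fewer-fields reading.
    """
    pe = np.asarray(curve, dtype=float)
    if pe.size == 0:
        raise ValidationError("empty PE curve")
    ms = np.asarray(ms) if ms is not None else np.arange(1, pe.size + 1)
    for i in range(pe.size - 1):
        if (i == 0 or pe[i] <= pe[i - 1]) and pe[i] < pe[i + 1]:
            return int(ms[i])
    return int(ms[int(np.argmin(pe))])


def one_se_select(mean_pe: Sequence[float], min_m: int, se_at_min: float, ms: Sequence[int] | None = None) -> int:
    """One-standard-error parsimony rule.

    The smallest m at or below ``min_m`` whose mean PE is within
    ``se_at_min`` of the minimum model's mean PE.
    """
    pe = np.asarray(mean_pe, dtype=float)
    ms = np.asarray(ms) if ms is not None else np.arange(1, pe.size + 1)
    if se_at_min < 0:
        raise ValidationError("se_at_min must be >= 0")
    idx_min = int(np.nonzero(ms == min_m)[0][0])
    threshold = pe[idx_min] + se_at_min
    for i in range(idx_min + 1):
        if pe[i] <= threshold:
            return int(ms[i])
    return int(min_m)


def avg_abs_standardized_score(
    predictions: Sequence[float],
    truths: Sequence[float],
    subject_sds: Sequence[float],
) -> float:
    """Mean over subjects of |yhat - ybar| / sd, excluding sd = 0 subjects.

    Measures how far a prediction sits from the whole-section average in
    units of that subject's own field-to-field SD.
    """
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    sds = np.asarray(subject_sds, dtype=float)
    if not (pred.shape == truth.shape == sds.shape):
        raise ValidationError("predictions, truths and subject_sds must be aligned")
    keep = sds > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValidationError("all subject SDs are zero; the standardized score is undefined")
    if n_excluded:
        log.debug("excluded %d subject(s) with zero SD from the standardized score", n_excluded)
    return float(np.mean(np.abs(pred[keep] - truth[keep]) / sds[keep]))


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------


def _draw_means_direct(rng: np.random.Generator, scores_list: list[np.ndarray], ms: np.ndarray, n_draws: int) -> np.ndarray:
    """(n_draws, n_subjects, n_m) m-field averages by direct subsampling.

    For every candidate m a fresh without-replacement m-subset per subject
    and draw: uniform random keys, the m smallest keys select the fields.
    Subjects are grouped by field count so each group is drawn as one
    array; m >= K falls back to the full-sample mean (the cap).
    """
    n_subj = len(scores_list)
    out = np.empty((n_draws, n_subj, ms.size))
    ks = np.array([len(s) for s in scores_list])
    for k in np.unique(ks):
        idx = np.nonzero(ks == k)[0]
        g = idx.size
        block = np.stack([scores_list[i] for i in idx])  # (g, k)
        full_mean = block.mean(axis=1)
        g_idx = np.arange(g)[None, :, None]
        for jm, m in enumerate(ms):
            take = min(int(m), int(k))
            if take == k:
                out[:, idx, jm] = full_mean
                continue
            keys = rng.random((n_draws, g, k))
            sel = np.argpartition(keys, take, axis=2)[:, :, :take]
            out[:, idx, jm] = block[g_idx, sel].mean(axis=2)
    return out


def _draw_means_parametric(
    rng: np.random.Generator, means: np.ndarray, sds: np.ndarray, ms: np.ndarray, n_draws: int
) -> np.ndarray:
    """(n_draws, n_subjects, n_m) averages of m i.i.d. Normal(mean_i, sd_i) draws.

    Drawn in the exactly equivalent one-shot form N(mean_i, sd_i^2 / m),
    independently for every candidate m.
    """
    z = rng.standard_normal((n_draws, means.size, ms.size))
    return means[None, :, None] + (sds[None, :, None] / np.sqrt(ms)[None, None, :]) * z


def _draw_means(rng, cfg, subj_idx, scores_list, means, sds, n_draws):
    ms = cfg.ms
    if cfg.sampling_mode == "direct":
        return _draw_means_direct(rng, [scores_list[i] for i in subj_idx], ms, n_draws)
    return _draw_means_parametric(rng, means[subj_idx], sds[subj_idx], ms, n_draws)


def _batch_regression(xl: np.ndarray, yl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS per (iteration, m).  xl: (B, n, M); yl: (B, n).

    Degenerate learning draws (zero x-variance) fall back to the
    intercept-only model: redrawing cannot help when the cohort itself is
    constant, and the intercept-only fit is the correct limiting model.
    """
    xm = xl.mean(axis=1)
    ym = yl.mean(axis=1)
    xc = xl - xm[:, None, :]
    sxx = np.einsum("bnm,bnm->bm", xc, xc)
    sxy = np.einsum("bnm,bn->bm", xc, yl - ym[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > _SXX_EPS, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    intercept = ym[:, None] - slope * xm
    return intercept, slope


def _pe_of(intercept, slope, xe, ye):
    """PE per (iteration, m).  xe: (B, n, M); ye: (B, n)."""
    pred = intercept[:, None, :] + slope[:, None, :] * xe
    return np.mean((pred - ye[:, :, None]) ** 2, axis=1)


def _outer_folds(rng: np.random.Generator, n: int, design: str, n_folds: int) -> list[np.ndarray]:
    if design == "loo_boot":
        return [np.array([i]) for i in range(n)]
    perm = rng.permutation(n)
    return [f for f in np.array_split(perm, n_folds)]


def _one_repeat(ss: np.random.SeedSequence, cfg, y, sds, scores_list):
    """One repetition of the full two-layer procedure.

    Returns (selected m, avg first local minimum, test PE per fold x m,
    across-fold SE at the minimum model, abs standardized score at the
    selected m).
    """
    ms = cfg.ms
    n = y.size
    rng = np.random.default_rng(ss)
    folds = _outer_folds(rng, n, cfg.design, cfg.n_outer_folds)
    n_folds = len(folds)

    flm = np.empty(n_folds)
    test_pe = np.empty((n_folds, ms.size))
    abs_std = np.full((n_folds, ms.size), np.nan)

    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        n_train = train_idx.size

        # ----- inner layer: model selection within the training set -----
        x_train = _draw_means(rng, cfg, train_idx, scores_list, y, sds, cfg.n_inner)
        y_train = y[train_idx]
        if cfg.design == "kfold_mc":
            n_eval = max(1, int(round(cfg.inner_eval_fraction * n_train)))
            n_learn = n_train - n_eval
            if n_learn < 3:
                raise ValidationError(f"training set of {n_train} leaves a learning set < 3; cohort too small")
            perm = np.argsort(rng.random((cfg.n_inner, n_train)), axis=1)
            learn_pos, eval_pos = perm[:, :n_learn], perm[:, n_learn:]
            xl = np.take_along_axis(x_train, learn_pos[:, :, None], axis=1)
            xe = np.take_along_axis(x_train, eval_pos[:, :, None], axis=1)
            yl, ye = y_train[learn_pos], y_train[eval_pos]
            intercept, slope = _batch_regression(xl, yl)
            pe_inner = _pe_of(intercept, slope, xe, ye).mean(axis=0)
        else:  # bootstrap with out-of-bag evaluation
            pe_sum = np.zeros(ms.size)
            n_done = 0
            boot = rng.integers(0, n_train, size=(cfg.n_inner, n_train))
            while n_done < cfg.n_inner:
                todo = boot[n_done:]
                oob_mask = np.ones((todo.shape[0], n_train), dtype=bool)
                np.put_along_axis(oob_mask, todo, False, axis=1)
                nonempty = oob_mask.any(axis=1)
                if not nonempty.all():  # redraw iterations whose bag covered everyone
                    n_redraw = int((~nonempty).sum())
                    log.debug("redrawing %d bootstrap iteration(s) with empty out-of-bag set", n_redraw)
                    boot = np.vstack([todo[nonempty], rng.integers(0, n_train, size=(n_redraw, n_train))])
                    n_done = 0
                    pe_sum[:] = 0.0
                    continue
                xl = np.take_along_axis(x_train, todo[:, :, None], axis=1)
                yl = y_train[todo]
                intercept, slope = _batch_regression(xl, yl)
                pred = intercept[:, None, :] + slope[:, None, :] * x_train
                sq = (pred - y_train[None, :, None]) ** 2
                w = oob_mask.astype(float)
                pe = np.einsum("bnm,bn->bm", sq, w) / w.sum(axis=1)[:, None]
                pe_sum += pe.sum(axis=0)
                n_done += todo.shape[0]
            pe_inner = pe_sum / cfg.n_inner
        flm[f] = first_local_minimum(pe_inner, ms)

        # ----- outer layer: test-set prediction error ------------------
        x_fit = _draw_means(rng, cfg, train_idx, scores_list, y, sds, 1)
        intercept, slope = _batch_regression(x_fit, y_train[None, :])
        x_test = _draw_means(rng, cfg, test_idx, scores_list, y, sds, 1)
        y_test = y[test_idx]
        pred = intercept[:, None, :] + slope[:, None, :] * x_test  # (1, n_test, M)
        test_pe[f] = np.mean((pred[0] - y_test[:, None]) ** 2, axis=0)
        keep = sds[test_idx] > 0
        if keep.any():
            abs_std[f] = np.mean(np.abs(pred[0][keep] - y_test[keep, None]) / sds[test_idx][keep, None], axis=0)

    avg_flm = float(flm.mean())
    min_m = int(np.clip(np.floor(avg_flm + 0.5), ms[0], ms[-1]))
    mean_test_pe = test_pe.mean(axis=0)
    idx_min = int(np.nonzero(ms == min_m)[0][0])
    se_at_min = float(test_pe[:, idx_min].std(ddof=1) / np.sqrt(n_folds)) if n_folds > 1 else 0.0
    m_sel = one_se_select(mean_test_pe, min_m, se_at_min, ms)
    idx_sel = int(np.nonzero(ms == m_sel)[0][0])
    with np.errstate(invalid="ignore"):
        score = float(np.nanmean(abs_std[:, idx_sel])) if not np.isnan(abs_std[:, idx_sel]).all() else np.nan
    return m_sel, avg_flm, test_pe, se_at_min, score


def run_selection_from_summaries(
    y: np.ndarray,
    sds: np.ndarray,
    config: SelectionConfig,
    scores_list: list[np.ndarray] | None = None,
) -> SelectionResult:
    """Run the two-layer procedure on per-subject data.

    ``y`` holds each subject's whole-section average, ``sds`` the
    field-level SDs; ``scores_list`` (raw FOV scores per subject) is
    required for direct sampling.
    """
    config.validate()
    y = np.asarray(y, dtype=float)
    sds = np.asarray(sds, dtype=float)
    n = y.size
    if config.sampling_mode == "direct":
        if scores_list is None:
            raise ValidationError("direct sampling requires per-subject FOV scores")
        k_max = max(len(s) for s in scores_list)
        if config.m_range[1] > k_max:
            log.warning(
                "m_range upper bound %d exceeds every subject's field count (max K=%d); direct draws are capped",
                config.m_range[1], k_max,
            )
    if (sds < 0).any():
        raise ValidationError("subject SDs must be >= 0")
    if config.design == "kfold_mc" and n < 10:
        raise ValidationError(f"kfold_mc needs >= 10 subjects, got {n}")
    if config.design == "loo_boot" and n < 4:
        raise ValidationError(f"loo_boot needs >= 4 subjects, got {n}")

    streams = np.random.SeedSequence(config.seed).spawn(config.n_repeats)
    ms = config.ms
    per_m = np.empty(config.n_repeats, dtype=int)
    per_flm = np.empty(config.n_repeats)
    per_se = np.empty(config.n_repeats)
    per_score = np.empty(config.n_repeats)
    pe_mean_acc = np.zeros(ms.size)
    pe_se_acc = np.zeros(ms.size)
    for r, ss in enumerate(streams):
        m_sel, avg_flm, test_pe, se_at_min, score = _one_repeat(ss, config, y, sds, scores_list)
        per_m[r] = m_sel
        per_flm[r] = avg_flm
        per_se[r] = se_at_min
        per_score[r] = score
        pe_mean_acc += test_pe.mean(axis=0)
        pe_se_acc += test_pe.std(axis=0, ddof=1) / np.sqrt(test_pe.shape[0]) if test_pe.shape[0] > 1 else 0.0

    mean_m = float(per_m.mean())
    curve = PeCurve(m=ms, mean_pe=pe_mean_acc / config.n_repeats, se_pe=pe_se_acc / config.n_repeats, source="test")
    with np.errstate(invalid="ignore"):
        avg_score = float(np.nanmean(per_score)) if not np.isnan(per_score).all() else np.nan
    return SelectionResult(
        optimal_m=mean_m,
        optimal_m_int=int(np.floor(mean_m + 0.5)),
        optimal_m_sd=float(per_m.std(ddof=1)) if config.n_repeats > 1 else 0.0,
        per_repeat_m=per_m,
        test_pe_curve=curve,
        avg_abs_std_score=avg_score,
        avg_first_local_min=float(per_flm.mean()),
        se_outer_mean=float(per_se.mean()),
        config=config,
    )


def run_selection(table: FovScoreTable, config: SelectionConfig) -> SelectionResult:
    """Run the full two-layer procedure on a score table.

    All of a subject's FOVs are pooled (ROI structure is irrelevant to
    sampling); the whole-section average is the regression target in both
    sampling modes.
    """
    summaries = summarize_subjects(table)
    y = np.array([s.mean_score for s in summaries])
    sds = np.array([s.sd_score for s in summaries])
    scores_list = list(table.scores_by_subject().values()) if config.sampling_mode == "direct" else None
    return run_selection_from_summaries(y, sds, config, scores_list=scores_list)


@dataclass
class ModeComparison:
    """Side-by-side direct vs parametric selection results."""

    direct: SelectionResult
    parametric: SelectionResult
    subset_size: int
    n_excluded: int

    @property
    def difference(self) -> float:
        return self.parametric.optimal_m - self.direct.optimal_m

    @property
    def pooled_sd(self) -> float:
        return float(np.sqrt((self.direct.optimal_m_sd**2 + self.parametric.optimal_m_sd**2) / 2.0))


def validate_parametric_mode(table: FovScoreTable, subset_size: int, config: SelectionConfig) -> ModeComparison:
    """Check parametric sampling against direct sampling on one cohort.

    For each subject a random ``subset_size``-field subset is drawn; its
    mean and SD define the normal distribution the parametric run samples
    from, exactly as one would do for a cohort where only a few fields were
    measured.  The direct run uses the full table.  Subjects with fewer
    than ``subset_size`` fields are excluded from the parametric run (with
    a warning).
    """
    if subset_size < 2:
        raise ValidationError("subset_size must be >= 2 (an SD is needed)")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))

    by_subject = table.scores_by_subject()
    means, sds = [], []
    n_excluded = 0
    for subj, scores in by_subject.items():
        if len(scores) < subset_size:
            n_excluded += 1
            log.warning("subject %s has %d < %d fields; excluded from parametric validation", subj, len(scores), subset_size)
            continue
        sub = rng.choice(scores, size=subset_size, replace=False)
        means.append(sub.mean())
        sds.append(sub.std(ddof=1))

    from dataclasses import replace

    direct_cfg = replace(config, sampling_mode="direct")
    par_cfg = replace(config, sampling_mode="parametric")
    direct = run_selection(table, direct_cfg)
    parametric = run_selection_from_summaries(np.array(means), np.array(sds), par_cfg)
    return ModeComparison(direct=direct, parametric=parametric, subset_size=subset_size, n_excluded=n_excluded)
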