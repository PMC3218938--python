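"""Intra-tumor heterogeneity via a three-level mixed-effects model.

Each epitope's per-field scores are modeled as

    y_ijk = beta0 + b_i + b_ij + eps_ijk

for subject i, region of interest (ROI) j and field (FOV) k, with
``b_i ~ N(0, var_subject)``, ``b_ij ~ N(0, var_roi)`` and residual
``eps_ijk ~ N(0, var_resid)``.  Between-subject spread (``var_subject``)
reflects inter-tumor biology; the ROI and field components together are the
*intra*-tumor variation this module quantifies.

The headline statistic is the intra-tumor coefficient of variation

    CoV = 100 * sqrt(var_roi + var_resid) / beta0   [percent]

i.e. the within-tumor SD as a percentage of the mean expression level.
Between-subject variance is excluded by default (it measures how tumors
differ, not how heterogeneous a single tumor is); a flag includes it for
sensitivity analysis.

Residual spread can grow with expression level.  With
``heteroscedastic=True`` the residual SD is modeled as
``sqrt(var_resid) * (mu_ij / beta0) ** het_power`` with the power estimated
from the data — the standard power-of-the-mean variance function.  The
homoscedastic model is fit by REML through statsmodels' MixedLM; the
power-variance extension is a profiled REML implemented here (per-subject
block covariance, weights refreshed from the current conditional means).

Confidence intervals for the CoV come from a parametric bootstrap that
resimulates cohorts with the table's exact subject/ROI/field layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize
import statsmodels.formula.api as smf

from .data_model import FovScoreTable, subject_design
from .errors import FittingError, UnsupportedStructureError, ValidationError

__all__ = [
    "VarianceComponents",
    "CovEstimate",
    "fit_mixed_model",
    "compute_cov",
    "cov_confidence_interval",
    "nested_anova_components",
    "simulate_from_components",
]


@dataclass
class VarianceComponents:
    """Fitted intercept and variance components of the three-level model.

    ``var_resid`` is the field-level residual variance at the mean; when the
    power variance function was fit, ``het_power`` holds the estimated power
    (None for a homoscedastic fit).
    """

    beta0: float
    var_subject: float
    var_roi: float
    var_resid: float
    loglik: float
    n_obs: int
    het_power: float | None = None

    @property
    def sd_subject(self) -> float:
        return float(np.sqrt(self.var_subject))

    @property
    def sd_roi(self) -> float:
        return float(np.sqrt(self.var_roi))

    @property
    def sd_resid(self) -> float:
        return float(np.sqrt(self.var_resid))


@dataclass
class CovEstimate:
    """Intra-tumor CoV (percent) with a bootstrap confidence interval."""

    cov_percent: float
    ci_low: float
    ci_high: float
    n_boot: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.cov_percent + 1e-12 and self.cov_percent - 1e-12 <= self.ci_high):
            raise ValidationError("CI must bracket the point estimate")


def _require_roi_structure(table: FovScoreTable) -> None:
    if not table.has_roi:
        raise UnsupportedStructureError(
            "table has no ROI labels; the intra-tumor variance components cannot be separated "
            "(for such cohorts a coefficient of variation is not computable)"
        )
    if table.n_subjects < 2:
        raise UnsupportedStructureError("need at least 2 subjects to fit the mixed model")
    n_rois = table.df.groupby("subject_id")["roi_id"].nunique()
    if (n_rois < 2).all():
        raise UnsupportedStructureError("no subject has >= 2 ROIs; ROI variance is not identifiable")


def fit_mixed_model(table: FovScoreTable, heteroscedastic: bool = False) -> VarianceComponents:
    """REML fit of the three-level random-intercept model.

    Parameters
    ----------
    table
        Score table with ROI labels for every row.
    heteroscedastic
        Also estimate a power-of-the-mean residual variance function.

    Raises
    ------
    UnsupportedStructureError
        When ROI labels are absent or the design cannot identify the ROI
        component.
    FittingError
        On optimizer failure (message carries the diagnostics).
    """
    _require_roi_structure(table)
    if heteroscedastic:
        return _fit_power_reml(table)

    df = table.df
    # degenerate zero-variance tables break the optimizer; handle exactly
    if np.ptp(df["score"].to_numpy()) == 0.0:
        return VarianceComponents(
            beta0=float(df["score"].iloc[0]), var_subject=0.0, var_roi=0.0, var_resid=0.0,
            loglik=np.inf, n_obs=len(df),
        )

    model = smf.mixedlm(
        "score ~ 1",
        data=df,
        groups=df["subject_id"],
        re_formula="1",
        vc_formula={"roi": "0 + C(roi_id)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = None
        last_exc: Exception | None = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method, maxiter=500)
            except Exception as exc:  # noqa: BLE001 - surface via FittingError below
                last_exc = exc
                continue
            if cand.converged:
                res = cand
                break
            res = res or cand
    if res is None:
        raise FittingError(f"mixed-model fit failed: {last_exc}")
    if not res.converged:
        raise FittingError(f"mixed-model fit did not converge (methods tried: lbfgs/bfgs/powell); {res.summary()}")
    return VarianceComponents(
        beta0=float(res.fe_params.iloc[0]),
        var_subject=float(res.cov_re.iloc[0, 0]),
        var_roi=float(res.vcomp[0]),
        var_resid=float(res.scale),
        loglik=float(res.llf),
        n_obs=len(df),
    )


# ---------------------------------------------------------------------------
# power-variance REML
# ---------------------------------------------------------------------------


def _subject_blocks(table: FovScoreTable) -> list[tuple[np.ndarray, list[int]]]:
    """Per subject: (score vector, ROI sizes in row order)."""
    blocks = []
    for _, g in table.df.groupby("subject_id", sort=False):
        g = g.sort_values("roi_id", kind="stable")  # contiguous ROI blocks
        sizes = [int(n) for _, n in g.groupby("roi_id", sort=False).size().items()]
        blocks.append((g["score"].to_numpy(), sizes))
    return blocks


def _reml_loglik(theta, blocks, weights):
    """Profiled REML log-likelihood of the three-level model.

    theta = (log var_subject, log var_roi, log var_resid); ``weights`` gives
    each observation's residual SD multiplier (per subject, aligned with the
    score vector).
    """
    vs, vr, ve = np.exp(theta)
    xtvx = 0.0
    xtvy = 0.0
    pieces = []
    logdet = 0.0
    for (y, sizes), w in zip(blocks, weights):
        n = len(y)
        sigma = np.full((n, n), vs)
        pos = 0
        for sz in sizes:
            sigma[pos : pos + sz, pos : pos + sz] += vr
            pos += sz
        sigma[np.diag_indices(n)] += ve * w**2
        try:
            c, low = sla.cho_factor(sigma, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdet += 2.0 * np.sum(np.log(np.diag(c)))
        one = np.ones(n)
        si_y = sla.cho_solve((c, low), y, check_finite=False)
        si_1 = sla.cho_solve((c, low), one, check_finite=False)
        xtvx += one @ si_1
        xtvy += one @ si_y
        pieces.append((y, si_y, si_1))
    beta = xtvy / xtvx
    quad = 0.0
    for y, si_y, si_1 in pieces:
        quad += y @ si_y - 2 * beta * (y @ si_1) + beta**2 * np.sum(si_1 * np.ones(len(si_1)))
    n_tot = sum(len(y) for y, _ in blocks)
    ll = -0.5 * (logdet + np.log(xtvx) + quad + (n_tot - 1) * np.log(2 * np.pi))
    return ll, beta


def _blups(theta, beta, blocks, weights):
    """Conditional ROI-level means mu_ij = beta0 + b_i + b_ij per subject."""
    vs, vr, ve = np.exp(theta)
    mus = []
    for (y, sizes), w in zip(blocks, weights):
        n = len(y)
        sigma = np.full((n, n), vs)
        pos = 0
        for sz in sizes:
            sigma[pos : pos + sz, pos : pos + sz] += vr
            pos += sz
        sigma[np.diag_indices(n)] += ve * w**2
        r = y - beta
        si_r = sla.solve(sigma, r, assume_a="pos", check_finite=False)
        b_i = vs * np.sum(si_r)
        mu = np.empty(len(sizes))
        pos = 0
        for j, sz in enumerate(sizes):
            b_ij = vr * np.sum(si_r[pos : pos + sz])
            mu[j] = beta + b_i + b_ij
            pos += sz
        mus.append(mu)
    return mus


def _fit_power_reml(table: FovScoreTable, n_outer: int = 4) -> VarianceComponents:
    """REML with residual SD proportional to (conditional ROI mean / beta0)^delta.

    Alternates (a) REML maximization over the three variance components and
    the power delta, holding the ROI-level conditional means that enter the
    weights fixed, with (b) refreshing those means from the current BLUPs —
    the same alternation generalized-least-squares mixed-model software uses
    for variance functions of the fitted mean.
    """
    blocks = _subject_blocks(table)
    y_all = np.concatenate([y for y, _ in blocks])
    if np.ptp(y_all) == 0.0:
        return VarianceComponents(float(y_all[0]), 0.0, 0.0, 0.0, np.inf, len(y_all), het_power=0.0)

    # initialize from the homoscedastic fit
    base = fit_mixed_model(table, heteroscedastic=False)
    floor = max(1e-8 * np.var(y_all), 1e-12)
    theta0 = np.log(np.maximum([base.var_subject, base.var_roi, base.var_resid], floor))
    beta = base.beta0
    # ROI observed means seed the weights
    mus = []
    for y, sizes in blocks:
        pos, mu = 0, []
        for sz in sizes:
            mu.append(np.mean(y[pos : pos + sz]))
            pos += sz
        mus.append(np.array(mu))
    delta = 0.5
    result = None

    for _ in range(n_outer):
        mu_floor = 0.05 * abs(beta) if beta != 0 else 1e-6

        def weights_for(delta_):
            return [
                np.repeat(np.maximum(mu, mu_floor) / abs(beta), sizes) ** delta_
                for mu, (_, sizes) in zip(mus, blocks)
            ]

        def neg(params):
            ll = _reml_loglik(params[:3], blocks, weights_for(params[3]))
            if ll is None:
                return 1e12
            return -ll[0]

        x0 = np.concatenate([theta0, [delta]])
        opt = scipy.optimize.minimize(neg, x0, method="Nelder-Mead", options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
        if not opt.success and opt.fun >= 1e11:
            raise FittingError(f"power-variance REML failed: {opt.message}")
        theta0, delta = opt.x[:3], float(opt.x[3])
        out = _reml_loglik(theta0, blocks, weights_for(delta))
        if out is None:
            raise FittingError("power-variance REML produced a non-PD covariance at the optimum")
        ll, beta = out
        mus = _blups(theta0, beta, blocks, weights_for(delta))
        result = (theta0, delta, ll, beta)

    theta0, delta, ll, beta = result
    vs, vr, ve = np.exp(theta0)
    return VarianceComponents(
        beta0=float(beta), var_subject=float(vs), var_roi=float(vr), var_resid=float(ve),
        loglik=float(ll), n_obs=len(y_all), het_power=delta,
    )


# ---------------------------------------------------------------------------
# CoV and its confidence interval
# ---------------------------------------------------------------------------


def compute_cov(vc: VarianceComponents, include_subject: bool = False) -> float:
    """Intra-tumor coefficient of variation, in percent.

    ``100 * sqrt(var_roi + var_resid) / beta0`` — within-tumor components
    only.  ``include_subject=True`` adds the between-subject variance to the
    numerator (sensitivity analysis; this measures total, not intra-tumor,
    variation).
    """
    if vc.beta0 <= 0:
        raise ValidationError(f"CoV requires a positive mean score; got beta0={vc.beta0}")
    num = vc.var_roi + vc.var_resid + (vc.var_subject if include_subject else 0.0)
    return 100.0 * float(np.sqrt(num)) / vc.beta0


def simulate_from_components(
    vc: VarianceComponents,
    design: list[tuple[str, list[int]]],
    rng: np.random.Generator,
) -> FovScoreTable:
    """Simulate one cohort from fitted components on an exact design.

    ``design`` is per-subject ROI sizes as returned by
    :func:`fovsample.data_model.subject_design`; the heteroscedastic power is
    honored when present.
    """
    rows = {"subject_id": [], "roi_id": [], "fov_id": [], "score": []}
    delta = vc.het_power or 0.0
    for subj, sizes in design:
        b_i = rng.normal(0.0, np.sqrt(vc.var_subject))
        for j, sz in enumerate(sizes):
            b_ij = rng.normal(0.0, np.sqrt(vc.var_roi))
            mu = vc.beta0 + b_i + b_ij
            scale = np.sqrt(vc.var_resid) * (max(mu, 1e-12) / vc.beta0) ** delta if delta else np.sqrt(vc.var_resid)
            y = np.maximum(mu + rng.normal(0.0, 1.0, size=sz) * scale, 0.0)
            rows["subject_id"].extend([subj] * sz)
            rows["roi_id"].extend([f"R{j + 1}"] * sz)
            rows["fov_id"].extend(f"F{j + 1}.{k + 1}" for k in range(sz))
            rows["score"].extend(y.tolist())
    return FovScoreTable.from_frame(pd.DataFrame(rows))


def nested_anova_components(table: FovScoreTable) -> VarianceComponents:
    """Method-of-moments variance components from the balanced nested ANOVA.

    Requires a balanced design (equal ROIs per subject, equal fields per
    ROI); on balanced data these closed-form estimators coincide with REML
    whenever the mean squares are ordered so no component truncates at zero.
    Fast enough to serve as the refit engine inside bootstrap loops.
    """
    _require_roi_structure(table)
    df = table.df
    sizes = df.groupby(["subject_id", "roi_id"]).size()
    rois = df.groupby("subject_id")["roi_id"].nunique()
    if sizes.nunique() != 1 or rois.nunique() != 1:
        raise UnsupportedStructureError("moment estimator requires a balanced design")
    a = int(rois.index.size)
    b = int(rois.iloc[0])
    n = int(sizes.iloc[0])
    if b < 2 or n < 2:
        raise UnsupportedStructureError("balanced moment estimator needs >= 2 ROIs/subject and >= 2 FOVs/ROI")

    grand = df["score"].mean()
    subj_means = df.groupby("subject_id")["score"].mean()
    roi_means = df.groupby(["subject_id", "roi_id"])["score"].mean()

    ms_subj = b * n * np.sum((subj_means - grand) ** 2) / (a - 1)
    ms_roi = n * np.sum((roi_means - roi_means.index.get_level_values(0).map(subj_means)) ** 2) / (a * (b - 1))
    resid = df["score"] - df.set_index(["subject_id", "roi_id"]).index.map(roi_means)
    ms_err = np.sum(resid**2) / (a * b * (n - 1))

    var_e = float(ms_err)
    var_r = float(max((ms_roi - ms_err) / n, 0.0))
    var_s = float(max((ms_subj - ms_roi) / (b * n), 0.0))
    return VarianceComponents(float(grand), var_s, var_r, var_e, loglik=np.nan, n_obs=len(df))


def cov_confidence_interval(
    table: FovScoreTable,
    vc: VarianceComponents,
    n_boot: int = 200,
    seed: int = 0,
    refit: str = "reml",
    include_subject: bool = False,
) -> CovEstimate:
    """Parametric-bootstrap 95% CI for the intra-tumor CoV.

    Simulates ``n_boot`` cohorts from the fitted components with the table's
    exact subject/ROI/field layout, refits each, and takes the 2.5/97.5
    percentiles of the refitted CoVs.  ``refit`` selects the engine:
    ``"reml"`` (the full mixed-model fit) or ``"anova"`` (balanced
    method-of-moments; much faster, balanced designs only).

    Raises
    ------
    FittingError
        When more than 10% of the bootstrap refits fail.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100 for percentile intervals")
    if refit not in ("reml", "anova"):
        raise ValidationError(f"unknown refit engine {refit!r}")
    design = subject_design(table)
    point = compute_cov(vc, include_subject=include_subject)
    rng = np.random.default_rng(seed)

    covs = []
    n_fail = 0
    for _ in range(n_boot):
        sim = simulate_from_components(vc, design, rng)
        if np.ptp(sim.df["score"].to_numpy()) == 0.0:
            covs.append(0.0)
            continue
        try:
            if refit == "anova":
                fit = nested_anova_components(sim)
            else:
                fit = fit_mixed_model(sim, heteroscedastic=vc.het_power is not None and vc.het_power != 0.0)
            covs.append(compute_cov(fit, include_subject=include_subject))
        except (FittingError, UnsupportedStructureError, ValidationError):
            n_fail += 1
    if n_fail > 0.1 * n_boot:
        raise FittingError(f"{n_fail}/{n_boot} bootstrap refits failed")
    lo, hi = np.percentile(covs, [2.5, 97.5])
    lo = min(float(lo), point)
    hi = max(float(hi), point)
    return CovEstimate(cov_percent=point, ci_low=lo, ci_high=hi, n_boot=n_boot)
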