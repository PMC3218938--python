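"""Synthetic cohorts with a hierarchical (subject / ROI / field) variance structure.

The generator simulates the three-level random-intercept model forward:

    y_ijk = beta0 + b_i + b_ij + eps_ijk

with ``b_i ~ N(0, sigma_subject^2)`` (between-tumor shift),
``b_ij ~ N(0, sigma_roi^2)`` (region-of-interest shift within a tumor) and
``eps_ijk`` the field-level residual.  Optionally the residual SD grows as a
power of the local mean, ``sigma_resid * (mu_ij / beta0)**het_power`` with
``mu_ij = beta0 + b_i + b_ij`` — the standard power-of-the-mean variance
function for scores whose spread scales with expression level.

Scores are truncated at zero (fluorescence scores are nonnegative); the
fraction of truncated draws is reported in the table's ``meta`` so callers
can verify it is negligible for their parameter choice.

It also fabricates matched index-array runs (a control array re-stained in
every run) whose non-baseline runs are a known monotone distortion of the
baseline plus noise, for exercising the between-run normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import FovScoreTable, IndexArraySet
from .errors import ValidationError

__all__ = ["CohortSpec", "generate_cohort", "generate_index_arrays", "MonotoneDistortion"]


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    Parameters
    ----------
    n_subjects
        Number of tumors (subjects).
    rois_per_subject
        ROIs circled per subject; an int, or a per-subject sequence.
    fovs_per_roi
        Fields per ROI; an int, or a callable ``f(rng) -> int`` drawn per ROI.
    beta0
        Grand-mean intercept, in score units.
    sigma_subject, sigma_roi, sigma_resid
        SDs of the subject intercept, ROI-within-subject intercept, and the
        field-level residual (at the mean, when heteroscedastic).
    het_power
        Residual SD is multiplied by ``(mu_ij / beta0) ** het_power``;
        0 gives a homoscedastic cohort.
    seed
        Seed for the single generator that drives all draws.
    """

    n_subjects: int
    rois_per_subject: int | Sequence[int] = 3
    fovs_per_roi: int | Callable[[np.random.Generator], int] = 20
    beta0: float = 50.0
    sigma_subject: float = 10.0
    sigma_roi: float = 3.0
    sigma_resid: float = 5.0
    het_power: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        for name in ("sigma_subject", "sigma_roi", "sigma_resid", "het_power"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.het_power > 0 and self.beta0 <= 0:
            raise ValidationError("beta0 must be > 0 when het_power > 0 (power law needs a positive scale)")
        if isinstance(self.rois_per_subject, int):
            if self.rois_per_subject < 1:
                raise ValidationError("rois_per_subject must be >= 1")
        else:
            if len(self.rois_per_subject) != self.n_subjects:
                raise ValidationError("per-subject ROI list must have n_subjects entries")
            if any(r < 1 for r in self.rois_per_subject):
                raise ValidationError("rois_per_subject entries must be >= 1")
        if isinstance(self.fovs_per_roi, int) and self.fovs_per_roi < 1:
            raise ValidationError("fovs_per_roi must be >= 1")


def generate_cohort(spec: CohortSpec) -> FovScoreTable:
    """Simulate a cohort forward from the three-level model.

    Draw order is fixed — subjects, then each subject's ROIs, then each
    ROI's fields — so a given seed reproduces the identical table.

    Returns a validated :class:`FovScoreTable`; ``meta['truncation_fraction']``
    is the fraction of scores clipped at zero and ``meta['spec']`` echoes the
    generating parameters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if isinstance(spec.rois_per_subject, int):
        n_rois = [spec.rois_per_subject] * spec.n_subjects
    else:
        n_rois = [int(r) for r in spec.rois_per_subject]

    rows_subject: list[str] = []
    rows_roi: list[str] = []
    rows_fov: list[str] = []
    scores: list[np.ndarray] = []
    n_total = 0
    n_truncated = 0

    for i in range(spec.n_subjects):
        b_i = rng.normal(0.0, spec.sigma_subject)
        subj = f"S{i + 1:03d}"
        for j in range(n_rois[i]):
            b_ij = rng.normal(0.0, spec.sigma_roi)
            mu_ij = spec.beta0 + b_i + b_ij
            if callable(spec.fovs_per_roi):
                k = int(spec.fovs_per_roi(rng))
                if k < 1:
                    raise ValidationError("fovs_per_roi sampler returned a count < 1")
            else:
                k = spec.fovs_per_roi
            if spec.het_power > 0:
                # mu can stray nonpositive in extreme tails; a floor keeps the
                # variance function defined (such cohorts are flagged by the
                # truncation fraction anyway)
                scale = spec.sigma_resid * (max(mu_ij, 1e-12) / spec.beta0) ** spec.het_power
            else:
                scale = spec.sigma_resid
            y = mu_ij + rng.normal(0.0, 1.0, size=k) * scale
            n_truncated += int((y < 0).sum())
            n_total += k
            scores.append(np.maximum(y, 0.0))
            rows_subject.extend([subj] * k)
            rows_roi.extend([f"R{j + 1}"] * k)
            rows_fov.extend(f"F{j + 1}.{kk + 1}" for kk in range(k))

    df = pd.DataFrame(
        {
            "subject_id": rows_subject,
            "roi_id": rows_roi,
            "fov_id": rows_fov,
            "score": np.concatenate(scores),
        }
    )
    meta = {
        "truncation_fraction": n_truncated / n_total,
        "spec": spec,
    }
    return FovScoreTable.from_frame(df, meta=meta)


@dataclass
class MonotoneDistortion:
    """Strictly increasing map  x -> offset + gain * (x/scale)**power * scale.

    With ``power=1`` this is affine; ``power != 1`` adds a smooth warp of the
    kind seen between staining runs (bulb aging, reagent lots).  ``scale``
    sets the pivot of the power warp so typical score magnitudes stay
    comparable.
    """

    gain: float = 1.0
    offset: float = 0.0
    power: float = 1.0
    scale: float = 1.0

    def validate(self) -> None:
        if self.gain <= 0 or self.power <= 0 or self.scale <= 0:
            raise ValidationError("distortion must be strictly increasing: gain, power and scale must be > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.offset + self.gain * self.scale * (x / self.scale) ** self.power


def generate_index_arrays(
    n_cores: int,
    n_runs: int,
    distortion: MonotoneDistortion | Sequence[MonotoneDistortion] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    latent_low: float = 5.0,
    latent_high: float = 100.0,
) -> IndexArraySet:
    """Matched index-array runs on a shared control-core set.

    The baseline run holds the latent core scores (uniform on
    ``[latent_low, latent_high]``); every other run is
    ``distortion(latent) + N(0, noise_sd^2)``.  One distortion may be given
    for all runs or one per non-baseline run.
    """
    if n_cores < 4:
        raise ValidationError("n_cores must be >= 4")
    if n_runs < 2:
        raise ValidationError("n_runs must be >= 2")
    if distortion is None:
        distortion = MonotoneDistortion()
    if isinstance(distortion, MonotoneDistortion):
        distortions = [distortion] * (n_runs - 1)
    else:
        distortions = list(distortion)
        if len(distortions) != n_runs - 1:
            raise ValidationError("need one distortion per non-baseline run")
    for d in distortions:
        d.validate()

    rng = np.random.default_rng(seed)
    latent = np.sort(rng.uniform(latent_low, latent_high, size=n_cores))
    cols = {"run1": latent}
    for r, d in enumerate(distortions, start=2):
        cols[f"run{r}"] = d(latent) + rng.normal(0.0, noise_sd, size=n_cores)
    core_ids = [f"C{i + 1:03d}" for i in range(n_cores)]
    scores = pd.DataFrame(cols, index=pd.Index(core_ids, name="core_id"))
    return IndexArraySet(core_ids, scores, baseline_run="run1")
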