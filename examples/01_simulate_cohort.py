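"""Simulate a cohort with subject / ROI / field variance structure.

Each subject's per-field scores follow
y_ijk = beta0 + b_i + b_ij + eps_ijk: a tumor-level shift, a
region-of-interest shift within the tumor, and field-level noise.
"""

import numpy as np

from fovsample import CohortSpec, generate_cohort, summarize_subjects

spec = CohortSpec(
    n_subjects=20,
    rois_per_subject=3,
    fovs_per_roi=15,
    beta0=50.0,        # grand-mean score (arbitrary fluorescence units)
    sigma_subject=10.0,  # between-tumor SD
    sigma_roi=3.0,       # between-ROI SD within a tumor
    sigma_resid=5.0,     # field-level SD
    seed=42,
)
table = generate_cohort(spec)
summaries = summarize_subjects(table)

print(f"cohort: {table.n_subjects} subjects, {table.n_records} field scores")
print(f"truncated at zero: {table.meta['truncation_fraction']:.2%}")
means = np.array([s.mean_score for s in summaries])
sds = np.array([s.sd_score for s in summaries])
print(f"whole-section means: {means.mean():.1f} +- {means.std(ddof=1):.1f} (target grand mean {spec.beta0})")
print(f"within-subject field SD: {sds.mean():.1f} (target ~ sqrt({spec.sigma_roi}^2 + {spec.sigma_resid}^2) = "
      f"{np.hypot(spec.sigma_roi, spec.sigma_resid):.1f})")
# The spread of whole-section means reflects between-tumor biology; the
# within-subject SD is the intra-tumor heterogeneity later stages quantify.
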