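"""Select the optimal number of 20X fields for a representative score.

Runs the two-layer resampling procedure: inner Monte-Carlo splits pick the
first local minimum of the prediction-error curve per training set; outer
cross-validation estimates test-set prediction error, and the
one-standard-error rule picks the smallest competitive field count.
"""

from fovsample import CohortSpec, SelectionConfig, generate_cohort, run_selection

spec = CohortSpec(
    n_subjects=30, rois_per_subject=2, fovs_per_roi=25,
    beta0=50.0, sigma_subject=10.0, sigma_roi=7.0, sigma_resid=7.0, seed=12,
)
table = generate_cohort(spec)
config = SelectionConfig(design="kfold_mc", sampling_mode="direct",
                         n_inner=200, n_repeats=10, seed=12)
res = run_selection(table, config)

print(f"optimal number of fields: {res.optimal_m_int}  (mean {res.optimal_m:.1f} over {config.n_repeats} repeats)")
print(f"SD over repeats: {res.optimal_m_sd:.1f}   across-fold SE of test PE at the minimum: {res.se_outer_mean:.2f}")
print(f"avg first local minimum of inner PE curves: {res.avg_first_local_min:.1f}")
print(f"average absolute standardized score at the selected m: {res.avg_abs_std_score:.2f} subject-SDs")
print("test PE at m=1,5,10,20:",
      "  ".join(f"{res.test_pe_curve.mean_pe[m-1]:.2f}" for m in (1, 5, 10, 20)))
# A standardized score well below 1 means the m-field average predicts the
# whole-section score to within a fraction of the subject's own field SD.
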