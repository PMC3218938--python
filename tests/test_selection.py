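import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fovsample as fs
from fovsample import (
    CohortSpec,
    SelectionConfig,
    avg_abs_standardized_score,
    first_local_minimum,
    fit_learning_regression,
    generate_cohort,
    one_se_select,
    prediction_error,
    run_selection,
    sample_fov_mean,
    summarize_subjects,
    validate_parametric_mode,
)
from fovsample.errors import FittingError, ValidationError
from fovsample.selection import _one_repeat


class TestFirstLocalMinimum:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            ([5, 4, 3, 3.5, 2], 3),   # interior dip wins over later global min
            ([5, 4, 3, 2, 1], 5),     # monotone decreasing -> global min
            ([2, 2, 2], 1),           # flat -> smallest m
            ([1, 2, 3], 1),           # increasing -> first point
            ([3, 1, 1, 0.5], 4),      # plateau then drop -> no interior min
            ([7], 1),                 # single point
        ],
    )
    def test_hand_cases(self, curve, expected):
        assert first_local_minimum(curve) == expected

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_returns_valid_m_and_definition_holds(self, curve):
        m = first_local_minimum(curve)
        assert 1 <= m <= len(curve)
        i = m - 1
        if i < len(curve) - 1 and curve[i] < curve[i + 1] and (i == 0 or curve[i] <= curve[i - 1]):
            pass  # genuine interior local minimum
        else:
            assert curve[i] == min(curve)  # fallback: global minimum


class TestOneSeSelect:
    @pytest.mark.parametrize(
        "curve,min_m,se,expected",
        [
            ([10, 6, 5, 5.3], 3, 0.4, 3),
            ([10, 6, 5, 5.3], 3, 1.2, 2),
            ([10, 6, 5, 5.3], 3, 0.0, 3),
            ([5, 5, 5], 3, 0.0, 1),  # exact ties at smaller m win
        ],
    )
    def test_hand_cases(self, curve, min_m, se, expected):
        assert one_se_select(curve, min_m, se) == expected

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=15),
        st.floats(0, 50, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_exceeds_minimum_model(self, curve, se):
        min_m = first_local_minimum(curve)
        assert one_se_select(curve, min_m, se) <= min_m


class TestSampleFovMean:
    def test_direct_full_sample_is_exact_mean(self, rng):
        scores = np.array([2.0, 4.0, 9.0])
        assert sample_fov_mean(scores, 3, "direct", rng) == pytest.approx(5.0)
        # m beyond K caps at the full mean
        assert sample_fov_mean(scores, 10, "direct", rng) == pytest.approx(5.0)

    def test_parametric_zero_sd_is_exact_mean(self, rng):
        s = fs.SubjectSummary("A", 5, 7.0, 0.0)
        assert sample_fov_mean(s, 4, "parametric", rng) == 7.0

    def test_direct_m1_unbiased(self, rng):
        draws = [sample_fov_mean(np.array([2.0, 4.0]), 1, "direct", rng) for _ in range(10_000)]
        # mean of a fair pick from {2,4}: SE = 1/sqrt(n)
        assert np.mean(draws) == pytest.approx(3.0, abs=3 / np.sqrt(10_000))


class TestRegressionAndPe:
    def test_exact_line(self):
        assert fit_learning_regression([(1, 2), (2, 4), (3, 6)]) == pytest.approx((0.0, 2.0))

    def test_identity_pairs_give_unit_slope(self):
        pairs = [(x, x) for x in (1.0, 2.0, 5.0, 9.0)]
        intercept, slope = fit_learning_regression(pairs)
        assert (intercept, slope) == pytest.approx((0.0, 1.0))
        assert prediction_error((intercept, slope), pairs) == pytest.approx(0.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(FittingError):
            fit_learning_regression([(2, 1), (2, 2), (2, 3)])

    def test_pe_hand_case(self):
        assert prediction_error((0.0, 1.0), [(2, 3), (4, 3)]) == pytest.approx(1.0)

    def test_pe_matches_independent_oracle(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        a, b = 0.7, 1.3
        oracle = float(np.sum((a + b * x - y) ** 2) / 100)
        assert prediction_error((a, b), list(zip(x, y))) == pytest.approx(oracle, abs=1e-12)

    def test_attenuation_vanishes_for_large_m(self, rng):
        # x is the subject mean plus shrinking sampling noise: slope -> 1
        truth = rng.normal(50, 10, size=50)
        x = truth + rng.normal(0, 8 / np.sqrt(50), size=50)
        _, slope = fit_learning_regression(list(zip(x, truth)))
        assert 0.8 <= slope <= 1.2


class TestAvgAbsStandardizedScore:
    def test_hand_case(self):
        assert avg_abs_standardized_score([5.0], [4.0], [2.0]) == pytest.approx(0.5)

    def test_perfect_predictions(self):
        assert avg_abs_standardized_score([1, 2], [1, 2], [3, 4]) == 0.0

    def test_zero_sd_subjects_excluded(self):
        assert avg_abs_standardized_score([5, 9], [4, 1], [2, 0]) == pytest.approx(0.5)

    def test_all_zero_sds_rejected(self):
        with pytest.raises(ValidationError):
            avg_abs_standardized_score([1], [2], [0.0])


class TestRunSelection:
    @pytest.mark.parametrize("design", ["kfold_mc", "loo_boot"])
    @pytest.mark.parametrize("mode", ["direct", "parametric"])
    def test_zero_variance_cohort_selects_one_field(self, zero_variance_cohort, design, mode):
        cfg = SelectionConfig(design=design, sampling_mode=mode, n_inner=100, n_repeats=5, seed=7)
        res = run_selection(zero_variance_cohort, cfg)
        assert res.optimal_m == 1.0
        assert res.optimal_m_sd == 0.0
        assert np.all(res.test_pe_curve.mean_pe == 0.0)

    def test_deterministic_given_seed(self):
        spec = CohortSpec(n_subjects=15, rois_per_subject=1, fovs_per_roi=12, beta0=50,
                          sigma_subject=8, sigma_roi=0, sigma_resid=6, seed=4)
        t = generate_cohort(spec)
        cfg = SelectionConfig(m_range=(1, 10), n_inner=80, n_repeats=4, seed=12)
        a = run_selection(t, cfg)
        b = run_selection(t, cfg)
        assert np.array_equal(a.per_repeat_m, b.per_repeat_m)
        np.testing.assert_array_equal(a.test_pe_curve.mean_pe, b.test_pe_curve.mean_pe)
        assert a.avg_abs_std_score == b.avg_abs_std_score

    def test_one_se_never_exceeds_first_local_min(self):
        spec = CohortSpec(n_subjects=16, rois_per_subject=1, fovs_per_roi=12, beta0=50,
                          sigma_subject=8, sigma_roi=0, sigma_resid=6, seed=41)
        t = generate_cohort(spec)
        cfg = SelectionConfig(m_range=(1, 10), n_inner=60, n_repeats=6, seed=3)
        res = run_selection(t, cfg)
        # selected m is bounded by the rounded average first local minimum
        assert res.per_repeat_m.max() <= np.ceil(res.avg_first_local_min + 0.5)

    def test_too_few_subjects_rejected(self):
        spec = CohortSpec(n_subjects=5, rois_per_subject=1, fovs_per_roi=8, seed=2)
        t = generate_cohort(spec)
        with pytest.raises(ValidationError):
            run_selection(t, SelectionConfig(design="kfold_mc", n_repeats=1, seed=0))

    def test_engine_agrees_with_naive_implementation(self):
        """The vectorized engine vs a plain-loop rendition built from the
        scalar operations; agreement is statistical (different RNG streams)."""
        spec = CohortSpec(n_subjects=12, rois_per_subject=1, fovs_per_roi=10, beta0=50,
                          sigma_subject=10, sigma_roi=0, sigma_resid=8, seed=21)
        t = generate_cohort(spec)
        cfg = SelectionConfig(m_range=(1, 8), n_inner=60, n_outer_folds=4, n_repeats=25, seed=99)
        res = run_selection(t, cfg)

        summ = summarize_subjects(t)
        y = np.array([s.mean_score for s in summ])
        scores_list = list(t.scores_by_subject().values())
        rng = np.random.default_rng(1234)
        naive_m = [self._naive_repeat(rng, cfg, y, scores_list) for _ in range(25)]
        # means differ by Monte-Carlo noise only: SE of each ~ sd/sqrt(25)
        pooled_se = np.sqrt((res.optimal_m_sd**2 + np.std(naive_m, ddof=1) ** 2) / 25)
        assert abs(res.optimal_m - np.mean(naive_m)) <= max(4 * pooled_se, 1.5)

    @staticmethod
    def _naive_repeat(rng, cfg, y, scores_list):
        ms = cfg.ms
        n = len(y)
        folds = np.array_split(rng.permutation(n), cfg.n_outer_folds)
        flms, test_pe = [], np.zeros((len(folds), ms.size))

        def draw_pairs(idx, m):
            return [(sample_fov_mean(scores_list[i], m, "direct", rng), y[i]) for i in idx]

        def fit(pairs):
            try:
                return fit_learning_regression(pairs)
            except FittingError:
                return (float(np.mean([b for _, b in pairs])), 0.0)

        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            n_eval = max(1, round(cfg.inner_eval_fraction * len(train_idx)))
            pe_acc = np.zeros(ms.size)
            for _ in range(cfg.n_inner):
                p = rng.permutation(train_idx)
                learn, ev = p[:-n_eval], p[-n_eval:]
                for jm, m in enumerate(ms):
                    pe_acc[jm] += prediction_error(fit(draw_pairs(learn, m)), draw_pairs(ev, m))
            flms.append(first_local_minimum(pe_acc / cfg.n_inner, ms))
            for jm, m in enumerate(ms):
                test_pe[f, jm] = prediction_error(fit(draw_pairs(train_idx, m)), draw_pairs(test_idx, m))
        avg_flm = float(np.mean(flms))
        min_m = int(np.clip(np.floor(avg_flm + 0.5), ms[0], ms[-1]))
        idx = int(np.nonzero(ms == min_m)[0][0])
        se = test_pe[:, idx].std(ddof=1) / np.sqrt(len(folds))
        return one_se_select(test_pe.mean(axis=0), min_m, se, ms)

    def test_parametric_test_pe_nearly_monotone(self):
        """With ample inner iterations the expected test PE decreases in m;
        the fitted curve should be close to its isotonic (decreasing) fit."""
        from sklearn.isotonic import IsotonicRegression

        spec = CohortSpec(n_subjects=200, rois_per_subject=1, fovs_per_roi=20, beta0=50,
                          sigma_subject=10, sigma_roi=0, sigma_resid=10, seed=8)
        t = generate_cohort(spec)
        cfg = SelectionConfig(sampling_mode="parametric", n_inner=300, n_repeats=4, seed=77)
        res = run_selection(t, cfg)
        pe = res.test_pe_curve.mean_pe
        iso = IsotonicRegression(increasing=False).fit_transform(res.test_pe_curve.m, pe)
        assert np.linalg.norm(pe - iso) <= 0.1 * np.linalg.norm(pe)

    def test_reduced_iterations_stay_within_two_sd(self):
        spec = CohortSpec(n_subjects=20, rois_per_subject=1, fovs_per_roi=12, beta0=50,
                          sigma_subject=10, sigma_roi=0, sigma_resid=8, seed=63)
        t = generate_cohort(spec)
        full = run_selection(t, SelectionConfig(m_range=(1, 10), n_inner=800, n_repeats=24, seed=5))
        reduced = run_selection(t, SelectionConfig(m_range=(1, 10), n_inner=200, n_repeats=8, seed=6))
        assert abs(reduced.optimal_m - full.optimal_m) <= 2 * max(full.optimal_m_sd, 0.5)


class TestValidateParametricMode:
    def test_zero_variance_both_modes_select_one(self, zero_variance_cohort):
        cfg = SelectionConfig(design="loo_boot", n_inner=60, n_repeats=3, seed=9)
        cmp_ = validate_parametric_mode(zero_variance_cohort, subset_size=8, config=cfg)
        assert cmp_.direct.optimal_m == 1.0
        assert cmp_.parametric.optimal_m == 1.0

    def test_fixed_seed_identical_report(self):
        spec = CohortSpec(n_subjects=14, rois_per_subject=1, fovs_per_roi=15, beta0=50,
                          sigma_subject=8, sigma_roi=0, sigma_resid=6, seed=44)
        t = generate_cohort(spec)
        cfg = SelectionConfig(design="loo_boot", m_range=(1, 8), n_inner=60, n_repeats=3, seed=2)
        a = validate_parametric_mode(t, subset_size=10, config=cfg)
        b = validate_parametric_mode(t, subset_size=10, config=cfg)
        assert a.direct.optimal_m == b.direct.optimal_m
        assert a.parametric.optimal_m == b.parametric.optimal_m
        assert a.difference == b.difference

    def test_short_subjects_excluded_with_count(self):
        spec = CohortSpec(n_subjects=12, rois_per_subject=1,
                          fovs_per_roi=10, beta0=50, sigma_subject=8, sigma_roi=0,
                          sigma_resid=6, seed=3)
        t = generate_cohort(spec)
        # shrink two subjects below the subset size
        df = t.df[~((t.df.subject_id == "S001") & (t.df.fov_id > "F1.4")) &
                  ~((t.df.subject_id == "S002") & (t.df.fov_id > "F1.4"))]
        t2 = fs.FovScoreTable.from_frame(df)
        cfg = SelectionConfig(design="loo_boot", m_range=(1, 6), n_inner=40, n_repeats=2, seed=2)
        cmp_ = validate_parametric_mode(t2, subset_size=8, config=cfg)
        assert cmp_.n_excluded == 2


def test_config_validation_errors():
    with pytest.raises(ValidationError):
        SelectionConfig(design="bogus").validate()
    with pytest.raises(ValidationError):
        SelectionConfig(m_range=(0, 5)).validate()
    with pytest.raises(ValidationError):
        SelectionConfig(inner_eval_fraction=1.5).validate()
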