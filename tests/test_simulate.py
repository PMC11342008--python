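import numpy as np
import pytest
from scipy.special import expit

import trajlens as tl
from trajlens.simulate import (
    GenerativeSpec,
    HIGH_RISK_PARAMS,
    LOW_RISK_PARAMS,
    MARKER_ODDS_RATIOS,
    STUDY_MIXING,
    simulate_marker_table,
)
from trajlens.zip_model import GroupParams, expected_counts, group_rates


def _single_group_spec(beta, alpha, n=10000, seed=0, **kw):
    return GenerativeSpec(
        n_users=n,
        mixing=(1.0,),
        group_params=(GroupParams(beta=beta, alpha=alpha),),
        time_codes=tl.default_grid().time_codes,
        seed=seed,
        **kw,
    )


class TestSimulateCounts:
    def test_pure_poisson_limit(self):
        # pi forced ~0 via large negative inflation intercept
        spec = _single_group_spec(beta=(np.log(2.0),), alpha=(-30.0,))
        cohort = tl.simulate_counts(spec)
        mean = cohort.counts.mean(axis=0)
        se = np.sqrt(2.0 / spec.n_users)
        assert np.all(np.abs(mean - 2.0) < 3 * se + 1e-9)

    def test_degenerate_inflation_all_zero(self):
        spec = _single_group_spec(beta=(1.0,), alpha=(30.0,), n=500)
        cohort = tl.simulate_counts(spec)
        assert cohort.counts.sum() == 0
        assert cohort.series == []  # eligibility filters everyone downstream

    def test_high_group_expected_count_dominates_everywhere(self):
        codes = tl.default_grid().time_codes
        high = expected_counts(HIGH_RISK_PARAMS, codes)
        low = expected_counts(LOW_RISK_PARAMS, codes)
        assert np.all(high > low)

    def test_seed_determinism_byte_identical(self):
        spec = tl.study_generative_spec(n_users=300, seed=5)
        a = tl.simulate_study_cohort(spec)
        b = tl.simulate_study_cohort(spec)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.true_groups, b.true_groups)
        c = tl.simulate_study_cohort(spec, seed=6)
        assert not np.array_equal(a.counts, c.counts)

    def test_group_shares_within_binomial_band(self):
        spec = tl.study_generative_spec(n_users=6000, seed=9)
        cohort = tl.simulate_counts(spec)
        p = STUDY_MIXING[0]
        share = (cohort.true_groups == 0).mean()
        assert abs(share - p) < 3 * np.sqrt(p * (1 - p) / spec.n_users)

    def test_moment_checks_mean_and_zero_fraction(self):
        """Empirical group/period moments match (1-pi)lam and
        pi + (1-pi)e^-lam within 4 SE at n=20000."""
        spec = tl.study_generative_spec(n_users=20000, seed=17)
        cohort = tl.simulate_counts(spec)
        codes = spec.time_codes
        for j, gp in enumerate(spec.group_params):
            lam, pi = group_rates(gp, codes)
            sub = cohort.counts[cohort.true_groups == j]
            n = sub.shape[0]
            mean_th = (1 - pi) * lam
            var_th = mean_th + pi * (1 - pi) * lam**2  # ZIP variance
            assert np.all(
                np.abs(sub.mean(axis=0) - mean_th) < 4 * np.sqrt(var_th / n)
            )
            p0 = pi + (1 - pi) * np.exp(-lam)
            se0 = np.sqrt(p0 * (1 - p0) / n)
            assert np.all(np.abs((sub == 0).mean(axis=0) - p0) < 4 * se0)

    def test_extreme_coefficients_raise_naming_group(self):
        spec = _single_group_spec(beta=(800.0,), alpha=(0.0,), n=100)
        with pytest.raises(FloatingPointError, match="group 1"):
            tl.simulate_counts(spec)

    def test_mixing_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GenerativeSpec(
                n_users=10,
                mixing=(0.5, 0.4),
                group_params=(HIGH_RISK_PARAMS, LOW_RISK_PARAMS),
                time_codes=tl.default_grid().time_codes,
            )


class TestSimulateFeatures:
    def test_zero_post_periods_have_no_words_or_hits(self, small_cohort):
        cohort, spec = small_cohort
        feats = tl.simulate_features(cohort)
        silent = cohort.counts == 0
        assert np.all(feats.total_words[silent] == 0)
        assert np.all(feats.hits[silent, :] == 0)

    def test_hits_never_exceed_words(self, small_cohort):
        cohort, _ = small_cohort
        feats = tl.simulate_features(cohort)
        assert np.all(feats.hits <= feats.total_words[:, :, None])

    def test_binomial_mean_of_hit_counts(self):
        # one user-period with a known word total: hits ~ Binomial(W, 0.1)
        spec = _single_group_spec(
            beta=(np.log(5.0),), alpha=(-30.0,), n=4000,
            category_rates={"cat": np.full((1, 7), 0.1)},
            words_per_post=20.0,
        )
        cohort = tl.simulate_counts(spec)
        feats = tl.simulate_features(cohort)
        posted = feats.total_words > 0
        ratio = feats.hits[:, :, 0][posted].sum() / feats.total_words[posted].sum()
        assert ratio == pytest.approx(0.1, abs=0.005)

    def test_missing_group_rate_rejected(self, small_cohort):
        cohort, spec = small_cohort
        from dataclasses import replace

        bad = replace(spec, category_rates={"cat": np.full((1, 7), 0.1)})
        with pytest.raises(ValueError, match="missing a group"):
            tl.simulate_features(cohort, spec=bad)


class TestSimulateMarkerTable:
    def test_null_model_hits_base_rate(self):
        table, groups = simulate_marker_table(
            4000, coefficients={"a": 0.0, "b": 0.0}, base_rate=0.5, seed=0
        )
        assert groups.mean() == pytest.approx(0.5, abs=0.03)

    def test_single_marker_cross_product_ratio(self):
        table, groups = simulate_marker_table(
            60000, coefficients={"m": np.log(6.0)}, base_rate=0.3,
            prevalences={"m": 0.5}, seed=1,
        )
        x = table["m"].to_numpy()
        a = ((x == 1) & (groups == 1)).sum()
        b = ((x == 1) & (groups == 0)).sum()
        c = ((x == 0) & (groups == 1)).sum()
        d = ((x == 0) & (groups == 0)).sum()
        assert (a * d) / (b * c) == pytest.approx(6.0, rel=0.1)

    def test_default_coefficients_are_published_odds_ratios(self):
        table, groups = simulate_marker_table(500, seed=2)
        assert list(table.columns) == list(MARKER_ODDS_RATIOS)
        assert set(np.unique(table.to_numpy())) <= {0, 1}

    def test_unattainable_base_rate_raises(self):
        with pytest.raises(ValueError, match="unattainable"):
            simulate_marker_table(
                200, coefficients={"m": 0.0}, base_rate=1.0, seed=0
            )

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 100"):
            simulate_marker_table(50, seed=0)
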