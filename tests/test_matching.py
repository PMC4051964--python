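"""Matching distances, donor pools, donor sampling, PMM/LRD imputation."""

import numpy as np
import pytest

from meanmatch import (
    ConstrainedSamplingError,
    EmptyDonorPoolError,
    IncompleteSample,
    MatchSpec,
    assign_donors,
    donor_pool_adaptive,
    donor_pool_caliper,
    donor_pool_fixed_k,
    fit_imputation_model,
    impute_lrd,
    impute_pmm,
    matching_distances,
    sample_donor,
)
from meanmatch.linear_model import LinearFit, ParameterDraw


def _manual_fit(alpha_hat, sample):
    resid = sample.x_obs - sample.z_obs @ np.asarray(alpha_hat, dtype=float)
    return LinearFit(
        alpha_hat=np.asarray(alpha_hat, dtype=float),
        sigma2_hat=float(resid @ resid) / max(sample.n_obs - sample.p, 1),
        residuals=resid,
        r_factor=np.linalg.qr(sample.z_obs)[1],
        dof=sample.n_obs - sample.p,
        n_obs=sample.n_obs,
    )


@pytest.fixture
def worked_example():
    """alpha_hat=(0,1), alpha*=(0,2); recipient y=1; donors y=(0.4, 1.0, 2.0)."""
    x = np.array([0.9, 1.0, 2.0, np.nan])
    y = np.array([0.4, 1.0, 2.0, 1.0])
    sample = IncompleteSample.from_xy(x, y)
    fit = _manual_fit([0.0, 1.0], sample)
    draw = ParameterDraw(np.array([0.0, 2.0]), 1.0)
    return sample, fit, draw


class TestMatchingDistances:
    def test_identical_covariates_type0(self, worked_example):
        sample, fit, _ = worked_example
        d = matching_distances(fit, None, sample, 0, recipient=0)
        # second donor has y_h = y_j = 1
        assert d[1] == pytest.approx(0.0)

    def test_type1_formula(self, worked_example):
        sample, fit, draw = worked_example
        d = matching_distances(fit, draw, sample, 1, recipient=0)
        # 2*1 - 1*0.4 = 1.6 against the first donor
        assert d[0] == pytest.approx(1.6)

    @pytest.mark.parametrize("match_type", [0, 1, 2])
    def test_sign_convention(self, worked_example, match_type):
        sample, fit, draw = worked_example
        d = matching_distances(fit, draw, sample, match_type, recipient=0)
        assert d.shape == (sample.n_obs,)

    def test_unknown_type(self, worked_example):
        sample, fit, draw = worked_example
        with pytest.raises(ValueError):
            matching_distances(fit, draw, sample, 3, recipient=0)

    def test_type0_and_type2_rank_donors_identically_single_covariate(self):
        """With z = (1, y) both scales are affine in y: same |delta| ranking."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        x[20:] = np.nan
        y = rng.normal(size=30)
        sample = IncompleteSample.from_xy(x, y)
        fit = fit_imputation_model(sample)
        draw = ParameterDraw(fit.alpha_hat + np.array([0.3, -0.7]), 1.0)
        for j in range(sample.n_mis):
            d0 = np.abs(matching_distances(fit, None, sample, 0, j))
            d2 = np.abs(matching_distances(fit, draw, sample, 2, j))
            np.testing.assert_array_equal(np.argsort(d0, kind="stable"),
                                          np.argsort(d2, kind="stable"))


class TestDonorPools:
    def test_full_pool(self, rng):
        deltas = np.array([0.5, 0.2, 0.9, 0.2])
        assert set(donor_pool_fixed_k(deltas, 4, rng)) == {0, 1, 2, 3}

    def test_two_smallest(self, rng):
        pool = donor_pool_fixed_k(np.array([0.5, 0.2, 0.9, 0.2]), 2, rng)
        assert set(pool) == {1, 3}

    def test_nearest_neighbour(self, rng):
        assert donor_pool_fixed_k(np.array([0.5, -0.2, 0.9]), 1, rng)[0] == 1

    def test_k_above_n_h_not_clamped(self, rng):
        with pytest.raises(ValueError):
            donor_pool_fixed_k(np.array([0.5, 0.2]), 3, rng)

    def test_boundary_ties_uniform(self):
        # |delta| = (0.1, 0.3, 0.3): second pool slot goes to donor 1 or 2
        # with equal probability.
        deltas = np.array([0.1, 0.3, 0.3])
        hits = np.zeros(3)
        rng = np.random.default_rng(123)
        n = 4000
        for _ in range(n):
            hits[list(donor_pool_fixed_k(deltas, 2, rng))] += 1
        assert hits[0] == n
        assert abs(hits[1] / n - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_caliper(self):
        deltas = np.array([0.5, -0.2, 0.9])
        assert list(donor_pool_caliper(deltas, np.inf)) == [0, 1, 2]
        assert list(donor_pool_caliper(deltas, 0.3)) == [1]
        with pytest.raises(EmptyDonorPoolError):
            donor_pool_caliper(deltas, 0.1)

    def test_adaptive(self, rng):
        deltas = np.array([0.5, -0.2, 0.9])
        # large caliper: unchanged
        assert list(donor_pool_adaptive(deltas, 10.0, rng)) == [0, 1, 2]
        # empty caliper pool -> two smallest
        assert set(donor_pool_adaptive(deltas, 0.1, rng)) == {0, 1}
        # singleton caliper pool -> expanded to 2
        assert set(donor_pool_adaptive(deltas, 0.3, rng)) == {0, 1}
        with pytest.raises(ValueError):
            donor_pool_adaptive(np.array([0.5]), 1.0, rng)

    def test_pool_quality_monotone_in_k(self, rng):
        deltas = np.random.default_rng(1).normal(size=40)
        worst = [
            np.max(np.abs(deltas[donor_pool_fixed_k(deltas, k, rng)]))
            for k in range(1, 41)
        ]
        assert all(a <= b + 1e-15 for a, b in zip(worst, worst[1:]))

    def test_matches_exhaustive_enumeration(self, rng):
        """Brute-force oracle for n_h <= 12: pool = k smallest by sorting."""
        gen = np.random.default_rng(2)
        for n_h in (3, 7, 12):
            deltas = gen.normal(size=n_h)
            for k in range(1, n_h + 1):
                expected = set(
                    sorted(range(n_h), key=lambda h: abs(deltas[h]))[:k]
                )
                assert set(donor_pool_fixed_k(deltas, k, rng)) == expected


class TestSampling:
    def test_singleton_pool(self, rng):
        spec = MatchSpec(k=1)
        counts = np.zeros(5, dtype=int)
        d = np.array([0.5, 0.1, 0.9, 0.2, 0.3])
        assert sample_donor(d, np.array([1]), spec, counts, rng) == 1
        assert counts[1] == 1

    def test_uniform_over_pool(self):
        spec = MatchSpec(k=4)
        d = np.array([0.1, 0.2, 0.3, 0.4, 5.0])
        pool = np.array([0, 1, 2, 3])
        rng = np.random.default_rng(8)
        n = 20_000
        hits = np.zeros(5)
        for _ in range(n):
            hits[sample_donor(d, pool, spec, np.zeros(5, dtype=int), rng)] += 1
        se = np.sqrt(0.25 * 0.75 / n)
        np.testing.assert_array_less(np.abs(hits[:4] / n - 0.25), 4 * se)
        assert hits[4] == 0

    def test_proportional_closeness_zero_is_uniform(self):
        spec = MatchSpec(pool_strategy="proportional", closeness=0.0)
        d = np.array([0.1, 1.0, 10.0])
        rng = np.random.default_rng(3)
        n = 20_000
        hits = np.zeros(3)
        for _ in range(n):
            hits[sample_donor(d, None, spec, np.zeros(3, dtype=int), rng)] += 1
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        np.testing.assert_array_less(np.abs(hits / n - 1 / 3), 4 * se)

    def test_proportional_weights_match_enumeration(self):
        """Sampling frequencies agree with the explicit power-law weights."""
        spec = MatchSpec(pool_strategy="proportional", closeness=2.0)
        d = np.array([0.5, 1.0, 2.0])
        w = (np.abs(d) + 1e-8) ** -2.0
        p = w / w.sum()
        rng = np.random.default_rng(4)
        n = 20_000
        hits = np.zeros(3)
        for _ in range(n):
            hits[sample_donor(d, None, spec, np.zeros(3, dtype=int), rng)] += 1
        se = np.sqrt(p * (1 - p) / n)
        np.testing.assert_array_less(np.abs(hits / n - p), 4 * se)

    def test_constrained_each_donor_once(self, rng):
        spec = MatchSpec(k=3, sampling_rule="constrained")
        d = np.array([0.1, 0.2, 0.3])
        pool = np.array([0, 1, 2])
        counts = np.zeros(3, dtype=int)
        chosen = {sample_donor(d, pool, spec, counts, rng) for _ in range(3)}
        assert chosen == {0, 1, 2}
        with pytest.raises(ConstrainedSamplingError):
            sample_donor(d, pool, spec, counts, rng)

    def test_slightly_constrained_penalises_repeat_donation(self):
        spec = MatchSpec(k=2, sampling_rule="slightly_constrained", penalty=0.1)
        d = np.array([0.1, 0.2])
        pool = np.array([0, 1])
        rng = np.random.default_rng(5)
        n = 10_000
        first = np.zeros(2)
        second = np.zeros(2)
        for _ in range(n):
            counts = np.zeros(2, dtype=int)
            first[sample_donor(d, pool, spec, counts, rng)] += 1
            second[sample_donor(d, pool, spec, counts, rng)] += 1
        # first pick is uniform; second strongly avoids the first donor
        assert abs(first[0] / n - 0.5) < 4 * np.sqrt(0.25 / n)
        # P(same donor twice) = 0.1/1.1 under the penalty weighting
        # P(second == 0) = P(first=0)*0.1/1.1 + P(first=1)*1/1.1 = 0.5
        assert abs(second[0] / n - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_empty_pool(self, rng):
        spec = MatchSpec(k=1)
        with pytest.raises(EmptyDonorPoolError):
            sample_donor(np.array([0.1]), np.array([], dtype=int), spec,
                         np.zeros(1, dtype=int), rng)


class TestAssignDonors:
    def test_constrained_feasibility(self, rng):
        x = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan, np.nan])
        y = np.linspace(0, 1, 7)
        sample = IncompleteSample.from_xy(x, y)
        fit = fit_imputation_model(sample)
        spec = MatchSpec(k=2, sampling_rule="constrained")
        with pytest.raises(ConstrainedSamplingError):
            assign_donors(fit, None, sample, spec, rng)

    def test_constrained_donation_counts(self, study1_sample, study1_fit, rng):
        spec = MatchSpec(match_type=0, k=10, sampling_rule="constrained")
        a = assign_donors(study1_fit, None, study1_sample, spec, rng)
        assert a.donation_counts.sum() == study1_sample.n_mis
        assert a.donation_counts.max() <= 1

    def test_fast_path_matches_per_recipient_pools(self, study1_sample,
                                                   study1_fit, rng):
        """The vectorised fixed-k/simple path picks from the same pools as
        the per-recipient primitives."""
        spec = MatchSpec(match_type=0, k=5)
        a = assign_donors(study1_fit, None, study1_sample, spec, rng)
        assert np.all(a.pool_size == 5)
        for j in range(study1_sample.n_mis):
            deltas = matching_distances(study1_fit, None, study1_sample, 0, j)
            pool = set(donor_pool_fixed_k(deltas, 5, rng))
            assert a.donor_idx[j] in pool
            assert a.delta[j] == pytest.approx(deltas[a.donor_idx[j]])

    def test_k1_is_nearest_neighbour(self, study1_sample, study1_fit, rng):
        spec = MatchSpec(match_type=0, k=1)
        a = assign_donors(study1_fit, None, study1_sample, spec, rng)
        for j in range(study1_sample.n_mis):
            deltas = matching_distances(study1_fit, None, study1_sample, 0, j)
            assert a.donor_idx[j] == np.argmin(np.abs(deltas))

    def test_fast_path_selection_is_uniform_over_pool(self):
        """Frequency check of the vectorised donor pick against uniformity."""
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, np.nan])
        y = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.05])
        sample = IncompleteSample.from_xy(x, y)
        fit = fit_imputation_model(sample)
        spec = MatchSpec(match_type=0, k=3)
        rng = np.random.default_rng(17)
        n = 9000
        hits = np.zeros(5)
        for _ in range(n):
            a = assign_donors(fit, None, sample, spec, rng)
            hits[a.donor_idx[0]] += 1
        in_pool = hits > 0
        assert in_pool.sum() == 3
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        np.testing.assert_array_less(np.abs(hits[in_pool] / n - 1 / 3), 4 * se)


class TestImputation:
    def test_pmm_takes_donor_value(self, worked_example):
        sample, fit, _ = worked_example
        spec = MatchSpec(match_type=0, k=1)
        a = assign_donors(fit, None, sample, spec, np.random.default_rng(0))
        # recipient y=1 matches donor y=1 exactly -> x* = 1.0
        np.testing.assert_array_equal(impute_pmm(sample, a), [1.0])

    def test_pmm_closure(self, study1_sample, study1_fit, rng):
        """PMM imputations are always members of the observed multiset."""
        observed = set(study1_sample.x_obs)
        for k in (1, 3, 10):
            spec = MatchSpec(match_type=0, k=k)
            a = assign_donors(study1_fit, None, study1_sample, spec, rng)
            assert set(impute_pmm(study1_sample, a)) <= observed

    def test_lrd_worked_example(self, worked_example):
        sample, fit, draw = worked_example
        # force the first donor (y_h=0.4, x_h=0.9) for the single recipient
        from meanmatch.matching import DonorAssignment

        a = DonorAssignment(
            donor_idx=np.array([0]),
            delta=np.array([1.6]),
            pool_size=np.array([1]),
            donation_counts=np.array([1, 0, 0]),
        )
        assert impute_lrd(sample, a, fit, draw, 1)[0] == pytest.approx(2.5)
        assert impute_lrd(sample, a, fit, draw, 2)[0] == pytest.approx(2.1)
        assert impute_lrd(sample, a, fit, draw, 0)[0] == pytest.approx(1.5)
        with pytest.raises(ValueError):
            impute_lrd(sample, a, fit, draw, 3)

    def test_lrd_types_coincide_when_draw_equals_estimate(self, worked_example):
        sample, fit, _ = worked_example
        degenerate = ParameterDraw(fit.alpha_hat.copy(), 1.0)
        spec = MatchSpec(match_type=0, k=2)
        a = assign_donors(fit, degenerate, sample, spec,
                          np.random.default_rng(1))
        vals = [impute_lrd(sample, a, fit, degenerate, t) for t in (0, 1, 2)]
        np.testing.assert_allclose(vals[0], vals[1])
        np.testing.assert_allclose(vals[0], vals[2])

    def test_lrd_type1_expectation_over_pool(self, worked_example):
        """E[x*_j | pool] = alpha* z_j + mean pool residual (enumeration)."""
        sample, fit, draw = worked_example
        spec = MatchSpec(match_type=0, k=3)
        rng = np.random.default_rng(2)
        n = 30_000
        vals = np.array(
            [
                impute_lrd(
                    sample,
                    assign_donors(fit, draw, sample, spec, rng),
                    fit,
                    draw,
                    1,
                )[0]
                for _ in range(n)
            ]
        )
        resid = sample.x_obs - sample.z_obs @ fit.alpha_hat
        expected = float(sample.z_mis[0] @ draw.alpha_star) + resid.mean()
        mcse = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean() - expected) < 4 * mcse
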