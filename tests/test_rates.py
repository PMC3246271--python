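"""Simple and blocked-ML rate estimators, binomial CIs, and the jackknife."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from synrate import (CloneObservation, MutationType, PopulationBlock,
                     binomial_rate_ci, blocked_loglik, closed_form_blocked_ml,
                     combine_rates, estimate_rate_blocked, fit_blocked_ml,
                     genomic_rate, group_blocks, jackknife_ci,
                     load_published_studies, point_estimate_simple)


def sig2(x: float) -> float:
    """Round to 2 significant figures, as rates are conventionally reported."""
    return float(f"{x:.2g}")


def make_obs(clone, population, t, counts, sites):
    return CloneObservation(
        clone=clone, population=population, generations=t,
        counts={ty: counts.get(ty, 0) for ty in MutationType},
        sites={ty: sites.get(ty, sites.get("all", 0.0)) for ty in MutationType},
    )


def random_blocks(rng, n_pops=4, max_clones=3):
    blocks = []
    for p in range(n_pops):
        obs = []
        for c in range(int(rng.integers(1, max_clones + 1))):
            t = int(rng.integers(5_000, 40_000))
            sites = {ty: float(rng.integers(500, 5_000))
                     for ty in MutationType}
            counts = {ty: int(rng.poisson(2.0)) for ty in MutationType}
            obs.append(CloneObservation(f"P{p}-c{c}", f"P{p}", t,
                                        counts, sites))
        blocks.append(PopulationBlock(f"P{p}", tuple(obs)))
    return blocks


class TestSimpleEstimator:
    def test_reproduces_published_cross_study_rates(self):
        """Pooled rates for the five published datasets, at 2 s.f. in
        units of 1e-11 per bp per generation."""
        studies = load_published_studies()
        expected = {"ltee": 8.9, "mg1655": 50.0, "w3110": 15.0,
                    "lt2": 40.0, "dk1622": 47.0}
        for row in studies.itertuples(index=False):
            est = point_estimate_simple(
                int(row.synonymous_mutations),
                row.cumulative_generations, row.synonymous_sites)
            assert sig2(est.rate * 1e11) == expected[row.study]

    def test_zero_mutations_zero_rate(self):
        assert point_estimate_simple(0, 1e5, 1e6).rate == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            point_estimate_simple(1, 0, 1e6)
        with pytest.raises(ValueError):
            point_estimate_simple(-1, 1e5, 1e6)


class TestBinomialCI:
    def test_reproduces_published_brackets(self):
        lo, _ = binomial_rate_ci(25, 300_000 * 941_000)
        assert sig2(lo * 1e11) == 5.7
        lo, hi = binomial_rate_ci(2, 13_850 * 945_000)
        assert (sig2(lo * 1e11), sig2(hi * 1e11)) == (1.9, 55.0)

    def test_zero_successes_has_zero_lower_limit(self):
        lo, hi = binomial_rate_ci(0, 1e9)
        assert lo == 0.0 and hi > 0.0

    def test_point_inside_interval(self):
        for m, trials in [(1, 1e6), (25, 1e11), (7, 1e4)]:
            lo, hi = binomial_rate_ci(m, trials)
            assert lo <= m / trials <= hi

    def test_m_exceeding_trials_rejected(self):
        with pytest.raises(ValueError):
            binomial_rate_ci(5, 4)

    def test_converges_to_exact_poisson_ci(self):
        """At huge trial counts the binomial limits coincide with the
        chi-square form of the exact Poisson limits (4 s.f.)."""
        trials = 1e11
        for m in (1, 5, 25):
            blo, bhi = binomial_rate_ci(m, trials)
            plo = stats.chi2.ppf(0.025, 2 * m) / 2 / trials
            phi = stats.chi2.ppf(0.975, 2 * (m + 1)) / 2 / trials
            assert blo == pytest.approx(plo, rel=1e-4)
            assert bhi == pytest.approx(phi, rel=1e-4)


class TestGenomicRate:
    def test_published_combination(self):
        mu = point_estimate_simple(25, 300_000, 941_000).rate
        assert sig2(genomic_rate(mu, 4.6e6)) == 0.00041

    @pytest.mark.parametrize("mu,size,expected", [
        (0.0, 4.6e6, 0.0), (1e-10, 1e6, 1e-4),
    ])
    def test_is_a_product(self, mu, size, expected):
        assert genomic_rate(mu, size) == pytest.approx(expected)


class TestBlockedLikelihood:
    def test_single_clone_mle_at_count_over_exposure(self):
        obs = make_obs("c", "P", 1000, {MutationType.GC_AT: 4}, {"all": 500.0})
        block = PopulationBlock("P", (obs,))
        mle = 4 / (1000 * 500.0)
        base = {t: mle for t in MutationType}
        ll_hat = blocked_loglik([block], base)
        for factor in (0.5, 0.9, 1.1, 2.0):
            other = dict(base)
            other[MutationType.GC_AT] = mle * factor
            assert blocked_loglik([block], other) < ll_hat

    def test_duplicated_clone_in_block_averages_out(self):
        obs = make_obs("c", "P", 1000, {MutationType.AT_GC: 3}, {"all": 400.0})
        rates = {t: 1e-6 for t in MutationType}
        single = blocked_loglik([PopulationBlock("P", (obs,))], rates)
        double = blocked_loglik([PopulationBlock("P", (obs, obs))], rates)
        assert double == pytest.approx(single, rel=1e-12)

    def test_zero_rate_with_positive_count_is_minus_inf(self):
        obs = make_obs("c", "P", 1000, {MutationType.GC_AT: 1}, {"all": 500.0})
        rates = {t: 0.0 for t in MutationType}
        assert blocked_loglik([PopulationBlock("P", (obs,))], rates) \
            == -math.inf

    def test_zero_sites_require_zero_counts(self):
        with pytest.raises(ValueError, match="zero callable sites"):
            make_obs("c", "P", 1000, {MutationType.GC_AT: 1}, {"all": 0.0})


class TestBlockedML:
    @pytest.mark.parametrize("seed", range(8))
    def test_numeric_optimum_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        blocks = random_blocks(rng)
        obs = [o for b in blocks for o in b.observations]
        closed = fit_blocked_ml(obs, blocks, method="closed_form").per_type
        numeric = fit_blocked_ml(obs, blocks, method="numeric").per_type
        for t in MutationType:
            if closed[t] == 0:
                assert numeric[t] == 0
            else:
                assert numeric[t] == pytest.approx(closed[t], rel=1e-6)

    def test_all_zero_counts_give_zero_rates_with_upper_bounds(self):
        obs = [make_obs(f"c{i}", f"P{i}", 1000, {}, {"all": 500.0})
               for i in range(3)]
        est = fit_blocked_ml(obs)
        assert all(v == 0.0 for v in est.per_type.values())
        # zero observed events still bound the rate from above
        exposure = 3 * 1000 * 500.0
        for t in MutationType:
            assert est.per_type_upper[t] == \
                pytest.approx(-math.log(0.05) / exposure)

    def test_duplicating_clones_within_blocks_changes_nothing(self):
        rng = np.random.default_rng(42)
        blocks = random_blocks(rng)
        doubled = [PopulationBlock(b.population, b.observations * 2)
                   for b in blocks]
        r1 = closed_form_blocked_ml(blocks)
        r2 = closed_form_blocked_ml(doubled)
        for t in MutationType:
            assert r2[t] == pytest.approx(r1[t], rel=1e-12)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(7)
        blocks = random_blocks(rng)
        base = closed_form_blocked_ml(blocks)
        scaled_sites = [
            PopulationBlock(b.population, tuple(
                CloneObservation(o.clone, o.population, o.generations,
                                 o.counts,
                                 {t: s * k for t, s in o.sites.items()})
                for o in b.observations))
            for b in blocks
        ]
        for t in MutationType:
            got = closed_form_blocked_ml(scaled_sites)[t]
            assert got == pytest.approx(base[t] / k, rel=1e-12)

    def test_combined_rate_matches_pooled_simple_estimator(self):
        """One clone per population, uniform sites and generations, and a
        50:50 base composition: the composition-weighted blocked-ML rate
        reduces algebraically to pooled-count / (generations x 2 x S)."""
        rng = np.random.default_rng(3)
        t, s = 10_000, 800.0
        obs = [
            make_obs(f"c{i}", f"P{i}", t,
                     {ty: int(rng.poisson(3)) for ty in MutationType},
                     {"all": s})
            for i in range(6)
        ]
        per_type = closed_form_blocked_ml(group_blocks(obs))
        combined = combine_rates(per_type, (0.5, 0.5))
        pooled = sum(sum(o.counts.values()) for o in obs)
        simple = point_estimate_simple(pooled, 6 * t, 2 * s).rate
        assert combined == pytest.approx(simple, rel=1e-9)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_blocked_ml([])


class TestCombineRates:
    def test_equal_rates_give_three_r(self):
        rates = {t: 2.5e-10 for t in MutationType}
        for f_at in (0.1, 0.5, 0.9):
            assert combine_rates(rates, (f_at, 1 - f_at)) == \
                pytest.approx(3 * 2.5e-10)

    def test_pure_at_composition_uses_only_at_rates(self):
        rng = np.random.default_rng(1)
        rates = {t: float(rng.uniform(0, 1e-9)) for t in MutationType}
        at_sum = sum(v for t, v in rates.items() if t.ancestral_pair == "AT")
        assert combine_rates(rates, (1.0, 0.0)) == pytest.approx(at_sum)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            rates = {t: float(rng.uniform(0, 1e-9)) for t in MutationType}
            f_at = float(rng.uniform(0.05, 0.95))
            direct = f_at * (rates[MutationType.AT_GC]
                             + rates[MutationType.AT_CG]
                             + rates[MutationType.AT_TA]) \
                + (1 - f_at) * (rates[MutationType.GC_AT]
                                + rates[MutationType.GC_TA]
                                + rates[MutationType.GC_CG])
            assert combine_rates(rates, (f_at, 1 - f_at)) == \
                pytest.approx(direct, rel=1e-12)


class TestJackknife:
    def _estimator(self, blocks):
        return combine_rates(closed_form_blocked_ml(blocks), (0.5, 0.5))

    def test_identical_blocks_zero_width(self):
        obs = make_obs("c", "P", 1000, {MutationType.GC_AT: 2}, {"all": 300.0})
        blocks = [PopulationBlock(f"P{i}", (
            CloneObservation(f"c{i}", f"P{i}", 1000, obs.counts, obs.sites),
        )) for i in range(5)]
        jk = jackknife_ci(self._estimator, blocks)
        assert jk.se == pytest.approx(0.0, abs=1e-25)
        assert jk.ci.lower == pytest.approx(jk.estimate)
        assert jk.ci.upper == pytest.approx(jk.estimate)

    def test_pseudo_value_mean_is_the_jackknife_point(self):
        rng = np.random.default_rng(11)
        blocks = random_blocks(rng, n_pops=6)
        jk = jackknife_ci(self._estimator, blocks)
        assert jk.point == pytest.approx(float(jk.pseudo_values.mean()))
        assert jk.n == 6 and jk.df == 5

    def test_delete_one_matches_closed_form_recomputation(self):
        rng = np.random.default_rng(13)
        blocks = random_blocks(rng, n_pops=5)
        # make one block mutation-free: dropping it must still agree
        empty = PopulationBlock("P9", (
            make_obs("c", "P9", 2000, {}, {"all": 700.0}),))
        blocks = blocks + [empty]
        jk = jackknife_ci(self._estimator, blocks)
        for i in range(len(blocks)):
            manual = self._estimator(blocks[:i] + blocks[i + 1:])
            assert jk.leave_one_out[i] == pytest.approx(manual, rel=1e-12)

    def test_fewer_than_two_blocks_rejected(self):
        obs = make_obs("c", "P", 1000, {}, {"all": 100.0})
        with pytest.raises(ValueError):
            jackknife_ci(self._estimator, [PopulationBlock("P", (obs,))])

    def test_interval_truncated_at_zero(self):
        # very sparse data drives the lower pseudo-limit negative
        blocks = []
        for i in range(4):
            counts = {MutationType.GC_AT: 1} if i == 0 else {}
            blocks.append(PopulationBlock(f"P{i}", (
                make_obs("c", f"P{i}", 1000, counts, {"all": 100.0}),)))
        jk = jackknife_ci(self._estimator, blocks)
        assert jk.ci.lower >= 0.0


class TestFullPipeline:
    def test_estimate_rate_blocked_reports_all_parts(self, ltee_records,
                                                     ltee_clones):
        from synrate import build_clone_observations
        from synrate.genome import SiteOpportunityTable
        table = SiteOpportunityTable({t: 160_000 for t in MutationType},
                                     4_000_000, 2_300_000, 2_300_000)
        obs = build_clone_observations(ltee_records, clones=ltee_clones,
                                       fallback=table)
        est = estimate_rate_blocked(obs, table, genome_size=4.6e6)
        assert est.rate > 0
        assert est.genomic == pytest.approx(est.rate * 4.6e6)
        assert est.ci is not None
        assert est.ci.lower <= est.rate <= est.ci.upper
        assert est.per_type[MutationType.GC_CG] == 0.0
        assert est.per_type_upper[MutationType.GC_CG] > 0.0
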