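"""Induced-prior RfD distributions: priors, closed forms, quantiles, grid."""

import math

import numpy as np
import pytest
from scipy import stats

from rfduq import reference_values as ref
from rfduq.prob_rfd import (
    LognormalSpec,
    PodDistribution,
    RfdDistribution,
    induced_rfd,
    lower_bound,
    percentile_of,
    pod_to_intake,
    scenario_grid,
    uf_prior,
)
from rfduq.rfd_core import Classification, Metric, UncertaintyFactorSpec

Z95 = stats.norm.ppf(0.95)


def _point_pod(value_pg, cls=Classification.LOAEL):
    return PodDistribution(
        form="point",
        spec=value_pg,
        metric=Metric.TCDD,
        threshold=5.0,
        classification=cls,
        unit="pg/kg/day",
    )


def _lognormal_pod(log_mean, log_sd, cls=Classification.LOAEL):
    return PodDistribution(
        form="lognormal",
        spec=LognormalSpec(log_mean, log_sd),
        metric=Metric.TCDD,
        threshold=5.0,
        classification=cls,
        unit="pg/kg/day",
    )


class TestUfPrior:
    def test_p95_convention_quantile_equation(self):
        spec = uf_prior(10.0)
        # median sqrt(10); nominal at the 95th percentile
        assert spec.median == pytest.approx(math.sqrt(10.0))
        assert spec.log_sd == pytest.approx(math.log(math.sqrt(10.0)) / Z95, rel=1e-9)
        assert spec.log_sd == pytest.approx(0.6999, abs=2e-4)
        assert spec.quantile(0.95) == pytest.approx(10.0, rel=1e-9)

    def test_degenerate_nominal_one(self):
        spec = uf_prior(1.0)
        assert spec.median == pytest.approx(1.0)
        assert spec.log_sd <= 1e-8

    def test_median_nominal_and_explicit(self):
        spec = uf_prior(10.0, convention="median_nominal", log_sd=0.5)
        assert spec.median == pytest.approx(10.0)
        spec = uf_prior(10.0, convention="explicit", log_mean=1.0, log_sd=0.5)
        assert spec.log_mean == 1.0

    def test_sub_unit_nominal_rejected(self):
        with pytest.raises(ValueError):
            uf_prior(0.5)


class TestInducedRfd:
    def test_point_inputs_collapse_to_deterministic(self):
        ufs = [UncertaintyFactorSpec("UF_L", 10.0), UncertaintyFactorSpec("UF_H", 3.0)]
        dist = induced_rfd(_point_pod(20.0), ufs, n_samples=10_000, seed=1)
        assert np.all(dist.samples == pytest.approx(20.0 / 30.0))

    def test_closed_form_combines_log_moments(self):
        pod = _lognormal_pod(math.log(20.0), 0.8)
        ufs = [
            UncertaintyFactorSpec("UF_L", 10.0, uf_prior(10.0)),
            UncertaintyFactorSpec("UF_H", 3.0, uf_prior(3.0)),
        ]
        dist = induced_rfd(pod, ufs, n_samples=10_000, seed=2)
        cf = dist.closed_form
        expected_mu = math.log(20.0) - uf_prior(10.0).log_mean - uf_prior(3.0).log_mean
        expected_sd = math.sqrt(0.8**2 + uf_prior(10.0).log_sd ** 2 + uf_prior(3.0).log_sd ** 2)
        assert cf.log_mean == pytest.approx(expected_mu)
        assert cf.log_sd == pytest.approx(expected_sd)

    def test_sequential_equals_composite_product(self):
        """Drawing UF 10 then UF 3 equals one draw of their product law."""
        pod = _lognormal_pod(math.log(20.0), 0.5)
        two = induced_rfd(
            pod,
            [
                UncertaintyFactorSpec("UF_L", 10.0, uf_prior(10.0)),
                UncertaintyFactorSpec("UF_H", 3.0, uf_prior(3.0)),
            ],
            n_samples=10_000,
            seed=3,
        )
        product_spec = LognormalSpec(
            uf_prior(10.0).log_mean + uf_prior(3.0).log_mean,
            math.hypot(uf_prior(10.0).log_sd, uf_prior(3.0).log_sd),
        )
        one = induced_rfd(
            pod,
            [UncertaintyFactorSpec("UF_LH", 30.0, product_spec)],
            n_samples=10_000,
            seed=3,
        )
        assert two.closed_form.log_mean == pytest.approx(one.closed_form.log_mean)
        assert two.closed_form.log_sd == pytest.approx(one.closed_form.log_sd)

    def test_seed_mandatory_and_minimum_samples(self):
        with pytest.raises(ValueError, match="seed"):
            induced_rfd(_point_pod(20.0), [], n_samples=10_000)
        with pytest.raises(ValueError, match="10,000"):
            induced_rfd(_point_pod(20.0), [], n_samples=100, seed=1)

    def test_serum_pod_must_be_converted(self):
        pod = PodDistribution(
            form="point", spec=235.0, metric=Metric.TCDD,
            threshold=5.0, classification=Classification.LOAEL, unit="ppt",
        )
        with pytest.raises(ValueError, match="intake"):
            induced_rfd(pod, [], n_samples=10_000, seed=1)
        intake = pod_to_intake(pod, ref.ANCHOR)
        assert intake.median == pytest.approx(20.0)  # 235 ppt at the anchor

    def test_reproducible_given_seed(self):
        pod = _lognormal_pod(1.0, 0.5)
        a = induced_rfd(pod, [], n_samples=10_000, seed=7)
        b = induced_rfd(pod, [], n_samples=10_000, seed=7)
        assert np.array_equal(a.samples, b.samples)


class TestQuantiles:
    def test_lower_bound_of_degenerate(self):
        dist = induced_rfd(_point_pod(5.0), [], n_samples=10_000, seed=1)
        assert lower_bound(dist) == pytest.approx(5.0)

    def test_closed_form_quantile_formula(self):
        dist = induced_rfd(_lognormal_pod(1.0, 0.5), [], n_samples=10_000, seed=1)
        assert lower_bound(dist, 0.025) == pytest.approx(
            math.exp(1.0 + stats.norm.ppf(0.025) * 0.5)
        )
        assert lower_bound(dist, 0.5) == pytest.approx(math.exp(1.0))

    def test_lower_bound_monotone_in_p(self):
        dist = induced_rfd(_lognormal_pod(1.0, 0.5), [], n_samples=10_000, seed=1)
        qs = [lower_bound(dist, p) for p in (0.01, 0.025, 0.25, 0.5, 0.9)]
        assert qs == sorted(qs)

    def test_percentile_inverse_of_lower_bound(self):
        dist = induced_rfd(_lognormal_pod(1.0, 0.7), [], n_samples=10_000, seed=1)
        assert percentile_of(dist, lower_bound(dist, 0.025)) == pytest.approx(2.5)

    def test_three_sigma_tail(self):
        dist = induced_rfd(_lognormal_pod(1.0, 0.5), [], n_samples=10_000, seed=1)
        v = math.exp(1.0 - 3 * 0.5)
        assert percentile_of(dist, v) == pytest.approx(100 * stats.norm.cdf(-3), rel=1e-6)

    def test_empirical_censoring_below_resolution(self):
        samples = np.exp(np.random.default_rng(1).normal(1.0, 0.5, 10_000))
        dist = RfdDistribution(samples=samples, closed_form=None, scenario={}, seed=1)
        with pytest.warns(UserWarning, match="censored"):
            p = percentile_of(dist, float(samples.min()) / 100.0)
        assert p == pytest.approx(100.0 / 10_000)

    def test_extreme_tail_needs_closed_form(self):
        """Analytic CDF resolves placements far below Monte Carlo resolution."""
        dist = induced_rfd(_lognormal_pod(math.log(100.0), 0.3), [], n_samples=10_000, seed=1)
        twelve_sigma_value = math.exp(math.log(100.0) - 12 * 0.3)
        p = percentile_of(dist, twelve_sigma_value)
        assert 0.0 < p < 1e-25  # ~Phi(-12), unreachable by sampling


@pytest.fixture(scope="module")
def grid(population_fits):
    return scenario_grid(population_fits, anchor=ref.ANCHOR, n_samples=20_000, seed=13)


class TestScenarioGrid:
    def test_exactly_eight_scenarios(self, grid):
        dists, table = grid
        assert len(dists) == 8
        assert len(table) == 8
        keys = set(
            zip(table["metric"], table["threshold_tsh_uU_mL"], table["classification"])
        )
        assert len(keys) == 8

    def test_monotonicity_relations(self, grid):
        _, t = grid
        piv = t.set_index(["metric", "threshold_tsh_uU_mL", "classification"])[
            "rfd_p2.5_pg_kg_day"
        ]
        for th in (5.0, 10.0):
            for met in ("TCDD", "TEQ"):
                assert piv[(met, th, "NOAEL")] > piv[(met, th, "LOAEL")]
            for cl in ("NOAEL", "LOAEL"):
                assert piv[("TEQ", th, cl)] >= piv[("TCDD", th, cl)]

    def test_bit_identical_summary_given_seed(self, population_fits, grid):
        _, t1 = grid
        _, t2 = scenario_grid(
            population_fits, anchor=ref.ANCHOR, n_samples=20_000, seed=13
        )
        assert t1.equals(t2)

    def test_ks_distance_closed_form_vs_samples(self, population_fits):
        dists, _ = scenario_grid(
            population_fits, anchor=ref.ANCHOR, n_samples=100_000, seed=5
        )
        for d in dists:
            stat = stats.kstest(np.log(d.samples), "norm",
                                args=(d.closed_form.log_mean, d.closed_form.log_sd)).statistic
            assert stat < 0.01
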