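"""Mark-ratio scaling, variance propagation, log-normal CIs, partitioning."""

import math

import numpy as np
import pytest

from rdcapture import (
    AbundanceEstimate,
    SpeciesProportions,
    ThetaEstimate,
    combined_cv,
    lognormal_ci,
    partition_species,
    scale_to_total,
    total_abundance,
    total_abundance_variance,
)


class TestTotalAbundance:
    @pytest.mark.parametrize(
        "nm, theta, expected",
        [(39, 0.78, 50), (24, 0.77, 31), (26, 0.69, 38), (22, 0.62, 35),
         (10, 0.65, 15)],
    )
    def test_published_yearly_ratios(self, nm, theta, expected):
        assert round(total_abundance(nm, ThetaEstimate(theta, 30))) == expected

    def test_fully_marked_population(self):
        assert total_abundance(123.0, ThetaEstimate(1.0, 10)) == 123.0

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            ThetaEstimate(0.0, 10)


class TestVariance:
    def test_no_uncertainty(self):
        assert total_abundance_variance(
            100.0, 100.0, 0.0, ThetaEstimate(1.0, 30)
        ) == 0.0

    def test_hand_evaluated(self):
        var = total_abundance_variance(100.0, 50.0, 25.0, ThetaEstimate(0.5, 30))
        assert var == pytest.approx(10000.0 * (0.01 + 1.0 / 30.0))

    def test_vanishes_with_large_photo_sample(self):
        var = total_abundance_variance(
            100.0, 50.0, 0.0, ThetaEstimate(0.5, 10**9)
        )
        assert var == pytest.approx(0.0, abs=1e-3)

    def test_reduces_to_cr_variance_when_theta_one(self):
        var = total_abundance_variance(80.0, 80.0, 16.0, ThetaEstimate(1.0, 5))
        assert var == pytest.approx(80.0**2 * 16.0 / 80.0**2)


class TestLognormalCI:
    def test_zero_se_collapses(self):
        assert lognormal_ci(100.0, 0.0) == (100.0, 100.0)

    def test_hand_evaluated(self):
        low, high = lognormal_ci(100.0, 20.0)
        C = math.exp(1.959963984540054 * math.sqrt(math.log(1.04)))
        assert (low, high) == pytest.approx((100.0 / C, 100.0 * C))
        assert C == pytest.approx(1.4743, abs=2e-4)

    def test_factor_monotone_in_cv(self):
        widths = [lognormal_ci(100.0, se)[1] for se in np.linspace(0, 60, 13)]
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_invalid_abundance(self):
        with pytest.raises(ValueError):
            lognormal_ci(0.0, 1.0)


class TestCombinedCV:
    def test_single_component(self):
        assert combined_cv(0.0, 0.0, 0.37) == 0.37

    def test_three_four_five(self):
        assert combined_cv(0.1, 0.2, 0.2) == pytest.approx(0.3)

    def test_dominates_every_component(self):
        cv = combined_cv(0.12, 0.08, 0.2)
        assert cv >= 0.2
        assert combined_cv(0, 0, 0) == 0.0


class TestPartition:
    PROPS = SpeciesProportions(
        ("striped", "common", "intermediate"),
        (0.944, 0.017, 0.039),
        (0.019, 0.27, 0.37),
    )

    def test_published_2011_partition(self):
        # pooled 2011 estimate 1,593: species shares 1504 / 27 / 62
        total = AbundanceEstimate.from_point_se(1593.0, 1593.0 * 0.12)
        parts = dict(partition_species(total, self.PROPS))
        assert parts["striped"].N == pytest.approx(1503.8, abs=0.1)
        assert parts["common"].N == pytest.approx(27.1, abs=0.1)
        assert parts["intermediate"].N == pytest.approx(62.1, abs=0.1)

    def test_partition_conserves_total(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            raw = rng.random(3)
            props = SpeciesProportions(
                ("a", "b", "c"), tuple(raw / raw.sum()), (0.1, 0.1, 0.1)
            )
            total = AbundanceEstimate.from_point_se(
                float(rng.uniform(50, 2000)), 10.0
            )
            parts = partition_species(total, props)
            assert sum(e.N for _, e in parts) == pytest.approx(total.N)

    def test_degenerate_proportions(self):
        props = SpeciesProportions(("a", "b"), (1.0, 0.0), (0.0, 0.0))
        total = AbundanceEstimate.from_point_se(100.0, 10.0)
        parts = partition_species(total, props)
        assert len(parts) == 1
        assert parts[0][1].N == 100.0

    def test_cv_ordering_follows_species_cv(self):
        # with a shared pooled CV, species CV ordering drives the final CVs
        total = AbundanceEstimate.from_point_se(1593.0, 1593.0 * 0.155)
        parts = dict(partition_species(total, self.PROPS, cv_distinctiveness=0.0))
        assert (
            parts["striped"].cv < parts["common"].cv < parts["intermediate"].cv
        )


def test_bootstrap_reproduces_analytic_cv():
    """Simulating theta and propagating matches the variance formula."""
    rng = np.random.default_rng(123)
    nm, se_nm, theta, n = 350.0, 25.0, 0.25, 600
    est = scale_to_total(nm, se_nm, ThetaEstimate(theta, n))
    reps = 4000
    nm_draws = rng.normal(nm, se_nm, reps)
    theta_draws = rng.binomial(n, theta, reps) / n
    boots = nm_draws / theta_draws
    assert boots.std() / boots.mean() == pytest.approx(est.cv, rel=0.10)
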