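"""(Q)AICc, Akaike weights and model averaging."""

import numpy as np
import pytest

from rdcapture import (
    RDModelSpec,
    akaike_weights,
    default_model_grid,
    fit_model,
    information_criterion,
    model_average,
    rank_models,
)
from conftest import random_matrix
from rdcapture.design import SamplingDesign


class TestInformationCriterion:
    def test_zero_loglik_zero_params(self):
        assert information_criterion(0.0, 0, 50) == 0.0

    def test_hand_evaluated_aicc(self):
        # -2(-100) + 2*5 + 2*5*6/94
        assert information_criterion(-100.0, 5, 100) == pytest.approx(
            210.0 + 60.0 / 94.0
        )

    def test_chat_scales_deviance_term_only(self):
        base = information_criterion(-100.0, 5, 100, chat=1.0)
        infl = information_criterion(-100.0, 5, 100, chat=2.0)
        assert base - infl == pytest.approx(100.0)  # deviance halved

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            information_criterion(-10.0, 5, 6)

    def test_chat_below_one_rejected(self):
        with pytest.raises(ValueError):
            information_criterion(-10.0, 2, 50, chat=0.5)


class TestAkaikeWeights:
    def test_equal_criteria_split_evenly(self):
        assert akaike_weights([100.0, 100.0]) == pytest.approx([0.5, 0.5])

    def test_published_two_model_ratio(self):
        # Delta = 2.06 between the two best striped-dolphin models:
        # weight ratio exp(1.03) ~ 2.80, consistent with 0.57 vs 0.20
        w = akaike_weights([0.0, 2.06])
        assert w[0] / w[1] == pytest.approx(np.exp(1.03), rel=1e-12)

    def test_published_six_model_pattern(self):
        # bottlenose Deltas; renormalized over the top six the published
        # weights (0.24, 0.15, 0.14, 0.10, 0.09, 0.09) keep the same ratios
        deltas = np.array([0.0, 0.91, 1.12, 1.83, 1.89, 1.98])
        w = akaike_weights(deltas)
        published = np.array([0.24, 0.15, 0.14, 0.10, 0.09, 0.09])
        assert np.allclose(w, published / published.sum(), atol=0.02)

    def test_shift_invariance_and_order(self):
        c = np.array([3.0, 1.0, 7.0])
        assert akaike_weights(c) == pytest.approx(akaike_weights(c + 123.4))
        w = akaike_weights(c)
        assert w[1] > w[0] > w[2]


class _FakeFit:
    """Minimal stand-in carrying a parameter table (synthetic, test-only)."""

    def __init__(self, est, se, emigration="random"):
        import pandas as pd

        self.spec = RDModelSpec(False, emigration, "constant")
        rows = {"parameter": ["S"], "estimate": [est], "se": [se]}
        if emigration != "none":  # real no-emigration fits carry no gamma row
            rows = {
                "parameter": ["S", "gamma"],
                "estimate": [est, 0.1],
                "se": [se, 0.01],
            }
        self.table = pd.DataFrame(rows)


class TestModelAverage:
    def test_single_model_passthrough(self):
        theta, se = model_average([_FakeFit(0.9, 0.02)], [1.0], "S")
        assert (theta, se) == (0.9, 0.02)

    def test_hand_evaluated_two_models(self):
        fits = [_FakeFit(0.1, 0.0), _FakeFit(0.3, 0.0)]
        theta, se = model_average(fits, [0.5, 0.5], "S")
        assert theta == pytest.approx(0.2)
        assert se == pytest.approx(0.1)  # pure between-model spread

    def test_degenerate_weights_return_best(self):
        fits = [_FakeFit(0.9, 0.02), _FakeFit(0.5, 0.3)]
        theta, se = model_average(fits, [1.0, 0.0], "S")
        assert (theta, se) == (0.9, 0.02)

    def test_absent_gamma_is_structural_zero(self):
        fits = [_FakeFit(0.9, 0.02, "none"), _FakeFit(0.9, 0.02, "random")]
        # under no-emigration gamma is fixed at 0, not missing
        theta, se = model_average(fits, [0.5, 0.5], "gamma")
        assert theta == pytest.approx(0.05)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            model_average([], [], "S")


def test_rank_models_table_properties():
    design = SamplingDesign.from_counts([3, 3, 3])
    m = random_matrix(design, 60, seed=21)
    grid = [
        RDModelSpec(False, "none", "constant"),
        RDModelSpec(False, "none", "primary"),
        RDModelSpec(False, "random", "constant"),
    ]
    fits = [fit_model(m, s, n_starts=2, seed=i, compute_se=False)
            for i, s in enumerate(grid)]
    table = rank_models(fits, chat=1.0)
    f = table.frame
    assert f["delta_AICc"].iloc[0] == 0.0
    assert f["weight"].sum() == pytest.approx(1.0)
    assert (f["AICc"].diff().dropna() >= 0).all()


def test_default_grid_has_thirty_models():
    grid = default_model_grid()
    assert len(grid) == 30
    assert len({s.label for s in grid}) == 30
    assert sum(s.heterogeneity != "none" for s in grid) == 6
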