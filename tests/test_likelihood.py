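"""Likelihood correctness against brute-force latent-path enumeration."""

import itertools
import math

import numpy as np
import pytest

from rdcapture import (
    CaptureMatrix,
    RDData,
    RDModelSpec,
    SamplingDesign,
    count_parameters,
    negative_log_likelihood,
    pstar,
)
from rdcapture.likelihood import ParamLayout, primary_pstar

from oracles import cjs_nll_oracle, closed_nll_oracle, open_nll_oracle


class TestPstar:
    def test_two_halves(self):
        assert pstar([0.5, 0.5]) == pytest.approx(0.75)

    def test_zero_detection(self):
        assert pstar([0.0, 0.0, 0.0]) == 0.0

    def test_monthly_estimates_2011(self):
        # within-season detection from per-month p of 0.22, 0.11, 0.38
        assert pstar([0.22, 0.11, 0.38]) == pytest.approx(0.569596, abs=1e-6)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            pstar([])

    def test_monotone_in_each_p(self):
        base = pstar([0.2, 0.3, 0.4])
        assert pstar([0.25, 0.3, 0.4]) > base
        assert pstar([0.2, 0.3, 0.45]) > base

    def test_mixture_weighting(self):
        lo, hi = pstar([0.1, 0.1]), pstar([0.6, 0.6])
        mid = pstar([0.1, 0.1], pi=0.3, p_row2=[0.6, 0.6])
        assert mid == pytest.approx(0.3 * lo + 0.7 * hi)


def _params(spec, design, **kw):
    """Real-scale params via the layout, with simple defaults."""
    layout = ParamLayout(spec, design)
    p = layout.unpack(np.zeros(layout.n_params))  # everything 0.5 / f0=1
    for key, val in kw.items():
        arr = getattr(p, key)
        if np.isscalar(val) and not np.isscalar(arr):
            if key == "p":
                arr[np.isfinite(arr)] = val
            else:
                arr[:] = val
        elif key == "pi":
            p.pi = val
        else:
            setattr(p, key, np.asarray(val, dtype=float))
    return p


def test_single_bernoulli_history():
    """One animal, one primary, one secondary, p=0.5, f0=0 -> -ln(0.5)."""
    design = SamplingDesign.from_counts([1])
    m = CaptureMatrix(design, ("a",), np.array([[1]]))
    spec = RDModelSpec(False, "none", "constant")
    params = _params(spec, design, p=0.5, f0=[0.0])
    assert negative_log_likelihood(params, m, spec) == pytest.approx(
        -math.log(0.5), abs=1e-12
    )


def test_markovian_with_zero_gammas_reduces_to_none(tiny_matrix):
    spec_m = RDModelSpec(False, "markovian", "constant")
    spec_n = RDModelSpec(False, "none", "constant")
    d = tiny_matrix.design
    pm = _params(spec_m, d, gamma_dp=[0.0], gamma_p=[0.0], p=0.4, S=[0.8])
    pn = _params(spec_n, d, p=0.4, S=[0.8])
    assert negative_log_likelihood(pm, tiny_matrix, spec_m) == pytest.approx(
        negative_log_likelihood(pn, tiny_matrix, spec_n), abs=1e-12
    )


def test_three_individuals_match_path_enumeration():
    """2 primaries x 2 secondaries: forward algorithm vs explicit paths."""
    design = SamplingDesign.from_counts([2, 2])
    rows = np.array([[1, 0, 0, 1], [1, 1, 0, 0], [0, 1, 1, 1]], dtype=np.uint8)
    m = CaptureMatrix(design, ("a", "b", "c"), rows)
    spec = RDModelSpec(False, "markovian", "primary_x_secondary")
    layout = ParamLayout(spec, design)
    rng = np.random.default_rng(42)
    x = rng.normal(size=layout.n_params)
    params = layout.unpack(x)

    got = negative_log_likelihood(params, m, spec)

    p_primary = [
        [params.p[t, : design.n_secondary[t], 0].tolist()]
        for t in range(2)
    ]
    blocks = [rows[:, sl] for sl in design.column_slices]
    pstars = primary_pstar(params, design)
    ph = (np.array([[1, 1], [1, 0], [1, 1]]))
    want = closed_nll_oracle(blocks, params.f0, p_primary) + open_nll_oracle(
        ph, params.S, params.gamma_dp, params.gamma_p, pstars
    )
    assert got == pytest.approx(want, abs=1e-10)


@pytest.mark.parametrize("emigration", ["none", "random", "markovian"])
@pytest.mark.parametrize("draw", range(3))
def test_random_micro_matrices_match_enumeration(emigration, draw):
    """Random <=4-animal matrices across emigration structures."""
    design = SamplingDesign.from_counts([2, 2])
    rng = np.random.default_rng(100 * draw + hash(emigration) % 50)
    det = (rng.random((4, 4)) < 0.5).astype(np.uint8)
    det[det.sum(axis=1) == 0, 0] = 1
    m = CaptureMatrix(design, tuple("abcd"), det)
    spec = RDModelSpec(True, emigration, "primary_x_secondary")
    layout = ParamLayout(spec, design)
    params = layout.unpack(rng.normal(size=layout.n_params))

    got = negative_log_likelihood(params, m, spec)

    blocks = [det[:, sl] for sl in design.column_slices]
    p_primary = [[params.p[t, :2, 0].tolist()] for t in range(2)]
    ph = np.column_stack([b.any(axis=1).astype(int) for b in blocks])
    want = closed_nll_oracle(blocks, params.f0, p_primary) + open_nll_oracle(
        ph, params.S, params.gamma_dp, params.gamma_p,
        primary_pstar(params, design),
    )
    assert got == pytest.approx(want, abs=1e-10)


def test_mixture_likelihood_matches_enumeration():
    design = SamplingDesign.from_counts([2, 2])
    det = np.array([[1, 1, 0, 1], [1, 0, 0, 0], [0, 1, 1, 0]], dtype=np.uint8)
    m = CaptureMatrix(design, ("a", "b", "c"), det)
    spec = RDModelSpec(False, "random", "constant", "mixture2")
    layout = ParamLayout(spec, design)
    rng = np.random.default_rng(7)
    params = layout.unpack(rng.normal(size=layout.n_params))

    got = negative_log_likelihood(params, m, spec)

    blocks = [det[:, sl] for sl in design.column_slices]
    p_primary = [
        [params.p[t, :2, 0].tolist(), params.p[t, :2, 1].tolist()]
        for t in range(2)
    ]
    ph = np.column_stack([b.any(axis=1).astype(int) for b in blocks])
    want = closed_nll_oracle(
        blocks, params.f0, p_primary, pi=params.pi
    ) + open_nll_oracle(
        ph, params.S, params.gamma_dp, params.gamma_p,
        primary_pstar(params, design),
    )
    assert got == pytest.approx(want, abs=1e-10)


def test_row_order_invariance(design_striped):
    from conftest import random_matrix

    m = random_matrix(design_striped, 30, seed=9)
    spec = RDModelSpec(False, "random", "secondary_index")
    layout = ParamLayout(spec, design_striped)
    params = layout.unpack(np.random.default_rng(1).normal(size=layout.n_params))
    base = negative_log_likelihood(params, m, spec)
    perm = np.random.default_rng(2).permutation(m.n_individuals)
    m2 = CaptureMatrix(
        design_striped, tuple(m.individual_ids[i] for i in perm), m.detections[perm]
    )
    assert negative_log_likelihood(params, m2, spec) == pytest.approx(base, abs=1e-9)


def test_open_component_reduces_to_cjs():
    """One secondary per primary, no emigration: open part == CJS."""
    design = SamplingDesign.from_counts([1, 1, 1, 1])
    rng = np.random.default_rng(5)
    det = (rng.random((12, 4)) < 0.5).astype(np.uint8)
    det[det.sum(axis=1) == 0, 0] = 1
    m = CaptureMatrix(design, tuple(f"i{j}" for j in range(12)), det)
    spec = RDModelSpec(True, "none", "primary")
    layout = ParamLayout(spec, design)
    params = layout.unpack(rng.normal(size=layout.n_params))

    from rdcapture.likelihood import RDData, _open_nll

    got = _open_nll(RDData.from_matrix(m), params)
    want = cjs_nll_oracle(
        det.tolist(), params.S.tolist(), params.p[:, 0, 0].tolist()
    )
    assert got == pytest.approx(want, abs=1e-10)


class TestCountParameters:
    """Structural parameter counts for the published designs."""

    @pytest.mark.parametrize(
        "tv, emi, expected",
        [(False, "none", 25), (False, "random", 26), (False, "markovian", 27),
         (True, "none", 28), (True, "random", 29), (True, "markovian", 30)],
    )
    def test_full_detection_striped(self, design_striped, tv, emi, expected):
        spec = RDModelSpec(tv, emi, "primary_x_secondary")
        assert count_parameters(spec, design_striped) == expected

    @pytest.mark.parametrize(
        "tv, emi, expected",
        [(False, "none", 10), (False, "random", 11), (False, "markovian", 12),
         (True, "random", 14)],
    )
    def test_secondary_index_striped(self, design_striped, tv, emi, expected):
        spec = RDModelSpec(tv, emi, "secondary_index")
        assert count_parameters(spec, design_striped) == expected

    def test_matches_layout_length(self, design_striped):
        for spec in (
            RDModelSpec(False, "random", "constant", "mixture2"),
            RDModelSpec(True, "markovian", "primary"),
        ):
            layout = ParamLayout(spec, design_striped)
            assert layout.n_params == count_parameters(spec, design_striped)


def test_parameter_domain_errors(tiny_matrix):
    spec = RDModelSpec(False, "none", "constant")
    params = _params(spec, tiny_matrix.design)
    params.f0 = np.array([-1.0, 1.0])
    with pytest.raises(ValueError):
        negative_log_likelihood(params, tiny_matrix, spec)
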