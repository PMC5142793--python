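"""Robust-design composite likelihood.

The objective combines, with shared detection parameters:

(a) one full closed-population likelihood per primary occasion
    (Otis-style Mt, optionally with a two-class finite mixture), in the
    f0 parameterization ``N_t = n_t + f0_t``; and
(b) an open component over primary-level (collapsed) histories,
    conditional on first detection, evaluated by the forward algorithm of
    a three-state hidden chain {inside, outside, dead} with transitions
    driven by apparent survival S and the temporary-emigration pair
    (gamma'', gamma'), and emission probability p*_t (detected at least
    once within primary t) when inside.

Additive constants (multinomial coefficients over observed histories) are
dropped; they cancel in likelihood ratios, AICc differences and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, logit

from .capture import CaptureMatrix, collapse_to_primary
from .design import SamplingDesign
from .models import RDModelSpec, count_parameters

_TINY = 1e-300


def pstar(p_row, pi: float | None = None, p_row2=None) -> float:
    """Probability of >=1 detection within a primary occasion.

    ``1 - prod_s (1 - p_s)`` for a single detection class; with a second
    class, the pi-weighted average of the per-class values.
    """
    p = np.asarray(p_row, dtype=float)
    if p.size == 0:
        raise ValueError("pstar needs at least one secondary occasion")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("detection probabilities must be in [0, 1]")
    one = 1.0 - np.prod(1.0 - p)
    if p_row2 is None:
        return float(one)
    if pi is None:
        raise ValueError("mixture pstar needs the mixing proportion pi")
    p2 = np.asarray(p_row2, dtype=float)
    two = 1.0 - np.prod(1.0 - p2)
    return float(pi * one + (1.0 - pi) * two)


@dataclass
class RDParams:
    """Real-scale parameter values for one model structure.

    Arrays are laid out over the design: ``S``, ``gamma_dp`` (gamma''),
    ``gamma_p`` (gamma') have one entry per interval; ``p`` has shape
    (T, max_secondaries, n_classes) with NaN padding for primaries with
    fewer secondaries; ``f0`` one entry per primary.  ``pi`` is the
    proportion in detection class 1 (1.0 when there is no mixture).
    """

    S: np.ndarray
    gamma_dp: np.ndarray
    gamma_p: np.ndarray
    p: np.ndarray
    f0: np.ndarray
    pi: float = 1.0

    def validate(self) -> None:
        for name in ("S", "gamma_dp", "gamma_p"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        pv = self.p[np.isfinite(self.p)]
        if np.any((pv < 0) | (pv > 1)):
            raise ValueError("p outside [0, 1]")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi outside [0, 1]")
        if np.any(self.f0 < 0):
            raise ValueError("f0 must be non-negative")


class ParamLayout:
    """Mapping between a flat link-scale vector and :class:`RDParams`.

    Probabilities live on the logit scale and f0 on the log scale, so the
    optimizer works on an unconstrained vector.
    """

    def __init__(self, spec: RDModelSpec, design: SamplingDesign):
        self.spec = spec
        self.design = design
        T = design.n_primary
        k = design.n_secondary
        self.T, self.k, self.kmax = T, k, max(k)
        self.C = spec.n_classes

        self.n_S = 0 if T == 1 else ((T - 1) if spec.survival_time_varying else 1)
        self.n_g = (
            0
            if T == 1
            else {"none": 0, "random": 1, "markovian": 2}[spec.emigration]
        )
        self.p_block = {
            "constant": 1,
            "secondary_index": self.kmax,
            "primary": T,
            "primary_x_secondary": sum(k),
        }[spec.detection]
        self.n_pi = 1 if self.C == 2 else 0
        self.n_f0 = T
        sizes = [self.n_S, self.n_g, self.p_block * self.C, self.n_pi, self.n_f0]
        edges = np.concatenate([[0], np.cumsum(sizes)])
        self.sl_S = slice(edges[0], edges[1])
        self.sl_g = slice(edges[1], edges[2])
        self.sl_p = slice(edges[2], edges[3])
        self.sl_pi = slice(edges[3], edges[4])
        self.sl_f0 = slice(edges[4], edges[5])
        self.n_params = int(edges[5])
        assert self.n_params == count_parameters(spec, design)

        # index map from (t, s) to position within one detection block
        idx = np.full((T, self.kmax), -1, dtype=int)
        pos = 0
        for t in range(T):
            for s in range(k[t]):
                if spec.detection == "constant":
                    idx[t, s] = 0
                elif spec.detection == "secondary_index":
                    idx[t, s] = s
                elif spec.detection == "primary":
                    idx[t, s] = t
                else:
                    idx[t, s] = pos
                    pos += 1
        self._p_index = idx

    # -- vector -> real-scale params ------------------------------------
    def unpack(self, x: np.ndarray) -> RDParams:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector has length {x.size}, expected {self.n_params}"
            )
        T, kmax, C = self.T, self.kmax, self.C
        n_int = max(T - 1, 0)

        if self.n_S == 0:
            S = np.ones(n_int)
        elif self.n_S == 1:
            S = np.full(n_int, expit(x[self.sl_S][0]))
        else:
            S = expit(x[self.sl_S])

        g = x[self.sl_g]
        if self.spec.emigration == "none" or T == 1:
            gdp = np.zeros(n_int)
            gp = np.zeros(n_int)
        elif self.spec.emigration == "random":
            gdp = np.full(n_int, expit(g[0]))
            gp = gdp.copy()
        else:
            gdp = np.full(n_int, expit(g[0]))
            gp = np.full(n_int, expit(g[1]))

        p = np.full((T, kmax, C), np.nan)
        blocks = expit(x[self.sl_p]).reshape(C, self.p_block)
        for t in range(T):
            for s in range(self.k[t]):
                p[t, s, :] = blocks[:, self._p_index[t, s]]

        pi = float(expit(x[self.sl_pi][0])) if self.n_pi else 1.0
        f0 = np.exp(x[self.sl_f0])
        return RDParams(S=S, gamma_dp=gdp, gamma_p=gp, p=p, f0=f0, pi=pi)

    # -- real-scale params -> vector ------------------------------------
    def pack(self, params: RDParams) -> np.ndarray:
        x = np.zeros(self.n_params)
        if self.n_S == 1:
            x[self.sl_S] = logit(np.clip(params.S[0], 1e-12, 1 - 1e-12))
        elif self.n_S > 1:
            x[self.sl_S] = logit(np.clip(params.S, 1e-12, 1 - 1e-12))
        if self.n_g == 1:
            x[self.sl_g] = logit(np.clip(params.gamma_dp[0], 1e-12, 1 - 1e-12))
        elif self.n_g == 2:
            x[self.sl_g] = logit(
                np.clip([params.gamma_dp[0], params.gamma_p[0]], 1e-12, 1 - 1e-12)
            )
        blocks = np.zeros((self.C, self.p_block))
        for t in range(self.T):
            for s in range(self.k[t]):
                blocks[:, self._p_index[t, s]] = params.p[t, s, :]
        x[self.sl_p] = logit(np.clip(blocks.ravel(), 1e-12, 1 - 1e-12))
        if self.n_pi:
            x[self.sl_pi] = logit(np.clip(params.pi, 1e-12, 1 - 1e-12))
        x[self.sl_f0] = np.log(np.maximum(params.f0, 1e-12))
        return x


@dataclass
class RDData:
    """Sufficient statistics of a capture matrix for fast likelihood evaluation."""

    design: SamplingDesign
    n_individuals: int
    n_t: np.ndarray  # detected per primary
    x_ts: list[np.ndarray]  # detections per secondary, per primary
    sec_hists: list[tuple[np.ndarray, np.ndarray]]  # unique within-primary histories + counts
    prim_hists: np.ndarray  # unique collapsed histories (H, T)
    prim_counts: np.ndarray  # multiplicity of each collapsed history
    first: np.ndarray  # first detected primary per unique history

    @classmethod
    def from_matrix(cls, m: CaptureMatrix) -> "RDData":
        design = m.design
        T = design.n_primary
        n_t = np.zeros(T, dtype=int)
        x_ts, sec_hists = [], []
        for t in range(T):
            block = m.primary_block(t)
            caught = block[block.any(axis=1)]
            n_t[t] = caught.shape[0]
            x_ts.append(caught.sum(axis=0).astype(float))
            uniq, counts = np.unique(caught, axis=0, return_counts=True)
            sec_hists.append((uniq.astype(float), counts.astype(float)))
        ph = collapse_to_primary(m).detections
        uniq, counts = np.unique(ph, axis=0, return_counts=True)
        first = uniq.argmax(axis=1)
        return cls(
            design=design,
            n_individuals=m.n_individuals,
            n_t=n_t,
            x_ts=x_ts,
            sec_hists=sec_hists,
            prim_hists=uniq,
            prim_counts=counts.astype(float),
            first=first,
        )


def _log(v):
    return np.log(np.maximum(v, _TINY))


def _closed_nll(data: RDData, params: RDParams, mixture: bool) -> float:
    """Negative log of the per-primary closed-population components."""
    total = 0.0
    for t in range(data.design.n_primary):
        k = data.design.n_secondary[t]
        n = float(data.n_t[t])
        f0 = params.f0[t]
        N = n + f0
        ll = gammaln(N + 1.0) - gammaln(f0 + 1.0)
        if not mixture:
            p = params.p[t, :k, 0]
            x = data.x_ts[t]
            ll += float(np.sum(x * _log(p) + (N - x) * _log(1.0 - p)))
        else:
            pi = np.array([params.pi, 1.0 - params.pi])
            p = params.p[t, :k, :]  # (k, 2)
            hists, counts = data.sec_hists[t]
            # P(h | class c) for every unique history
            lph = hists @ _log(p) + (1.0 - hists) @ _log(1.0 - p)  # (H, 2)
            ll += float(np.sum(counts * _log(np.exp(lph) @ pi)))
            miss = np.exp(np.sum(_log(1.0 - p), axis=0)) @ pi
            ll += f0 * _log(miss)
        total -= ll
    return total


def primary_pstar(params: RDParams, design: SamplingDesign) -> np.ndarray:
    """p*_t (detected >=1 within primary t), mixture-weighted if needed."""
    T = design.n_primary
    out = np.zeros(T)
    for t in range(T):
        k = design.n_secondary[t]
        p = params.p[t, :k, :]
        per_class = 1.0 - np.prod(1.0 - p, axis=0)  # (C,)
        if p.shape[1] == 2:
            out[t] = params.pi * per_class[0] + (1.0 - params.pi) * per_class[1]
        else:
            out[t] = per_class[0]
    return out


def _open_nll(data: RDData, params: RDParams) -> float:
    """Negative log of the open component (forward algorithm)."""
    T = data.design.n_primary
    if T == 1:
        return 0.0
    ps = primary_pstar(params, data.design)
    # transition matrices, one per interval: states (inside, outside, dead)
    mats = []
    for j in range(T - 1):
        S, gdp, gp = params.S[j], params.gamma_dp[j], params.gamma_p[j]
        mats.append(
            np.array(
                [
                    [S * (1 - gdp), S * gdp, 1 - S],
                    [S * (1 - gp), S * gp, 1 - S],
                    [0.0, 0.0, 1.0],
                ]
            )
        )
    total = 0.0
    for h, c, f in zip(data.prim_hists, data.prim_counts, data.first):
        alpha = np.array([1.0, 0.0, 0.0])
        loglik = 0.0
        for t in range(f + 1, T):
            alpha = alpha @ mats[t - 1]
            if h[t]:
                alpha = np.array([alpha[0] * ps[t], 0.0, 0.0])
            else:
                alpha = alpha * np.array([1.0 - ps[t], 1.0, 1.0])
            # scale to avoid underflow on long histories
            norm = alpha.sum()
            loglik += _log(norm)
            if norm > _TINY:
                alpha = alpha / norm
        total -= c * loglik
    return total


def negative_log_likelihood(
    params: RDParams,
    m: CaptureMatrix | RDData,
    spec: RDModelSpec,
) -> float:
    """Composite negative log-likelihood (closed x open, shared p)."""
    data = m if isinstance(m, RDData) else RDData.from_matrix(m)
    params.validate()
    if params.p.shape != (data.design.n_primary, max(data.design.n_secondary), spec.n_classes):
        raise ValueError("parameter array shape does not match spec/design")
    if spec.emigration == "none" and (
        np.any(params.gamma_dp != 0) or np.any(params.gamma_p != 0)
    ):
        raise ValueError("emigration='none' forces gamma''=gamma'=0")
    if spec.emigration == "random" and not np.allclose(
        params.gamma_dp, params.gamma_p
    ):
        raise ValueError("emigration='random' forces gamma''=gamma'")
    mixture = spec.n_classes == 2
    return _closed_nll(data, params, mixture) + _open_nll(data, params)


def nll_vector(x: np.ndarray, data: RDData, layout: ParamLayout) -> float:
    """Objective on the link scale (fast path used by the optimizer)."""
    params = layout.unpack(x)
    val = _closed_nll(data, params, layout.C == 2) + _open_nll(data, params)
    return val if np.isfinite(val) else 1e12
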