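"""Model ranking by (Q)AICc, Akaike weights, and model averaging.

When the goodness-of-fit test indicates overdispersion, the variance
inflation factor c-hat converts AICc into QAICc (deviance divided by
c-hat).  Estimates from closely competing models are combined with
Akaike weights, with the unconditional standard error of Burnham &
Anderson that adds the between-model spread to the within-model
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capture import CaptureMatrix
from .fit import FitResult, fit_model
from .likelihood import RDData
from .models import RDModelSpec, default_model_grid


def information_criterion(
    loglik: float, K: int, n_eff: int, chat: float = 1.0
) -> float:
    """AICc (chat=1) or QAICc: -2 loglik / chat + 2K + 2K(K+1)/(n_eff-K-1)."""
    if chat < 1.0:
        raise ValueError("chat must be >= 1 (no variance deflation)")
    if n_eff <= K + 1:
        raise ValueError(
            f"effective sample size {n_eff} too small for K={K} parameters"
        )
    return -2.0 * loglik / chat + 2.0 * K + 2.0 * K * (K + 1) / (n_eff - K - 1)


def akaike_weights(criteria) -> np.ndarray:
    """w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    c = np.asarray(criteria, dtype=float)
    if c.size == 0 or not np.any(np.isfinite(c)):
        raise ValueError("need at least one finite criterion value")
    delta = c - np.nanmin(c)
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


@dataclass
class ModelTable:
    """Ranked model-selection table (ascending criterion)."""

    frame: pd.DataFrame  # model, K, criterion, delta, weight
    chat: float
    criterion_name: str
    results: list[FitResult]

    def best(self) -> FitResult:
        return self.results[0]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def rank_models(results: list[FitResult], chat: float = 1.0) -> ModelTable:
    """Build the (Q)AICc table for a collection of fitted models."""
    crit = np.array(
        [information_criterion(r.loglik, r.K, r.n_eff, chat) for r in results]
    )
    order = np.argsort(crit, kind="stable")
    crit = crit[order]
    ordered = [results[i] for i in order]
    w = akaike_weights(crit)
    name = "QAICc" if chat > 1.0 else "AICc"
    frame = pd.DataFrame(
        {
            "model": [r.label for r in ordered],
            "n_par": [r.K for r in ordered],
            name: crit,
            f"delta_{name}": crit - crit[0],
            "weight": w,
            "converged": [r.converged for r in ordered],
        }
    )
    return ModelTable(frame=frame, chat=chat, criterion_name=name, results=ordered)


def fit_model_grid(
    m: CaptureMatrix,
    grid: list[RDModelSpec] | None = None,
    chat: float = 1.0,
    n_starts: int = 5,
    seed: int = 0,
    n_eff: int | None = None,
) -> ModelTable:
    """Fit every model in the grid (default: the 30-model set) and rank."""
    if grid is None:
        grid = default_model_grid()
    if not grid:
        raise ValueError("empty model grid")
    data = RDData.from_matrix(m)
    results = [
        fit_model(data, spec, n_starts=n_starts, seed=seed + i, n_eff=n_eff)
        for i, spec in enumerate(grid)
    ]
    return rank_models(results, chat=chat)


def _collect(result: FitResult, parameter: str) -> tuple[float, float] | None:
    """(estimate, SE) of a real-scale parameter, with structural constants
    for parameters a simpler model fixes (gamma=0 under no emigration)."""
    tab = result.table
    row = tab[tab["parameter"] == parameter]
    if not row.empty:
        return float(row["estimate"].iloc[0]), float(row["se"].iloc[0])
    if parameter in ("gamma", "gamma''", "gamma'"):
        if result.spec.emigration == "none":
            return 0.0, 0.0
        if result.spec.emigration == "random" and parameter in ("gamma''", "gamma'"):
            return _collect(result, "gamma")
        if result.spec.emigration == "markovian" and parameter == "gamma":
            return _collect(result, "gamma'")
    if parameter == "S" and result.spec.survival_time_varying:
        return None
    return None


def model_average(
    results: list[FitResult],
    weights,
    parameter: str,
    mode: str = "all",
    top_k: int | None = None,
    delta_threshold: float | None = None,
    criteria=None,
) -> tuple[float, float]:
    """Weighted model average of one real-scale parameter.

    Returns (theta_bar, unconditional SE) with
    ``SE = sum_i w_i sqrt(var_i + (theta_i - theta_bar)^2)``.

    ``mode='top_k'`` keeps the ``top_k`` best models (by ``criteria``,
    or by weight), ``mode='delta_threshold'`` keeps models within
    ``delta_threshold`` of the best criterion; weights are renormalized
    over the kept subset.
    """
    w = np.asarray(weights, dtype=float)
    if len(results) != w.size:
        raise ValueError("results and weights length mismatch")
    keep = np.arange(w.size)
    if mode == "top_k":
        if top_k is None:
            raise ValueError("top_k required")
        order = (
            np.argsort(np.asarray(criteria)) if criteria is not None else np.argsort(-w)
        )
        keep = order[:top_k]
    elif mode == "delta_threshold":
        if delta_threshold is None or criteria is None:
            raise ValueError("delta_threshold and criteria required")
        c = np.asarray(criteria, dtype=float)
        keep = np.flatnonzero(c - c.min() <= delta_threshold)
    elif mode != "all":
        raise ValueError(f"unknown mode {mode!r}")

    pairs, wk = [], []
    for i in keep:
        got = _collect(results[i], parameter)
        if got is not None:
            pairs.append(got)
            wk.append(w[i])
    if not pairs:
        raise ValueError(f"no model in the subset estimates {parameter!r}")
    wk = np.asarray(wk)
    wk = wk / wk.sum()
    est = np.array([p[0] for p in pairs])
    se = np.array([p[1] for p in pairs])
    theta = float(np.sum(wk * est))
    unc_se = float(np.sum(wk * np.sqrt(se**2 + (est - theta) ** 2)))
    return theta, unc_se
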