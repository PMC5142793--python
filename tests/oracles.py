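"""Independent brute-force oracles used to check the fast implementations.

Everything here is written for clarity, not speed: explicit loops,
explicit enumeration of latent state paths, dense grid searches.  None of
it shares code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INSIDE, OUTSIDE, DEAD = 0, 1, 2


def mixture_history_prob(hist, p_classes, pi) -> float:
    """P(secondary history) as a pi-weighted sum over detection classes."""
    total = 0.0
    for c, w in enumerate((pi, 1.0 - pi)[: len(p_classes)]):
        prob = 1.0
        for x, p in zip(hist, p_classes[c]):
            prob *= p if x else (1.0 - p)
        total += w * prob
    return total


def closed_nll_oracle(blocks, f0, p_primary, pi=1.0) -> float:
    """Closed-component NLL by direct evaluation, one primary at a time.

    blocks: list over primaries of 2-D 0/1 arrays (all individuals).
    p_primary: list over primaries of per-class detection lists
               [[p_s...], ...] (one inner list per class).
    """
    nll = 0.0
    for t, block in enumerate(blocks):
        caught = [row for row in block if any(row)]
        n = len(caught)
        N = n + f0[t]
        ll = math.lgamma(N + 1.0) - math.lgamma(f0[t] + 1.0)
        for row in caught:
            ll += math.log(mixture_history_prob(row, p_primary[t], pi))
        miss = mixture_history_prob([0] * len(p_primary[t][0]), p_primary[t], pi)
        ll += f0[t] * math.log(miss) if miss > 0 else (0.0 if f0[t] == 0 else -math.inf)
        nll -= ll
    return nll


def open_nll_oracle(primary_histories, S, gamma_dp, gamma_p, pstars) -> float:
    """Open-component NLL by exhaustive enumeration of latent state paths.

    Each animal enters at its first detected primary in state INSIDE; every
    later occasion can be INSIDE, OUTSIDE or DEAD.  Transition and emission
    probabilities are multiplied along each path and paths are summed.
    """
    T = len(pstars)
    nll = 0.0
    for h in primary_histories:
        f = next(t for t, x in enumerate(h) if x)
        lik = 0.0
        for path in itertools.product((INSIDE, OUTSIDE, DEAD), repeat=T - f - 1):
            states = (INSIDE,) + path
            prob = 1.0
            for j in range(len(states) - 1):
                t_int = f + j  # interval index
                a, b = states[j], states[j + 1]
                if a == DEAD:
                    prob *= 1.0 if b == DEAD else 0.0
                elif b == DEAD:
                    prob *= 1.0 - S[t_int]
                elif a == INSIDE:
                    prob *= S[t_int] * (gamma_dp[t_int] if b == OUTSIDE else 1 - gamma_dp[t_int])
                else:
                    prob *= S[t_int] * (gamma_p[t_int] if b == OUTSIDE else 1 - gamma_p[t_int])
            for j, st in enumerate(states[1:], start=1):
                t = f + j
                if h[t]:
                    prob *= pstars[t] if st == INSIDE else 0.0
                else:
                    prob *= (1.0 - pstars[t]) if st == INSIDE else 1.0
            lik += prob
        nll -= math.log(lik) if lik > 0 else -math.inf
    return nll


def cjs_nll_oracle(histories, phi, p) -> float:
    """Cormack-Jolly-Seber conditional NLL (recursive chi formulation).

    histories: 0/1 primary-level rows; phi: survival per interval;
    p: detection per occasion (occasions 2..T enter the likelihood).
    """
    T = len(p)
    chi = [1.0] * T  # chi[t]: P(never seen after t | alive at t)
    for t in range(T - 2, -1, -1):
        chi[t] = (1 - phi[t]) + phi[t] * (1 - p[t + 1]) * chi[t + 1]
    nll = 0.0
    for h in histories:
        f = next(t for t, x in enumerate(h) if x)
        last = max(t for t, x in enumerate(h) if x)
        ll = 0.0
        for t in range(f, last):
            ll += math.log(phi[t])
            ll += math.log(p[t + 1] if h[t + 1] else 1 - p[t + 1])
        ll += math.log(chi[last])
        nll -= ll
    return nll


def mt_grid_mle(histories, n_grid=400):
    """Closed Mt MLE by nested grid refinement over (f0, p_1..p_k).

    Independent of the package optimizer: coordinate-wise dense grids,
    iterated to convergence.
    """
    k = len(histories[0])
    n = len(histories)
    x = [sum(h[s] for h in histories) for s in range(k)]

    def nll(f0, p):
        N = n + f0
        ll = math.lgamma(N + 1) - math.lgamma(f0 + 1)
        for s in range(k):
            ll += x[s] * math.log(p[s]) + (N - x[s]) * math.log(1 - p[s])
        return -ll

    f0, p = 1.0, [0.5] * k
    for _ in range(200):
        # profile each p_s on a dense grid
        for s in range(k):
            grid = np.linspace(1e-4, 1 - 1e-4, n_grid)
            vals = [nll(f0, p[:s] + [g] + p[s + 1 :]) for g in grid]
            p[s] = float(grid[int(np.argmin(vals))])
        grid = np.linspace(1e-6, 5 * n, n_grid)
        vals = [nll(g, p) for g in grid]
        f0_new = float(grid[int(np.argmin(vals))])
        if abs(f0_new - f0) < 1e-10:
            f0 = f0_new
            break
        f0 = f0_new
    # local refinement
    for _ in range(60):
        for s in range(k):
            lo, hi = max(p[s] - 0.01, 1e-6), min(p[s] + 0.01, 1 - 1e-6)
            grid = np.linspace(lo, hi, 201)
            vals = [nll(f0, p[:s] + [g] + p[s + 1 :]) for g in grid]
            p[s] = float(grid[int(np.argmin(vals))])
        lo, hi = max(f0 - 0.05, 0.0), f0 + 0.05
        grid = np.linspace(lo + 1e-9, hi, 201)
        vals = [nll(g, p) for g in grid]
        f0 = float(grid[int(np.argmin(vals))])
    return f0, p, nll(f0, p)


def chi2_2x2(table) -> float:
    """Textbook Pearson chi-square for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    total = t.sum()
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    return float(((t - exp) ** 2 / exp).sum())


def slope_test_power_mc(
    n, cv, overall_change, alpha=0.05, reps=10000, rng=None
) -> float:
    """Monte-Carlo power of the one-tailed slope t-test.

    Abundance follows the linear trajectory; estimate errors are normal
    with sd = cv_i * A_i and CV scaling with sqrt(abundance).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    from scipy import stats

    t = np.arange(n, dtype=float)
    A = 1.0 + overall_change * t / (n - 1)
    cvs = cv * np.sqrt(A / A[0])
    sd = cvs * A
    tbar = t.mean()
    s_tt = ((t - tbar) ** 2).sum()
    Y = A + rng.standard_normal((reps, n)) * sd
    b = ((t - tbar) * Y).sum(axis=1) / s_tt
    a = Y.mean(axis=1) - b * tbar
    resid = Y - (a[:, None] + b[:, None] * t)
    s2 = (resid**2).sum(axis=1) / (n - 2)
    tstat = b / np.sqrt(s2 / s_tt)
    t_crit = stats.t.ppf(alpha, n - 2)
    return float((tstat < t_crit).mean())
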