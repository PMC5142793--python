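"""Contingency-table goodness-of-fit tests for primary-pooled histories.

The classical Cormack-Jolly-Seber diagnostics are computed on the
capture histories collapsed to primary occasions:

- TEST3.SR (transience): do animals encountered for the first time at
  occasion t have the same chance of ever being re-encountered as
  previously known animals?
- TEST3.Sm: among animals seen at t and seen again, do new and old
  animals share the distribution of the occasion of next encounter?
- TEST2.CT (trap dependence): conditional on being alive and present at
  t and t+1, does detection at t change the odds of detection at t+1?
- TEST2.CL: among animals not seen at t+1, does detection at t shift
  the occasion of next encounter beyond t+1?

The global statistic (TEST2 + TEST3) is the overall fit test for the
CJS model; chi2/df is the variance-inflation factor c-hat used to turn
AICc into QAICc.  Cells with expected counts below 2 are pooled
(re-encounter-time categories merged first); tables that cannot be
pooled into shape contribute zero with zero degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .capture import PrimaryHistoryMatrix

POOL_EXPECTED = 2.0


def _trim(table: np.ndarray) -> np.ndarray:
    """Drop all-zero rows and columns."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    return table


def pooled_chi2(table: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Pearson chi-square with expected-count pooling.

    Columns (re-encounter-time categories) with expected counts below
    ``POOL_EXPECTED`` are merged with their right neighbour (last column
    folds left).  A table that cannot reach valid shape is dropped:
    (0.0, 0, table).  Returns (chi2, df, pooled table).
    """
    t = _trim(np.asarray(table, dtype=float))
    while True:
        if t.shape[0] < 2 or t.shape[1] < 2:
            return 0.0, 0, t
        exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if (exp >= POOL_EXPECTED).all():
            chi2 = float(((t - exp) ** 2 / exp).sum())
            df = (t.shape[0] - 1) * (t.shape[1] - 1)
            return chi2, df, t
        if t.shape[1] > 2:
            j = int(np.argmin(exp.min(axis=0)))  # worst column
            k = j + 1 if j + 1 < t.shape[1] else j - 1
            t[:, min(j, k)] += t[:, max(j, k)]
            t = np.delete(t, max(j, k), axis=1)
        elif t.shape[0] > 2:
            i = int(np.argmin(exp.min(axis=1)))
            k = i + 1 if i + 1 < t.shape[0] else i - 1
            t[min(i, k), :] += t[max(i, k), :]
            t = np.delete(t, max(i, k), axis=0)
        else:
            return 0.0, 0, t


def _signed_z(table: np.ndarray, chi2: float) -> float:
    """Direction of a 2x2 effect: positive when cell (0,0) exceeds its
    expectation (more 'new, never re-seen' = transience; more 'seen at t,
    seen at t+1' = trap-happiness)."""
    if table.shape != (2, 2) or table.sum() == 0:
        return 0.0
    exp00 = table.sum(axis=1)[0] * table.sum(axis=0)[0] / table.sum()
    return float(np.sign(table[0, 0] - exp00) * np.sqrt(chi2))


@dataclass
class GofComponent:
    name: str
    chi2: float
    df: int
    p_value: float
    signed_z: float | None = None
    tables: list[np.ndarray] = field(default_factory=list)


@dataclass
class GofReport:
    components: dict[str, GofComponent]
    chi2: float
    df: int
    p_value: float

    def frame(self) -> pd.DataFrame:
        rows = [
            (c.name, c.chi2, c.df, c.p_value)
            for c in self.components.values()
        ] + [("GLOBAL", self.chi2, self.df, self.p_value)]
        return pd.DataFrame(rows, columns=["component", "chi2", "df", "p_value"])


def _first_last(ph: np.ndarray):
    first = ph.argmax(axis=1)
    T = ph.shape[1]
    last = T - 1 - ph[:, ::-1].argmax(axis=1)
    return first, last


def gof_tests(ph: PrimaryHistoryMatrix) -> GofReport:
    """All four components plus the global test on primary-pooled data."""
    m = np.asarray(ph.detections, dtype=int)
    n, T = m.shape
    if T < 3:
        raise ValueError("goodness-of-fit tests need at least 3 primary occasions")
    first, last = _first_last(m)
    seen_after = np.zeros((n, T), dtype=bool)  # any detection strictly after t
    nxt = np.full((n, T), -1)  # occasion of next encounter after t
    for t in range(T - 2, -1, -1):
        seen_after[:, t] = seen_after[:, t + 1] | (m[:, t + 1] == 1)
        nxt[:, t] = np.where(m[:, t + 1] == 1, t + 1, nxt[:, t + 1])

    comp: dict[str, GofComponent] = {}

    # TEST3.SR: new vs old x (re-seen later, never again), occasions 2..T-1
    chi_sum, df_sum, zs, tabs = 0.0, 0, [], []
    for t in range(1, T - 1):
        at_t = m[:, t] == 1
        new = at_t & (first == t)
        old = at_t & (first < t)
        tab = np.array(
            [
                [np.sum(new & ~seen_after[:, t]), np.sum(new & seen_after[:, t])],
                [np.sum(old & ~seen_after[:, t]), np.sum(old & seen_after[:, t])],
            ],
            dtype=float,
        )
        chi2, df, pooled = pooled_chi2(tab)
        if df:
            chi_sum += chi2
            df_sum += df
            zs.append(_signed_z(pooled, chi2))
        tabs.append(tab)
    comp["TEST3.SR"] = GofComponent(
        "TEST3.SR",
        chi_sum,
        df_sum,
        float(stats.chi2.sf(chi_sum, df_sum)) if df_sum else 1.0,
        signed_z=float(np.sum(zs) / np.sqrt(len(zs))) if zs else 0.0,
        tables=tabs,
    )

    # TEST3.Sm: among animals seen at t and re-seen, new vs old x next occasion
    chi_sum, df_sum, tabs = 0.0, 0, []
    for t in range(1, T - 1):
        sel = (m[:, t] == 1) & seen_after[:, t]
        rows = []
        for grp in (first[sel] == t, first[sel] < t):  # new, old
            nx = nxt[sel][grp, t]
            rows.append([np.sum(nx == u) for u in range(t + 1, T)])
        tab = np.array(rows, dtype=float)
        chi2, df, _ = pooled_chi2(tab)
        if df:
            chi_sum += chi2
            df_sum += df
        tabs.append(tab)
    comp["TEST3.Sm"] = GofComponent(
        "TEST3.Sm",
        chi_sum,
        df_sum,
        float(stats.chi2.sf(chi_sum, df_sum)) if df_sum else 1.0,
        tables=tabs,
    )

    # TEST2.CT: animals known alive around t..t+1 (seen at or before t and
    # after t): seen at t vs not x seen at t+1 vs not
    chi_sum, df_sum, zs, tabs = 0.0, 0, [], []
    for t in range(T - 1):
        alive = (first <= t) & seen_after[:, t]
        r_t = m[alive, t] == 1
        c_t1 = m[alive, t + 1] == 1
        tab = np.array(
            [
                [np.sum(r_t & c_t1), np.sum(r_t & ~c_t1)],
                [np.sum(~r_t & c_t1), np.sum(~r_t & ~c_t1)],
            ],
            dtype=float,
        )
        chi2, df, pooled = pooled_chi2(tab)
        if df:
            chi_sum += chi2
            df_sum += df
            zs.append(_signed_z(pooled, chi2))
        tabs.append(tab)
    comp["TEST2.CT"] = GofComponent(
        "TEST2.CT",
        chi_sum,
        df_sum,
        float(stats.chi2.sf(chi_sum, df_sum)) if df_sum else 1.0,
        signed_z=float(np.sum(zs) / np.sqrt(len(zs))) if zs else 0.0,
        tables=tabs,
    )

    # TEST2.CL: animals seen at or before t, not at t+1, seen after t+1:
    # seen at t vs not x occasion of next encounter beyond t+1
    chi_sum, df_sum, tabs = 0.0, 0, []
    for t in range(T - 2):
        sel = (first <= t) & (m[:, t + 1] == 0) & seen_after[:, t + 1]
        rows = []
        for grp in (m[sel, t] == 1, m[sel, t] == 0):
            nx = nxt[sel][grp, t + 1]
            rows.append([np.sum(nx == u) for u in range(t + 2, T)])
        tab = np.array(rows, dtype=float)
        chi2, df, _ = pooled_chi2(tab)
        if df:
            chi_sum += chi2
            df_sum += df
        tabs.append(tab)
    comp["TEST2.CL"] = GofComponent(
        "TEST2.CL",
        chi_sum,
        df_sum,
        float(stats.chi2.sf(chi_sum, df_sum)) if df_sum else 1.0,
        tables=tabs,
    )

    chi2 = sum(c.chi2 for c in comp.values())
    df = sum(c.df for c in comp.values())
    p = float(stats.chi2.sf(chi2, df)) if df else 1.0
    return GofReport(components=comp, chi2=chi2, df=df, p_value=p)


def variance_inflation(chi2: float, df: int) -> float:
    """c-hat = chi2 / df of the global goodness-of-fit test."""
    if df < 1:
        raise ValueError("variance inflation needs df >= 1")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return chi2 / df


def chat_for_qaicc(chi2: float, df: int) -> float:
    """c-hat clamped at 1 for QAICc use (no variance deflation)."""
    return max(variance_inflation(chi2, df), 1.0)
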