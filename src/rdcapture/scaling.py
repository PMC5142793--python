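"""Scaling marked abundance to total abundance.

Capture histories contain only well-marked (D1) animals, so a fitted
marked abundance Nm must be divided by the mark ratio theta (share of
marked animals in the population, estimated from high-quality photos):
``Ntot = Nm / theta``.  Variance follows the standard ratio-correction

    Var(Ntot) = Ntot^2 ( Var(Nm)/Nm^2 + (1 - theta) / (n theta) )

with n the number of animals theta was estimated from, and 95% CIs are
log-normal, ``(Ntot/C, Ntot*C)`` with
``C = exp(1.96 sqrt(ln(1 + CV^2)))``.

When several species occur in mixed groups and cannot be told apart in
capture photos, the pooled estimate is partitioned by species
proportions; per-species CVs combine the component CVs in quadrature
(root sum of squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

_Z = 1.959963984540054


@dataclass(frozen=True)
class ThetaEstimate:
    """Mark ratio: proportion of distinctively marked (D1) individuals."""

    theta: float
    n: int  # number of identified animals the ratio is based on

    def __post_init__(self) -> None:
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must be in (0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class AbundanceEstimate:
    """Point abundance with SE and log-normal 95% CI."""

    N: float
    se: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("abundance must be positive")
        if self.se < 0:
            raise ValueError("SE must be non-negative")
        if not (self.ci_low <= self.N <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    @property
    def cv(self) -> float:
        return self.se / self.N

    @classmethod
    def from_point_se(cls, N: float, se: float) -> "AbundanceEstimate":
        low, high = lognormal_ci(N, se)
        return cls(N=N, se=se, ci_low=low, ci_high=high)


@dataclass(frozen=True)
class SpeciesProportions:
    """Species composition of a mixed-species population with CVs."""

    labels: tuple[str, ...]
    proportions: tuple[float, ...]
    cvs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if len(self.labels) != p.size or len(self.cvs) != p.size:
            raise ValueError("labels, proportions and cvs must align")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must be in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {p.sum()}, expected 1")
        if any(cv < 0 for cv in self.cvs):
            raise ValueError("CVs must be non-negative")


def total_abundance(Nm: float, theta: ThetaEstimate) -> float:
    """Point estimate of total abundance, Ntot = Nm / theta."""
    if Nm <= 0:
        raise ValueError("marked abundance must be positive")
    return Nm / theta.theta


def total_abundance_variance(
    Ntot: float, Nm: float, var_Nm: float, theta: ThetaEstimate
) -> float:
    """Var(Ntot) combining CR variance and binomial mark-ratio variance."""
    if Ntot <= 0 or Nm <= 0 or var_Nm < 0:
        raise ValueError("invalid inputs")
    return Ntot**2 * (var_Nm / Nm**2 + (1.0 - theta.theta) / (theta.n * theta.theta))


def lognormal_ci(N: float, se: float) -> tuple[float, float]:
    """Log-normal 95% CI: (N/C, N*C), C = exp(1.96 sqrt(ln(1 + (se/N)^2)))."""
    if N <= 0:
        raise ValueError("N must be positive")
    if se < 0:
        raise ValueError("SE must be non-negative")
    C = math.exp(_Z * math.sqrt(math.log1p((se / N) ** 2)))
    return N / C, N * C


def scale_to_total(
    Nm: float, se_Nm: float, theta: ThetaEstimate
) -> AbundanceEstimate:
    """Marked abundance with SE -> total abundance with SE and CI."""
    N = total_abundance(Nm, theta)
    var = total_abundance_variance(N, Nm, se_Nm**2, theta)
    return AbundanceEstimate.from_point_se(N, math.sqrt(var))


def combined_cv(cv_species: float, cv_distinctiveness: float, cv_N: float) -> float:
    """Root-sum-of-squares combination of independent CV components."""
    if min(cv_species, cv_distinctiveness, cv_N) < 0:
        raise ValueError("CVs must be non-negative")
    return math.sqrt(cv_species**2 + cv_distinctiveness**2 + cv_N**2)


def partition_species(
    total: AbundanceEstimate,
    props: SpeciesProportions,
    cv_distinctiveness: float = 0.0,
) -> list[tuple[str, AbundanceEstimate]]:
    """Split a pooled abundance estimate by species proportions.

    Per-species ``N = total.N * proportion``; the per-species CV combines
    the species-proportion CV, the mark-ratio (distinctiveness) CV and
    the pooled-estimate CV in quadrature, and the CI is log-normal.
    Species with proportion 0 are reported with zero-width placeholder
    handling skipped (no abundance to report).
    """
    out = []
    for label, prop, cv_sp in zip(props.labels, props.proportions, props.cvs):
        if prop == 0.0:
            continue
        N = total.N * prop
        cv = combined_cv(cv_sp, cv_distinctiveness, total.cv)
        out.append((label, AbundanceEstimate.from_point_se(N, cv * N)))
    return out


def species_table(
    per_year: dict[str, list[tuple[str, AbundanceEstimate]]]
) -> pd.DataFrame:
    """Assemble a species-by-year total-abundance table (CSV-ready)."""
    rows = []
    for year, entries in per_year.items():
        for label, est in entries:
            rows.append(
                (year, label, est.N, est.ci_low, est.ci_high, est.cv)
            )
    return pd.DataFrame(
        rows, columns=["year", "species", "N_tot", "ci_low", "ci_high", "cv"]
    )
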