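"""Generative model of a robust-design photo-identification study.

Marked animals live and die with annual apparent survival S, move in and
out of the study area as a two-state Markov chain driven by the
temporary-emigration pair (gamma'', gamma'), and are detected by
Bernoulli draws per secondary occasion only while inside.  Optionally a
two-class detection mixture assigns each animal a latent class once, and
a photographic sample is drawn on top: a binomial mark ratio theta
(marked vs all high-quality photos) and multinomial species labels for
mixed-species groups.

Every draw flows from one seed, so the same truth always produces a
bit-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .capture import CaptureMatrix
from .design import SamplingDesign

INSIDE, OUTSIDE, DEAD = 0, 1, 2


@dataclass(frozen=True)
class SimulationTruth:
    """True parameter values behind a simulated study."""

    design: SamplingDesign
    n_super: int  # marked animals in the super-population
    S: float = 0.94
    gamma_dp: float = 0.0  # gamma'': P(emigrate | was inside)
    gamma_p: float = 0.0  # gamma':  P(stay out | was outside)
    p: float | np.ndarray = 0.3  # scalar, (T, kmax), or (T, kmax, 2)
    pi: float = 1.0  # proportion in detection class 1
    p2: float | np.ndarray | None = None  # class-2 detection (mixture)
    theta: float = 1.0  # mark ratio
    species_proportions: tuple[float, ...] = (1.0,)
    species_labels: tuple[str, ...] = ("species1",)
    initial_outside_prob: float = 0.0
    recruitment_per_primary: int = 0  # animals added before each primary > 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("S", "gamma_dp", "gamma_p", "pi", "initial_outside_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not 0.0 < self.theta <= 1.0:
            raise ValueError("theta must be in (0, 1]")
        if abs(sum(self.species_proportions) - 1.0) > 1e-9:
            raise ValueError("species proportions must sum to 1")
        if self.n_super < 1:
            raise ValueError("n_super must be >= 1")


@dataclass
class SimulatedStudy:
    """Simulator output: observed matrix plus the latent truth records."""

    matrix: CaptureMatrix | None
    states: np.ndarray  # (n_total, T) in {INSIDE, OUTSIDE, DEAD}
    classes: np.ndarray  # (n_total,) detection class per animal
    detections_all: np.ndarray  # (n_total, total_secondaries), incl. never-seen
    n_inside: np.ndarray  # true marked abundance inside, per primary
    ever_detected: np.ndarray  # bool per super-population animal


def _detection_array(truth: SimulationTruth) -> np.ndarray:
    """Expand p to shape (T, kmax, 2) with NaN padding."""
    design = truth.design
    T, kmax = design.n_primary, max(design.n_secondary)
    out = np.full((T, kmax, 2), np.nan)
    p = np.asarray(truth.p, dtype=float)
    if p.ndim == 0:
        base = np.full((T, kmax), float(p))
    elif p.ndim == 2:
        base = p
    elif p.ndim == 3:
        for t in range(T):
            k = design.n_secondary[t]
            out[t, :k, :] = p[t, :k, :]
        return out
    else:
        raise ValueError("p must be scalar, (T,kmax) or (T,kmax,2)")
    p2 = truth.p2
    second = base if p2 is None else (
        np.full((T, kmax), float(p2)) if np.ndim(p2) == 0 else np.asarray(p2, float)
    )
    for t in range(T):
        k = design.n_secondary[t]
        out[t, :k, 0] = base[t, :k]
        out[t, :k, 1] = second[t, :k]
    return out


def simulate_capture_matrix(truth: SimulationTruth) -> SimulatedStudy:
    """Simulate latent states and secondary detections for one study."""
    rng = np.random.default_rng(truth.seed)
    design = truth.design
    T = design.n_primary
    p = _detection_array(truth)

    # recruitment: animals entering before primary t start OUTSIDE-of-study
    # dynamics at their entry occasion (alive, inside)
    entries = [0] * truth.n_super
    for t in range(1, T):
        entries += [t] * truth.recruitment_per_primary
    entry = np.asarray(entries)
    n_total = entry.size

    states = np.full((n_total, T), DEAD, dtype=np.int8)
    classes = (rng.random(n_total) >= truth.pi).astype(np.int8)  # 0 = class 1
    for i in range(n_total):
        e = entry[i]
        states[i, e] = (
            OUTSIDE if rng.random() < truth.initial_outside_prob else INSIDE
        )
        for t in range(e + 1, T):
            prev = states[i, t - 1]
            if prev == DEAD:
                break
            if rng.random() >= truth.S:
                states[i, t] = DEAD
                continue
            if prev == INSIDE:
                states[i, t] = OUTSIDE if rng.random() < truth.gamma_dp else INSIDE
            else:
                states[i, t] = OUTSIDE if rng.random() < truth.gamma_p else INSIDE

    det = np.zeros((n_total, design.total_secondaries), dtype=np.uint8)
    for t, sl in enumerate(design.column_slices):
        k = design.n_secondary[t]
        inside = states[:, t] == INSIDE
        probs = p[:, :k, :][t][:, classes].T  # (n_total, k)
        draws = rng.random((n_total, k)) < probs
        det[:, sl] = (draws & inside[:, None]).astype(np.uint8)

    ever = det.sum(axis=1) > 0
    ids = tuple(f"sim{i + 1}" for i in np.flatnonzero(ever))
    matrix = (
        CaptureMatrix(design, ids, det[ever]) if ever.any() else None
    )
    return SimulatedStudy(
        matrix=matrix,
        states=states,
        classes=classes,
        detections_all=det,
        n_inside=(states == INSIDE).sum(axis=0),
        ever_detected=ever,
    )


def simulate_photo_sample(
    truth: SimulationTruth, photos_per_year: int, seed: int | None = None
) -> dict:
    """Binomial marked-photo counts and multinomial species counts per year.

    Returns per-year records with ``total_photos``, ``marked_photos`` and
    ``species_counts`` (species-attributable photos per label).
    """
    if photos_per_year < 1:
        raise ValueError("photos_per_year must be >= 1")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    out = {}
    for lab in truth.design.primary_labels:
        marked = int(rng.binomial(photos_per_year, truth.theta))
        species = rng.multinomial(photos_per_year, truth.species_proportions)
        out[lab] = {
            "total_photos": photos_per_year,
            "marked_photos": marked,
            "species_counts": dict(zip(truth.species_labels, species.tolist())),
        }
    return out
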