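"""Robust-design model structures and the default model grid.

A model structure says how apparent survival S, the temporary-emigration
pair (gamma'', gamma') and detection probability p are constrained:

- survival: constant ``S(.)`` or per-interval ``S(year)``;
- emigration: ``none`` (gamma''=gamma'=0), ``random`` (gamma''=gamma',
  one shared parameter) or ``markovian`` (two parameters);
- detection: ``constant`` p(.), ``secondary_index`` p(month)/p(day)
  (one parameter per within-primary position, shared across primaries),
  ``primary`` p(year), or ``primary_x_secondary`` p(year.month)/p(day.year);
- heterogeneity: ``none``, ``mixture2`` (two latent detection classes,
  Mh) or ``mixture2_x_time`` (two classes crossed with the secondary
  index, Mth).
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import SamplingDesign

EMIGRATION = ("none", "random", "markovian")
DETECTION = ("constant", "secondary_index", "primary", "primary_x_secondary")
HETEROGENEITY = ("none", "mixture2", "mixture2_x_time")

_P_LABEL = {
    "constant": "p(.)",
    "secondary_index": "p(month)",
    "primary": "p(year)",
    "primary_x_secondary": "p(year.month)",
}


@dataclass(frozen=True)
class RDModelSpec:
    """Structure of one robust-design model."""

    survival_time_varying: bool = False
    emigration: str = "none"
    detection: str = "primary_x_secondary"
    heterogeneity: str = "none"

    def __post_init__(self) -> None:
        if self.emigration not in EMIGRATION:
            raise ValueError(f"emigration must be one of {EMIGRATION}")
        if self.detection not in DETECTION:
            raise ValueError(f"detection must be one of {DETECTION}")
        if self.heterogeneity not in HETEROGENEITY:
            raise ValueError(f"heterogeneity must be one of {HETEROGENEITY}")
        if self.heterogeneity == "mixture2" and self.detection != "constant":
            raise ValueError("mixture2 (Mh) uses detection='constant'")
        if (
            self.heterogeneity == "mixture2_x_time"
            and self.detection != "secondary_index"
        ):
            raise ValueError("mixture2_x_time (Mth) uses detection='secondary_index'")

    @property
    def n_classes(self) -> int:
        return 1 if self.heterogeneity == "none" else 2

    @property
    def label(self) -> str:
        s = "S(year)" if self.survival_time_varying else "S(.)"
        if self.heterogeneity == "mixture2":
            p = "p(mixture)"
        elif self.heterogeneity == "mixture2_x_time":
            p = "p(mixture.month)"
        else:
            p = _P_LABEL[self.detection]
        return f"{s} {p} gamma({self.emigration})"


def count_parameters(spec: RDModelSpec, design: SamplingDesign) -> int:
    """Number of structural parameters of ``spec`` under ``design``.

    f0 contributes one parameter per primary; S one (constant) or T-1
    (time-varying); emigration 0/1/2 shared parameters; p one block per
    detection class, sized by the detection structure; a mixture adds the
    mixing proportion pi.
    """
    T = design.n_primary
    k = design.n_secondary
    n = T  # f0 per primary
    if T > 1:  # open parameters exist only with >=1 interval
        n += (T - 1) if spec.survival_time_varying else 1
        n += {"none": 0, "random": 1, "markovian": 2}[spec.emigration]
    block = {
        "constant": 1,
        "secondary_index": max(k),
        "primary": T,
        "primary_x_secondary": sum(k),
    }[spec.detection]
    n += block * spec.n_classes
    if spec.n_classes == 2:
        n += 1  # pi
    return n


def default_model_grid(include_mixture: bool = True) -> list[RDModelSpec]:
    """The 30-model grid: {none,random,markovian} x {S(.),S(year)} x
    {p(.),p(month),p(year),p(year.month)} plus, with S(.), the Mh and Mth
    two-class mixture variants."""
    grid = [
        RDModelSpec(tv, emi, det, "none")
        for emi in EMIGRATION
        for tv in (False, True)
        for det in DETECTION
    ]
    if include_mixture:
        grid += [
            RDModelSpec(False, emi, det, het)
            for emi in EMIGRATION
            for det, het in (
                ("constant", "mixture2"),
                ("secondary_index", "mixture2_x_time"),
            )
        ]
    return grid


def parse_model_label(label: str) -> RDModelSpec:
    """Inverse of :attr:`RDModelSpec.label` (compact string -> spec)."""
    parts = label.split()
    if len(parts) != 3:
        raise ValueError(f"cannot parse model label {label!r}")
    s, p, g = parts
    tv = s == "S(year)"
    emigration = g[len("gamma(") : -1]
    het = "none"
    rev = {v: k for k, v in _P_LABEL.items()}
    if p == "p(mixture)":
        det, het = "constant", "mixture2"
    elif p == "p(mixture.month)":
        det, het = "secondary_index", "mixture2_x_time"
    elif p in rev:
        det = rev[p]
    else:
        raise ValueError(f"unknown detection term {p!r}")
    return RDModelSpec(tv, emigration, det, het)
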