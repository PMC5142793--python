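# rdcapture

Robust-design capture–recapture analysis for photo-identification
studies of wild populations: abundance, apparent survival and temporary
emigration from binary capture matrices, mark-ratio scaling to total
abundance, mixed-species partitioning, and trend-detection power
analysis.

## The problem

Photo-identification gives repeated "captures" of naturally marked
animals (e.g. dolphins identified by dorsal-fin nicks). Under Pollock's
robust design, sampling is organised into primary occasions (field
seasons) containing secondary occasions (months or days): the
population is closed within a primary and open between primaries.
Closed-population models on the secondaries yield detection probability
`p` and marked abundance `N_t = n_t + f0_t`; an open model on the
season-level histories yields apparent survival `S` and the temporary
emigration pair (γ″, γ′) of a three-state inside/outside/dead hidden
chain, with season-level detection `p*_t = 1 − Π_s (1 − p_ts)`.

Because only well-marked animals enter the histories, marked abundance
is scaled by the mark ratio θ, `Ntot = Nm/θ`, with

    Var(Ntot) = Ntot²(Var(Nm)/Nm² + (1−θ)/(nθ))

and log-normal confidence intervals `(Ntot/C, Ntot·C)`,
`C = exp(1.96√ln(1+CV²))`. Mixed-species pools are partitioned by
species proportions with CVs combined in quadrature. Finally, a
Gerrodette-style power analysis asks what overall decline a series of
`n` yearly estimates with mean precision CV could detect by linear
regression — and how many more years it would take to detect a smaller
one. `docs/methods.md` has the full model description.

## Worked example

```python
from rdcapture import (RDModelSpec, SamplingDesign, SimulationTruth,
                       fit_model, simulate_capture_matrix)

design = SamplingDesign.from_counts([3, 4, 4, 4, 4],
    primary_labels=["2011", "2012", "2013", "2014", "2015"])
truth = SimulationTruth(design=design, n_super=400, S=0.94, p=0.3, seed=42)
study = simulate_capture_matrix(truth)
fit = fit_model(study.matrix, RDModelSpec(False, "none", "constant"), seed=1)
```

Running `python examples/simulate_and_fit.py` (which does exactly the
above) prints:

```
simulated catalog: 395 identified animals
true marked abundance per season: [400, 383, 360, 336, 325]

apparent survival: 0.945 (95% CI 0.927-0.958); truth 0.94

marked abundance (Nm = detected + estimated undetected):
primary   n     Nm    se    lcl    ucl   cv
   2011 282 431.82 16.48 402.77 467.86 0.04
   2012 296 391.29 12.20 370.14 418.48 0.03
   ...
```

`n` is the number of animals actually photographed each season and
`Nm` the estimated number of marked animals present (detected plus the
estimated never-detected `f0`); survival comes out at its true value
with an honest interval. The other scripts in `examples/` walk through
model selection with AICc weights and model averaging, the TEST2/TEST3
goodness-of-fit battery with the variance inflation factor ĉ = χ²/df,
mark-ratio scaling with species partitioning, and the power analysis:

```
abundant, precise series  (n=5, CV=0.155): minimum detectable decline 47% at power 0.8
small, imprecise series   (n=5, CV=0.32):  minimum detectable decline 80% at power 0.8
short series              (n=4, CV=0.192): minimum detectable decline 67% at power 0.8

years of monitoring to detect a 30% decline at CV 0.155: 13
```

A five-year series of estimates at CV 0.155 can only detect a decline
of about half the population; detecting a 30% decline would take
thirteen yearly samples.

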