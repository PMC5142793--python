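"""Rank competing emigration structures by AICc and model-average.

Simulates a population with random temporary emigration (animals leave
the study area between seasons with probability 0.2 regardless of where
they were), fits no-emigration, random and Markovian structures, and
shows the AICc ranking plus the model-averaged emigration rate.
"""

from rdcapture import (
    RDModelSpec,
    SamplingDesign,
    SimulationTruth,
    fit_model,
    model_average,
    rank_models,
    simulate_capture_matrix,
)

design = SamplingDesign.from_counts([4, 4, 4, 4, 4])
truth = SimulationTruth(
    design=design, n_super=300, S=0.92, gamma_dp=0.2, gamma_p=0.2, p=0.35,
    seed=7,
)
m = simulate_capture_matrix(truth).matrix
print(f"{m.n_individuals} identified animals; true gamma'' = gamma' = 0.2\n")

fits = [
    fit_model(m, RDModelSpec(False, emi, "constant"), n_starts=3, seed=i)
    for i, emi in enumerate(("none", "random", "markovian"))
]
table = rank_models(fits)
print(table.frame.round(3).to_string(index=False))

crit = table.frame["AICc"].to_numpy()
gamma, se = model_average(
    table.results, table.frame["weight"].to_numpy(), "gamma",
    mode="delta_threshold", delta_threshold=2.0, criteria=crit,
)
print(f"\nmodel-averaged temporary emigration: {gamma:.3f} (SE {se:.3f})")
print("Weights favor the structures that allow emigration; the averaged")
print("rate should sit near the true 0.2.")
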