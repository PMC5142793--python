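"""Simulate a robust-design photo-id study and recover its parameters.

Generates five field seasons of capture histories for 400 marked animals
with annual survival 0.94 and no temporary emigration, fits the
generating model structure, and prints the estimates next to the truth.
"""

import numpy as np

from rdcapture import (
    RDModelSpec,
    SamplingDesign,
    SimulationTruth,
    fit_model,
    simulate_capture_matrix,
)

design = SamplingDesign.from_counts(
    [3, 4, 4, 4, 4], primary_labels=["2011", "2012", "2013", "2014", "2015"]
)
truth = SimulationTruth(design=design, n_super=400, S=0.94, p=0.3, seed=42)
study = simulate_capture_matrix(truth)
print(f"simulated catalog: {study.matrix.n_individuals} identified animals")
print(f"true marked abundance per season: {study.n_inside.tolist()}")

fit = fit_model(study.matrix, RDModelSpec(False, "none", "constant"), seed=1)
row = fit.table[fit.table["parameter"] == "S"].iloc[0]
print(f"\napparent survival: {row['estimate']:.3f} "
      f"(95% CI {row['lcl']:.3f}-{row['ucl']:.3f}); truth 0.94")
print("\nmarked abundance (Nm = detected + estimated undetected):")
print(fit.nm.round(2).to_string(index=False))
print("\nEach Nm row should bracket the true inside count for that season.")
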