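import numpy as np
import pytest

from rdcapture import (
    CaptureMatrix,
    RDData,
    RDModelSpec,
    SamplingDesign,
    SimulationTruth,
    simulate_capture_matrix,
)


@pytest.fixture
def design_2x3():
    """Two primaries with three secondaries each."""
    return SamplingDesign.from_counts([3, 3])


@pytest.fixture
def design_striped():
    """Table-1 layout of the striped/common dolphin matrix (3+4+4+4+4)."""
    return SamplingDesign.from_counts(
        [3, 4, 4, 4, 4], primary_labels=["2011", "2012", "2013", "2014", "2015"]
    )


@pytest.fixture
def tiny_matrix(design_2x3):
    rows = np.array(
        [
            [1, 0, 1, 0, 0, 0],
            [0, 0, 0, 1, 1, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 1, 0, 0, 0, 1],
        ],
        dtype=np.uint8,
    )
    return CaptureMatrix(design_2x3, ("a", "b", "c", "d"), rows)


@pytest.fixture(scope="session")
def sim_study_medium():
    """A study-sized simulated dataset (no emigration) reused across tests."""
    design = SamplingDesign.from_counts([3, 4, 4, 4, 4])
    truth = SimulationTruth(
        design=design, n_super=400, S=0.94, gamma_dp=0.0, gamma_p=0.0,
        p=0.3, seed=20260925,
    )
    return truth, simulate_capture_matrix(truth)


def random_matrix(design: SamplingDesign, n: int, seed: int) -> CaptureMatrix:
    """Random capture matrix with no all-zero rows."""
    rng = np.random.default_rng(seed)
    while True:
        det = (rng.random((n, design.total_secondaries)) < 0.35).astype(np.uint8)
        if (det.sum(axis=1) > 0).all():
            return CaptureMatrix(
                design, tuple(f"i{j}" for j in range(n)), det
            )
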