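import numpy as np
import pytest

from drstissue import (
    GeneratorConfig,
    Measurement,
    SpectraSet,
    Spectrum,
    WavelengthGrid,
    generate_dataset,
)


@pytest.fixture(scope="session")
def canonical_grid():
    return WavelengthGrid.canonical()


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped synthetic cohort (59 patients, default separation)."""
    spectra, truth = generate_dataset(GeneratorConfig(seed=1))
    return spectra, truth


def make_set(label_counts, grid=None, seed=0, n_patients=8):
    """A small SpectraSet with prescribed per-label measurement counts."""
    if grid is None:
        grid = WavelengthGrid.regular(400, 490, 10)
    rng = np.random.default_rng(seed)
    measurements = []
    i = 0
    for label, count in label_counts.items():
        for _ in range(count):
            pid = f"P{i % n_patients:02d}"
            spec = Spectrum(grid=grid, reflectance=rng.uniform(0.1, 1.0, len(grid)))
            measurements.append(Measurement(pid, f"L{i:04d}", label, spec))
            i += 1
    return SpectraSet(tuple(measurements), grid)


@pytest.fixture
def table1_shaped_set():
    """152 labeled measurements: 80 tumor, 72 healthy."""
    return make_set({"tumor": 80, "healthy": 72})
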