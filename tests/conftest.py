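import numpy as np
import pytest

from mesograph.synthetic import (CoreSpec, render_core,
                                 sample_cell_population, simulate_cohort)


@pytest.fixture(scope="session")
def biphasic_detections():
    spec = CoreSpec(n_cells=60, sarcomatoid_fraction=0.5, bag_class="B",
                    core_diameter=300.0, seed=7)
    return sample_cell_population(spec, core_id="bip")


@pytest.fixture(scope="session")
def biphasic_image(biphasic_detections):
    return render_core(biphasic_detections, mpp=1.0, core_diameter=300.0,
                       seed=7)


@pytest.fixture(scope="session")
def mini_cohort():
    """Nine small cores over three slides, rendered; fast shared fixture."""
    return simulate_cohort((3, 3, 3), 3, seed=5, n_cells_range=(40, 60),
                           core_diameter=300.0)


@pytest.fixture(scope="session")
def random_points():
    rng = np.random.default_rng(11)
    return rng.uniform(0, 200, size=(50, 2))
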