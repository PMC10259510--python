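import numpy as np
import pytest

from tifm.calibration_control import sweep_calibration
from tifm.cli_io import scenario_preset
from tifm.optics_sim import OpticsConfig
from tifm.plant_twin import PiezoModel, ProbeSpec, TissueModel


@pytest.fixture(scope="session")
def sharp_probe() -> ProbeSpec:
    return ProbeSpec(spring_constant=0.01)


@pytest.fixture(scope="session")
def foil_probe() -> ProbeSpec:
    return ProbeSpec(
        spring_constant=0.2,
        tip_thickness=15.0,
        tip_shape="foil",
        foil_width=200.0,
        foil_height=200.0,
        foil_thickness=15.0,
    )


@pytest.fixture(scope="session")
def optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture(scope="session")
def quiet_piezo() -> PiezoModel:
    return PiezoModel(drift_rate=0.0, readout_noise_capacitance=0.0)


def make_free_plant_factory(preset_name: str = "axial_stall"):
    """Factory of sample-free plants (chip visible to imaging)."""
    cfg = scenario_preset(preset_name)

    def factory(rng):
        plant = cfg.build_plant(rng)
        plant.tissue = TissueModel(active_stress_capacity=0.0, free_velocity=0.0)
        plant.state.in_contact = False
        return plant

    return factory


@pytest.fixture(scope="session")
def free_plant_factory():
    return make_free_plant_factory()


@pytest.fixture(scope="session")
def calibration_table(free_plant_factory):
    plant = free_plant_factory(np.random.default_rng(5))
    return sweep_calibration(plant, np.linspace(0.0, 150.0, 16), frames_per_point=10)
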