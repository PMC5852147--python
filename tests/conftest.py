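import numpy as np
import pytest

from magslice import WaveformParams, build_template_cell, calibrate_waveforms
from magslice.pipeline import ScenarioConfig, run_scenario


@pytest.fixture(scope="session")
def template_cell():
    return build_template_cell()


@pytest.fixture(scope="session")
def calibrated_params(template_cell):
    return calibrate_waveforms(WaveformParams(), 0.2, cell=template_cell)


@pytest.fixture(scope="session")
def slice_spiking_run():
    """Density-subsampled spiking scenario with linear rescaling applied."""
    cfg = ScenarioConfig.from_preset(
        "slice_spiking", {"population": {"density_subsample": 0.1}}
    )
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def slice_nonspiking_run():
    cfg = ScenarioConfig.from_preset(
        "slice_nonspiking", {"population": {"density_subsample": 0.1}}
    )
    return run_scenario(cfg)


@pytest.fixture(scope="session")
def saturation_curve():
    """Peak |B_X| versus active thickness, nested populations (same seeds)."""
    thicknesses = [50.0, 100.0, 150.0, 200.0, 250.0, 300.0]
    peaks = []
    for d in thicknesses:
        cfg = ScenarioConfig.from_preset(
            "slice_spiking",
            {
                "population": {"density_subsample": 0.3, "active_thickness_um": d},
                "sensor": {"frame_window_ms": [13.0, 17.0]},
            },
        )
        peaks.append(run_scenario(cfg)["peak_fields_nt"]["B_X"])
    return np.asarray(thicknesses), np.asarray(peaks)
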