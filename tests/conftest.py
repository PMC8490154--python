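import numpy as np
import pytest

from mspt.massmap import CalibrationModel, fit_calibration
from mspt.pipeline import RunConfig, analyze_video
from mspt.simulate import (SimulationConfig, gen_background, gen_trajectories,
                           render_ratiometric_video, synthesize_camera_video)


@pytest.fixture(scope="session")
def calibration() -> CalibrationModel:
    """Two-point line through the monomer/dimer standard contrasts."""
    return fit_calibration([(1.9e-3, 33.0), (3.5e-3, 66.0)])


@pytest.fixture(scope="session")
def small_run(calibration):
    """A 600-frame simulated dimer video analysed end to end (shared)."""
    cfg = SimulationConfig(n_frames=600, particle_density_um2=0.1, seed=21)
    tracks = gen_trajectories(cfg, 1.0, contrast=3.5e-3)
    ratio = render_ratiometric_video(tracks, cfg)
    video = synthesize_camera_video(ratio, gen_background(cfg, seed=22))
    result = analyze_video(video, calibration, RunConfig(expected_d_um2s=1.0))
    return {"config": cfg, "tracks": tracks, "video": video, "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
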