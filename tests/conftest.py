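import warnings

import numpy as np
import pandas as pd
import pytest

from smdol.io import AnalysisConfig
from smdol.registration import AffineTransform2D
from smdol.sim import (
    CameraModel,
    Photophysics,
    REFERENCE_PHOTOPHYSICS,
    SimConfig,
    SimulationGroundTruth,
    simulate_experiment,
)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Pipeline stages warn on degenerate inputs; tests assert on return
    values, not on warnings, unless they opt in explicitly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def analysis_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


def make_ground_truth(
    positions_nm,
    frame_size_px=(64, 64),
    pixel_size_nm=160.0,
    has_target=True,
    unspecific_nm=(),
    cell_mask=None,
    chromatic=None,
):
    """Hand-built ground truth for fixture images: probes at explicit
    positions, full-frame cell unless a mask is given."""
    positions = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    if positions.size == 0:
        positions = positions.reshape(0, 2)
    n = len(positions)
    if cell_mask is None:
        cell_mask = np.ones(frame_size_px, dtype=bool)
    probes = pd.DataFrame(
        {
            "x_nm": positions[:, 0],
            "y_nm": positions[:, 1],
            "has_reference": np.ones(n, dtype=bool),
            "has_target": np.broadcast_to(np.asarray(has_target, bool), (n,)).copy(),
        }
    )
    unspec = np.atleast_2d(np.asarray(unspecific_nm, dtype=float))
    if unspec.size == 0:
        unspec = unspec.reshape(0, 2)
    unspecific = pd.DataFrame({"x_nm": unspec[:, 0], "y_nm": unspec[:, 1]})
    return SimulationGroundTruth(
        frame_size_px=frame_size_px,
        pixel_size_nm=pixel_size_nm,
        cell_mask=cell_mask,
        probes=probes,
        unspecific=unspecific,
        true_dol=float(np.mean(probes["has_target"])) if n else 0.0,
        true_unspec_density=0.0,
        chromatic_transform=chromatic or AffineTransform2D.identity(),
        seed=0,
    )


@pytest.fixture(scope="session")
def quiet_camera() -> CameraModel:
    """Low-noise camera for fixtures that probe the fitting itself."""
    return CameraModel(read_noise=0.5)


@pytest.fixture(scope="session")
def reference_photophysics() -> Photophysics:
    return REFERENCE_PHOTOPHYSICS


@pytest.fixture(scope="session")
def medium_density_cells(sim_config):
    """Three simulated cells at 0.2 probes/um^2, true DOL 0.5 — the
    workhorse fixture for stage-level checks against ground truth."""
    cfg = sim_config.replace(probe_density_um2=0.2, true_dol=0.5)
    return simulate_experiment(cfg, 3, seed=101)
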