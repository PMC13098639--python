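import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    from necrotherm.optics import VoxelGrid
    return VoxelGrid(extent=(20.0, 20.0, 20.0), voxel_size=2.0)  # 10^3


@pytest.fixture(scope="session")
def default_density(small_grid):
    """Low-resolution Monte Carlo deposition shared across thermal tests."""
    from necrotherm.optics import (BeamSpec, OpticalProperties,
                                   run_photon_transport)
    return run_photon_transport(OpticalProperties(), BeamSpec(), small_grid,
                                n_photons=50_000, seed=42)


@pytest.fixture(scope="session")
def coarse_section_params():
    """Section rendered at 1 um/px: fast yet several patches across."""
    from necrotherm.synth import SynthSectionParams
    return SynthSectionParams(
        width_px=1200, height_px=1200, um_per_px=1.0,
        region_radius_um=300.0, ring_width_um=80.0, seed=7)


@pytest.fixture(scope="session")
def coarse_section(coarse_section_params):
    from necrotherm.synth import gen_section
    return gen_section(coarse_section_params)


@pytest.fixture(scope="session")
def quantified_section(coarse_section):
    from necrotherm.histoquant import quantify_section
    section, truth, cells = coarse_section
    nmap, meas_cells = quantify_section(section)
    return nmap, meas_cells, truth
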