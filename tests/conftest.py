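import numpy as np
import pytest

from pcatcalib.centerline import Centerline, truncate_centerline
from pcatcalib.phantom import PhantomSpec, default_spec, default_tissues, generate_phantom


@pytest.fixture(scope="session")
def wide_spec_zero_noise():
    return default_spec("wide-detector-256", noise=False)


@pytest.fixture(scope="session")
def wide_spec_noisy():
    return default_spec("wide-detector-256", noise=True, seed=7)


@pytest.fixture(scope="session")
def zero_noise_series(wide_spec_zero_noise):
    """All 8 (kVp, recon) phantoms of the zero-noise default spec."""
    spec = wide_spec_zero_noise
    return {
        (kvp, recon): generate_phantom(spec, kvp, recon)
        for kvp in spec.kvp_list
        for recon in spec.recon_list
    }


@pytest.fixture(scope="session")
def iso_cylinder_spec():
    """0.5 mm isotropic phantom with the vessel at a generic lattice offset.

    Radius 1.5 mm, 40 mm straight vessel: the configuration whose lumen
    voxel count can be checked against the analytic cylinder volume.
    """
    path = np.column_stack(
        [np.full(21, 10.13), np.full(21, 9.87), np.linspace(5.0, 45.0, 21)]
    )
    return PhantomSpec(
        grid_shape=(40, 40, 100),
        voxel_size_mm=(0.5, 0.5, 0.5),
        vessel_path=path,
        lumen_radius_mm=1.5,
        fat_sheath_outer_radius_mm=4.0,
        tissues=default_tissues(),
        myocardium_radius_mm=6.0,
        lv_offset_mm=(6.5, 0.0),
        lv_radius_mm=0.5,
        container_outer_radius_mm=9.5,
        container_wall_mm=1.0,
    )


@pytest.fixture(scope="session")
def iso_cylinder_phantom(iso_cylinder_spec):
    return generate_phantom(iso_cylinder_spec, 120, "FBP")


@pytest.fixture
def straight_centerline(wide_spec_zero_noise):
    return truncate_centerline(
        Centerline(points=wide_spec_zero_noise.vessel_path, vessel_id="V1")
    )
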