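import numpy as np
import pytest

from bonespm.segmentation import (
    attach_membership,
    find_periosteal_surface,
    split_compartments,
)
from bonespm.synthetic import PhantomSpec, make_phantom

H = 0.082  # mm, scanner voxel size


@pytest.fixture(scope="session")
def hollow_cylinder():
    """Noise-free hollow shell: outer 2.5 mm, wall 1.0 mm, 36 slices."""
    spec = PhantomSpec(
        grid_shape=(72, 72, 36),
        spacing=H,
        outer_radius_profile=2.5,
        cortical_thickness_profile=1.0,
        trabecular_thickness=1e-4,  # effectively no lattice
        trabecular_period=10.0,
        bmd_bone=900.0,
        bmd_marrow=30.0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def hollow_cylinder_seg(hollow_cylinder):
    peri = find_periosteal_surface(hollow_cylinder)
    seg = split_compartments(hollow_cylinder, peri)
    attach_membership(seg, hollow_cylinder)
    return seg


@pytest.fixture(scope="session")
def lattice_phantom():
    """Noise-free plates lattice: BV/TV 7/30, Tb.N 1/0.6 per construction."""
    spec = PhantomSpec(
        grid_shape=(64, 64, 48),
        spacing=H,
        outer_radius_profile=2.2,
        cortical_thickness_profile=0.6,
        trabecular_period=0.6,
        trabecular_thickness=0.14,
        lattice_kind="plates",
        bmd_bone=886.0,
        bmd_marrow=30.0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def lattice_phantom_seg(lattice_phantom):
    peri = find_periosteal_surface(lattice_phantom)
    seg = split_compartments(lattice_phantom, peri)
    attach_membership(seg, lattice_phantom)
    return seg
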