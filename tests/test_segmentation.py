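import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.vq import kmeans2

from bonespm.core import CalibratedVolume
from bonespm.segmentation import (
    EmptySegmentationError,
    SMembershipParams,
    attach_membership,
    find_periosteal_surface,
    nlfcm_endosteal,
    s_membership,
    split_compartments,
)
from bonespm.synthetic import PhantomSpec, make_phantom

H = 0.082


class TestSMembership:
    def test_endpoints_midpoint_and_quarter(self):
        p = SMembershipParams(400.0, 800.0)
        assert s_membership(400.0, p) == 0.0
        assert s_membership(800.0, p) == 1.0
        assert s_membership(600.0, p) == pytest.approx(0.5)
        # quarter point: 2*((500-400)/400)^2 = 0.125
        assert s_membership(500.0, p) == pytest.approx(0.125)

    def test_monotone_and_bounded(self):
        p = SMembershipParams(100.0, 900.0)
        x = np.linspace(-100, 1100, 500)
        y = s_membership(x, p)
        assert np.all(np.diff(y) >= -1e-12)
        assert y.min() >= 0 and y.max() <= 1

    def test_scale_invariance(self):
        """Scaling the volume and (a, b) together leaves membership fixed."""
        x = np.linspace(50, 950, 100)
        p = SMembershipParams(200.0, 700.0)
        c = 3.7
        pc = SMembershipParams(200.0 * c, 700.0 * c)
        assert np.allclose(s_membership(x, p), s_membership(x * c, pc))

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            SMembershipParams(500.0, 500.0)

    @settings(max_examples=60, derandomize=True)
    @given(
        a=st.floats(-500, 1500),
        width=st.floats(1e-3, 2000),
        xs=st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=30),
    )
    def test_properties_hold_for_arbitrary_calibrations(self, a, width, xs):
        """Bounds, endpoint values and monotonicity for any a < b."""
        p = SMembershipParams(a, a + width)
        x = np.sort(np.asarray(xs))
        y = s_membership(x, p)
        assert np.all((y >= 0) & (y <= 1))
        assert np.all(np.diff(y) >= -1e-12)
        assert s_membership(p.a, p) == 0.0
        assert s_membership(p.b, p) == 1.0


class TestPeriostealSurface:
    def test_solid_cylinder_volume_matches_analytic(self):
        spec = PhantomSpec(
            grid_shape=(64, 64, 12), outer_radius_profile=2.0,
            cortical_thickness_profile=1.9999, trabecular_thickness=1e-4,
            trabecular_period=1.0,
        )
        vol = make_phantom(spec)
        mask = find_periosteal_surface(vol)
        # analytic enumeration: voxel centers within radius R
        x = (np.arange(64) + 0.5) * H - 32 * H
        X, Y = np.meshgrid(x, x, indexing="ij")
        analytic = (np.hypot(X, Y) <= 2.0).sum() * 12
        ring = int(2 * np.pi * 2.0 / H) * 12  # one boundary ring of voxels
        assert abs(int(mask.sum()) - analytic) <= ring

    def test_all_marrow_raises(self):
        vol = CalibratedVolume(np.full((24, 24, 8), 20.0))
        with pytest.raises(EmptySegmentationError):
            find_periosteal_surface(vol, threshold=300.0)

    def test_interior_gaps_filled(self, lattice_phantom, hollow_cylinder):
        """The filled periosteal mask ignores interior lattice structure."""
        spec_solid = PhantomSpec(
            grid_shape=(64, 64, 48), outer_radius_profile=2.2,
            cortical_thickness_profile=2.1999, trabecular_thickness=1e-4,
            trabecular_period=1.0,
        )
        solid = find_periosteal_surface(make_phantom(spec_solid))
        latt = find_periosteal_surface(lattice_phantom)
        agree = (solid == latt).mean()
        assert agree > 0.995


class TestSplitCompartments:
    def test_partition_tiles_periosteal_mask(self, lattice_phantom_seg):
        seg = lattice_phantom_seg
        seg.check_invariants()
        union = seg.cortical_mask | seg.trabecular_mask
        assert np.all(seg.periosteal_mask[union])
        assert not np.any(seg.cortical_mask & seg.trabecular_mask)

    def test_hollow_shell_has_no_trabecular_bone(self, hollow_cylinder,
                                                 hollow_cylinder_seg):
        seg = hollow_cylinder_seg
        frac = (seg.bone_mask & seg.trabecular_mask).sum() / max(
            seg.trabecular_mask.sum(), 1
        )
        assert frac < 0.01

    def test_shell_thickness_recovered(self, hollow_cylinder_seg):
        """Max EDT inside the 1.0 mm wall is half the thickness."""
        from scipy.ndimage import distance_transform_edt

        cort = hollow_cylinder_seg.cortical_mask
        mid = cort[:, :, 16:20]
        edt = distance_transform_edt(cort)[:, :, 16:20] * H
        assert 2 * edt.max() == pytest.approx(1.0, abs=H)

    def test_small_pore_stays_cortical(self):
        spec = PhantomSpec(
            grid_shape=(64, 64, 16), outer_radius_profile=2.2,
            cortical_thickness_profile=0.8, trabecular_thickness=1e-4,
            trabecular_period=1.0,
        )
        vol = make_phantom(spec)
        pristine = split_compartments(vol, find_periosteal_surface(vol))
        data = vol.data.copy()
        data[45, 32, 8] = 30.0  # one-voxel pore inside the shell
        vol2 = CalibratedVolume(data, vol.spacing)
        pored = split_compartments(vol2, find_periosteal_surface(vol2))
        assert np.array_equal(pristine.cortical_mask, pored.cortical_mask)

    def test_membership_zero_outside_periosteum(self, lattice_phantom,
                                                lattice_phantom_seg):
        seg = lattice_phantom_seg
        assert np.all(seg.membership[~seg.periosteal_mask] == 0)
        assert seg.membership.min() >= 0 and seg.membership.max() <= 1
        # membership high in the solid shell, low in marrow
        marrow = seg.trabecular_mask & ~seg.bone_mask
        assert np.median(seg.membership[seg.cortical_mask & seg.bone_mask]) > 0.9
        assert np.median(seg.membership[marrow]) < 0.1


def _blob_volume(sep_sd=10.0, n=400, seed=0):
    """Two feature clusters separated by sep_sd standard deviations, laid
    out as inner/outer voxel groups in a small grid."""
    rng = np.random.default_rng(seed)
    shape = (10, 10, 8)
    bmd = np.zeros(shape)
    dom = np.zeros(shape, bool)
    dom[1:9, 1:9, :] = True
    outer = dom & ~np.zeros(shape, bool)
    inner = np.zeros(shape, bool)
    inner[3:7, 3:7, :] = True
    outer = dom & ~inner
    bmd[outer] = 900 + rng.normal(0, 1, outer.sum())
    bmd[inner] = 900 + sep_sd + rng.normal(0, 1, inner.sum())
    dist = np.zeros(shape)
    dist[outer] = 1.0
    dist[inner] = 3.0
    return CalibratedVolume(bmd), dom, dist, inner, outer


class TestNLFCM:
    def test_separated_blobs_recovered_exactly(self):
        """lambda=0 on 10-sigma-separated blobs: k-means-grade labels."""
        vol, dom, dist, inner, outer = _blob_volume()
        res = nlfcm_endosteal(vol, dom, dist, lam=0.0,
                              rng=np.random.default_rng(1))
        assert res.converged
        # cortical-like label (0) = smaller periosteal distance = outer
        assert np.all(res.labels[outer] == 0)
        assert np.all(res.labels[inner] == 1)
        # oracle: plain k-means on the same features agrees
        feats = np.stack([vol.data[dom], dist[dom]]).T
        feats = (feats - feats.mean(0)) / feats.std(0)
        _, km = kmeans2(feats, 2, seed=7, minit="++")
        ours = res.labels[dom]
        agree = max((km == ours).mean(), (km != ours).mean())
        assert agree == 1.0

    def test_memberships_sharpen_as_m_decreases(self):
        vol, dom, dist, inner, outer = _blob_volume(sep_sd=4.0)
        max_mem = []
        for m in (3.0, 2.0, 1.3):
            res = nlfcm_endosteal(vol, dom, dist, lam=0.0, m=m,
                                  rng=np.random.default_rng(2))
            max_mem.append(res.memberships.max(axis=0)[dom].mean())
        assert max_mem[0] < max_mem[1] < max_mem[2]

    def test_objective_nonincreasing_at_lambda_zero(self):
        vol, dom, dist, *_ = _blob_volume(sep_sd=3.0)
        res = nlfcm_endosteal(vol, dom, dist, lam=0.0,
                              rng=np.random.default_rng(3))
        diffs = np.diff(res.objective_history)
        assert np.all(diffs <= 1e-9 * np.abs(res.objective_history[:-1]))

    def test_identical_features_flagged_degenerate(self):
        vol = CalibratedVolume(np.full((8, 8, 6), 500.0))
        dom = np.ones((8, 8, 6), bool)
        res = nlfcm_endosteal(vol, dom, np.ones((8, 8, 6)), lam=0.0,
                              rng=np.random.default_rng(4))
        assert not res.converged

    def test_nonlocal_term_preserves_blob_solution(self):
        vol, dom, dist, inner, outer = _blob_volume()
        res = nlfcm_endosteal(vol, dom, dist, lam=0.5,
                              rng=np.random.default_rng(5))
        assert np.all(res.labels[outer] == 0)
        assert np.all(res.labels[inner] == 1)

    def test_invalid_fuzzifier_rejected(self):
        vol, dom, dist, *_ = _blob_volume()
        with pytest.raises(ValueError):
            nlfcm_endosteal(vol, dom, dist, m=1.0)
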