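import numpy as np
import pytest

from bonespm.core import CalibratedVolume
from bonespm.maps import (
    EmptyDomainError,
    ball_kernel,
    extract_periosteal_mesh,
    homogenize,
    inter_trabecular_distance_map,
    local_bvtv,
    local_thickness,
    read_vertex_maps_ply,
    solve_laplace,
    surface_aggregates,
    surface_map_set,
    trace_streamlines,
    write_vertex_maps_ply,
)
from bonespm.metrics import cortical_metrics
from bonespm.segmentation import CompartmentSegmentation

H = 0.082


class TestHomogenize:
    def test_constant_map_unchanged(self):
        dom = np.ones((20, 20, 20), bool)
        out = homogenize(np.full(dom.shape, 3.5), dom, radius=4)
        assert np.allclose(out, 3.5, atol=1e-9)

    def test_impulse_gives_inverse_ball_count(self):
        dom = np.ones((31, 31, 31), bool)
        x = np.zeros(dom.shape)
        x[15, 15, 15] = 1.0
        for r in (1, 3, 5):
            out = homogenize(x, dom, radius=r)
            count = int(ball_kernel(r).sum())
            assert out[15, 15, 15] == pytest.approx(1.0 / count, rel=1e-9)

    def test_radius_one_is_seven_point_mean(self):
        assert int(ball_kernel(1).sum()) == 7

    def test_contraction(self):
        rng = np.random.default_rng(0)
        dom = rng.random((16, 16, 16)) > 0.3
        x = rng.normal(size=dom.shape)
        out = homogenize(x, dom, radius=3)
        ok = ~np.isnan(out)
        assert out[ok].min() >= x[dom].min() - 1e-12
        assert out[ok].max() <= x[dom].max() + 1e-12

    def test_empty_domain_raises(self):
        with pytest.raises(EmptyDomainError):
            homogenize(np.zeros((5, 5, 5)), np.zeros((5, 5, 5), bool), 2)


class TestLocalBVTV:
    def test_pure_phases(self):
        dom = np.ones((16, 16, 16), bool)
        assert np.allclose(local_bvtv(dom, dom, 3), 1.0)
        assert np.allclose(local_bvtv(np.zeros_like(dom), dom, 3), 0.0)

    def test_plate_fraction_under_large_kernel(self):
        # plates: 2 voxels of every 10 along x
        n = 40
        idx = np.arange(n) % 10 < 2
        bone = np.broadcast_to(idx[:, None, None], (n, n, n)).copy()
        dom = np.ones_like(bone)
        out = local_bvtv(bone, dom, radius=11)
        core = out[15:25, 15:25, 15:25]
        assert np.nanmean(core) == pytest.approx(0.2, abs=0.01)

    def test_mean_matches_global_fraction(self, lattice_phantom_seg):
        seg = lattice_phantom_seg
        out = local_bvtv(seg.bone_mask, seg.trabecular_mask, radius=5)
        inside = seg.trabecular_mask
        global_frac = (seg.bone_mask & inside).sum() / inside.sum()
        assert np.nanmean(out[inside]) == pytest.approx(global_frac, abs=0.01)


class TestLocalThickness:
    def test_slab_diameter_within_one_voxel(self):
        for s in (4, 7, 10):
            phase = np.zeros((30, 20, 20), bool)
            phase[10 : 10 + s] = True
            lt = local_thickness(phase)
            mid = lt[10 + s // 2, 10, 10]
            assert abs(mid - s) <= 1.0

    def test_solid_bone_gives_zero_map(self):
        bone = np.ones((10, 10, 10), bool)
        trab = np.ones_like(bone)
        with pytest.warns(UserWarning):
            out = inter_trabecular_distance_map(bone, trab)
        assert np.all(out == 0)

    def test_wider_separation_increases_mean(self):
        means = []
        for s in (3, 6):
            bone = np.zeros((36, 12, 12), bool)
            bone[:: s + 2] = True  # plates every s+2 voxels
            trab = np.ones_like(bone)
            out = inter_trabecular_distance_map(bone, trab)
            means.append(out[~bone].mean())
        assert means[1] > means[0]


class TestLaplace:
    def test_annulus_closed_form(self, hollow_cylinder, hollow_cylinder_seg):
        """Mid-wall potential matches ln(r/b)/ln(a/b) for the effective
        (discrete boundary-band) radii to < 1 %."""
        lap = solve_laplace(hollow_cylinder_seg, H)
        n = hollow_cylinder.shape[0]
        x = (np.arange(n) + 0.5) * H - n * H / 2
        X, Y = np.meshgrid(x, x, indexing="ij")
        r = np.hypot(X, Y)
        k = 18
        # effective Dirichlet radii from the boundary bands themselves
        pk = lap.potential[:, :, k]
        ck = hollow_cylinder_seg.cortical_mask[:, :, k]
        b_eff = float(r[ck & (pk == 0.0)].mean())
        a_eff = float(r[ck & (pk == 1.0)].mean())
        rc = 0.5 * (a_eff + b_eff)
        # angular averaging removes boundary-digitization noise; the radial
        # profile is the closed-form prediction
        for r_lo in np.arange(rc - 0.2, rc + 0.2, H):
            sel = ck & (r >= r_lo) & (r < r_lo + H)
            r_mean = r[sel].mean()
            exact = np.log(r_mean / b_eff) / np.log(a_eff / b_eff)
            assert pk[sel].mean() == pytest.approx(exact, abs=0.01)

    def test_slab_is_linear_ramp(self):
        shape = (24, 10, 10)
        peri = np.ones(shape, bool)
        cort = np.zeros(shape, bool)
        cort[2:12] = True
        trab = np.zeros(shape, bool)
        trab[12:22] = True
        peri = cort | trab
        seg = CompartmentSegmentation(
            periosteal_mask=peri, cortical_mask=cort, trabecular_mask=trab,
            bone_mask=cort,
        )
        lap = solve_laplace(seg, H)
        prof = lap.potential[2:12, 5, 5]
        ramp = np.linspace(0, 1, 10)
        assert np.allclose(prof, ramp, atol=0.02)

    def test_maximum_principle(self, hollow_cylinder_seg):
        lap = solve_laplace(hollow_cylinder_seg, H)
        vals = lap.potential[hollow_cylinder_seg.cortical_mask]
        assert np.nanmin(vals) >= 0.0
        assert np.nanmax(vals) <= 1.0

    def test_missing_boundary_raises(self):
        shape = (10, 10, 10)
        cort = np.ones(shape, bool)  # no trabecular region at all
        seg = CompartmentSegmentation(
            periosteal_mask=cort, cortical_mask=cort,
            trabecular_mask=np.zeros(shape, bool), bone_mask=cort,
        )
        with pytest.raises(EmptyDomainError):
            solve_laplace(seg, H)


@pytest.fixture(scope="module")
def cylinder_surface(hollow_cylinder, hollow_cylinder_seg):
    mesh = extract_periosteal_mesh(
        hollow_cylinder_seg.periosteal_mask, H, target_vertices=2500
    )
    sms = surface_map_set(
        hollow_cylinder, hollow_cylinder_seg, sed_map=None, mesh=mesh
    )
    return mesh, sms


class TestStreamlines:

    def test_wall_thickness_recovered(self, cylinder_surface):
        _, sms = cylinder_surface
        th = sms.surf_app_ct_th
        ok = np.isfinite(th)
        assert ok.sum() > 200
        within = np.abs(th[ok] - 1.0) <= H / 2
        assert within.mean() >= 0.95

    def test_sit_bounded_by_thickness(self, cylinder_surface):
        _, sms = cylinder_surface
        ok = np.isfinite(sms.surf_app_ct_th) & np.isfinite(sms.surf_ct_sit)
        assert np.all(sms.surf_ct_sit[ok] <= sms.surf_app_ct_th[ok] + 1e-9)

    def test_mean_thickness_matches_standard_ct_th(
        self, hollow_cylinder, hollow_cylinder_seg, cylinder_surface
    ):
        """Streamline thickness vs annular volume/area thickness: the
        annulus geometry relates them by b/((a+b)/2) within 5 %."""
        _, sms = cylinder_surface
        ct = cortical_metrics(hollow_cylinder, hollow_cylinder_seg)
        mean_stream = np.nanmean(sms.surf_app_ct_th)
        a, b = 1.5, 2.5
        assert ct["ct_th"] * (2 * b / (a + b)) == pytest.approx(
            mean_stream, rel=0.05
        )

    def test_slab_straight_lines(self):
        shape = (30, 12, 12)
        cort = np.zeros(shape, bool)
        cort[4:14] = True
        trab = np.zeros(shape, bool)
        trab[14:26] = True
        peri = cort | trab
        seg = CompartmentSegmentation(
            periosteal_mask=peri, cortical_mask=cort, trabecular_mask=trab,
            bone_mask=cort,
        )
        lap = solve_laplace(seg, H)
        seeds = np.array(
            [[4 * H, (4 + j) * H, (4 + k) * H] for j in range(4) for k in range(4)]
        )
        sl = trace_streamlines(lap, seeds)
        ok = sl.defined
        assert ok.mean() > 0.9
        # wall spans 10 voxels of cortex
        assert np.nanmean(sl.arc_lengths) == pytest.approx(10 * H, abs=H)
        for path in (p for p, d in zip(sl.points, ok) if d):
            lateral = np.ptp(path[:, 1:], axis=0)
            assert np.all(lateral < H)

    def test_membership_scaling_of_sit(self, hollow_cylinder,
                                       hollow_cylinder_seg):
        lap = solve_laplace(hollow_cylinder_seg, H)
        mesh = extract_periosteal_mesh(
            hollow_cylinder_seg.periosteal_mask, H, target_vertices=800
        )
        sl = trace_streamlines(lap, np.asarray(mesh.vertices))
        shape = hollow_cylinder.shape
        ones = np.ones(shape)
        agg1 = surface_aggregates(sl, ones, ones * 900.0, None, H)
        agg_half = surface_aggregates(sl, 0.5 * ones, ones * 900.0, None, H)
        ok = sl.defined
        assert np.allclose(agg1["surf_ct_sit"][ok], sl.arc_lengths[ok], rtol=1e-9)
        assert np.allclose(
            agg_half["surf_ct_sit"][ok], 0.5 * sl.arc_lengths[ok], rtol=1e-9
        )
        assert np.allclose(agg1["surf_ct_bmd"][ok], 900.0, rtol=1e-9)


class TestMeshIO:
    def test_watertight_and_roundtrip(self, hollow_cylinder_seg, tmp_path):
        mesh = extract_periosteal_mesh(
            hollow_cylinder_seg.periosteal_mask, H, target_vertices=2000
        )
        assert mesh.is_watertight
        maps = {
            "surf_app_ct_th": np.random.default_rng(0).random(len(mesh.vertices)),
            "surf_ct_sit": np.zeros(len(mesh.vertices)),
        }
        path = tmp_path / "surface.ply"
        write_vertex_maps_ply(mesh, maps, path)
        mesh2, maps2 = read_vertex_maps_ply(path)
        assert len(mesh2.vertices) == len(mesh.vertices)
        assert np.allclose(maps2["surf_app_ct_th"], maps["surf_app_ct_th"],
                           atol=1e-6)

    def test_decimation_respects_budget(self, hollow_cylinder_seg):
        mesh = extract_periosteal_mesh(
            hollow_cylinder_seg.periosteal_mask, H, target_vertices=500
        )
        assert len(mesh.vertices) <= 1500  # clustering is approximate
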