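"""Synthetic distal-radius phantoms and two-group cohorts.

The clinical images this pipeline targets are not publicly available, so the
package ships a generator that emulates their salient features: a roughly
tubular bone with a dense cortical shell, a periodic interior trabecular
lattice with controllable bone volume fraction and spacing, BMD contrast
between bone and marrow, smooth anatomical variation along the axis,
inter-subject shape/size variation, and group effects in the directions seen
in postmenopausal Colles'-fracture cohorts (fracture group: lower density,
lower BV/TV, thinner cortex).

Axis convention: axis 2 is axial, slice 0 is distal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import CalibratedVolume

#: isotropic in-vivo HR-pQCT voxel size (mm) and slices per stack
DEFAULT_SPACING = 0.082
DEFAULT_N_SLICES = 110


class SizingError(ValueError):
    """The requested bone does not fit in the requested grid."""


# --------------------------------------------------------------------------
# single phantom
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of a single tubular bone phantom.

    Lengths are mm, densities mg HA/cm^3. ``outer_radius_profile`` and
    ``cortical_thickness_profile`` may be scalars or per-slice arrays.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = DEFAULT_SPACING
    outer_radius_profile: float | np.ndarray = 2.2
    cortical_thickness_profile: float | np.ndarray = 1.0
    trabecular_period: float = 0.6
    trabecular_thickness: float = 0.14
    lattice_kind: str = "plates"  # plates | rods | plates+rods
    bmd_bone: float = 886.0
    bmd_marrow: float = 30.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    lattice_phase: tuple[float, float] = (0.0, 0.0)
    lattice_drift: float = 0.0  # mm of in-plane phase shift per mm of axis
    seed: int = 0

    def profiles(self) -> tuple[np.ndarray, np.ndarray]:
        nz = self.grid_shape[2]
        outer = np.broadcast_to(np.asarray(self.outer_radius_profile, float), (nz,))
        cort = np.broadcast_to(
            np.asarray(self.cortical_thickness_profile, float), (nz,)
        )
        return outer.copy(), cort.copy()

    def validate(self) -> None:
        outer, cort = self.profiles()
        if not np.all(outer > cort):
            raise ValueError("outer radius must exceed cortical thickness")
        if not self.trabecular_thickness < self.trabecular_period:
            raise ValueError("trabecular thickness must be < period")
        if not self.bmd_bone > self.bmd_marrow:
            raise ValueError("bmd_bone must exceed bmd_marrow")
        if self.lattice_kind not in ("plates", "rods", "plates+rods"):
            raise ValueError(f"unknown lattice kind {self.lattice_kind!r}")
        half_extent = 0.5 * min(self.grid_shape[0], self.grid_shape[1]) * self.spacing
        if outer.max() + self.spacing > half_extent:
            raise SizingError(
                f"outer radius {outer.max():.3f} mm does not fit in a grid of "
                f"half-extent {half_extent:.3f} mm"
            )


def _stripes(coord: np.ndarray, period: float, thickness: float, phase: float) -> np.ndarray:
    """Periodic slabs: True where (coord - phase) mod period < thickness."""
    return np.mod(coord - phase, period) < thickness


def lattice_mask(
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
    period: float,
    thickness: float,
    phase: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Trabecular lattice indicator on mm coordinate grids ``x``, ``y``.

    ``plates``: one family of parallel plates normal to x (bone fraction
    exactly thickness/period over full periods). ``rods``: axial rods of
    square cross-section on a square grid. ``plates+rods``: two orthogonal
    plate families plus axial rods offset by half a period. ``x``/``y`` may
    be 3D (e.g. with an axial phase drift folded in).
    """
    sx = _stripes(x, period, thickness, phase[0])
    if kind == "plates":
        return sx
    sy = _stripes(y, period, thickness, phase[1])
    if kind == "rods":
        return sx & sy
    rods = _stripes(x, period, thickness, phase[0] + period / 2) & _stripes(
        y, period, thickness, phase[1] + period / 2
    )
    return sx | sy | rods


def make_phantom(spec: PhantomSpec) -> CalibratedVolume:
    """Generate a BMD-calibrated tubular phantom; deterministic given seed."""
    spec.validate()
    nx, ny, nz = spec.grid_shape
    h = spec.spacing
    outer, cort = spec.profiles()

    cx = nx * h / 2.0
    cy = ny * h / 2.0
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    X, Y = np.meshgrid(x, y, indexing="ij")
    r = np.hypot(X - cx, Y - cy)

    R = outer[None, None, :]
    Ri = (outer - cort)[None, None, :]
    r3 = r[:, :, None]
    inside = r3 <= R
    interior = r3 <= Ri
    cortex = inside & ~interior

    z = (np.arange(nz) + 0.5) * h
    if spec.lattice_drift != 0.0:
        # trabeculae are not axially invariant: drift the in-plane phase
        # along the axis (slightly tilted plates)
        drift = spec.lattice_drift * z[None, None, :]
        X3 = X[:, :, None] - drift
        Y3 = Y[:, :, None] - drift
        lat = lattice_mask(
            X3, Y3, spec.lattice_kind, spec.trabecular_period,
            spec.trabecular_thickness, spec.lattice_phase,
        )
    else:
        lat = lattice_mask(
            X, Y, spec.lattice_kind, spec.trabecular_period,
            spec.trabecular_thickness, spec.lattice_phase,
        )[:, :, None]
    bone = cortex | (interior & lat)

    vol = np.zeros((nx, ny, nz), dtype=np.float64)
    vol[inside] = spec.bmd_marrow
    vol[bone] = spec.bmd_bone

    if spec.blur_sigma > 0:
        vol = gaussian_filter(vol, sigma=spec.blur_sigma / h)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)

    return CalibratedVolume(
        data=vol.astype(np.float32),
        spacing=(h, h, h),
        meta={"phantom_seed": spec.seed},
    )


# --------------------------------------------------------------------------
# correlated latent fields
# --------------------------------------------------------------------------


def correlated_pair_cohort(
    n: int,
    shape: tuple[int, ...],
    rho: float | np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject field pairs with a planted location-wise correlation.

    Each location carries, across subjects, a standard-normal pair whose
    Pearson (and hence Spearman, up to rank noise) correlation equals
    ``rho`` (scalar or an array broadcastable to ``shape``; values in
    [0, 1)). Construction: shared factor with weight sqrt(rho).
    """
    rho_arr = np.broadcast_to(np.asarray(rho, float), shape)
    if np.any(rho_arr < 0) or np.any(rho_arr >= 1):
        raise ValueError("rho must be in [0, 1)")
    w = np.sqrt(rho_arr)
    g = rng.standard_normal((n,) + shape)
    e1 = rng.standard_normal((n,) + shape)
    e2 = rng.standard_normal((n,) + shape)
    a = w * g + np.sqrt(1.0 - rho_arr) * e1
    b = w * g + np.sqrt(1.0 - rho_arr) * e2
    return a, b


def axial_rho_profile(
    shape: tuple[int, int, int], rho_distal: float, rho_proximal: float
) -> np.ndarray:
    """Correlation ramp along the axial direction (slice 0 = distal)."""
    nz = shape[2]
    ramp = np.linspace(rho_distal, rho_proximal, nz)
    return np.broadcast_to(ramp[None, None, :], shape)


# --------------------------------------------------------------------------
# two-group cohorts
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Two-group cohort with multiplicative fracture-group effects.

    Group means follow the published clinical tables (controls: BV/TV 0.23,
    Ct.Th 1.01 mm, matrix BMD ~ cortical BMD 886 mg/cm^3, Tb.N 1.67 /mm);
    the fracture-group effect ratios default to the published fracture/control
    mean ratios. Between-subject relative SDs are deliberately modest
    (d ~ 1.4-1.7) so that desk-scale cohorts retain the discriminative power
    the clinical cohort had at n ~ 90 per group; see docs/methods.md.
    """

    n_control: int = 25
    n_fracture: int = 25
    # fracture/control multiplicative effects (published mean ratios)
    effect_bvtv: float = 0.19 / 0.23
    effect_ctth: float = 0.95 / 1.01
    effect_bmd: float = 858.4 / 886.0
    effect_tbn: float = 1.47 / 1.67
    # control-group means
    bvtv_mean: float = 0.23
    ctth_mean: float = 1.01
    bmd_bone_mean: float = 886.0
    tbn_mean: float = 1.67
    # between-subject relative SDs (same in both groups)
    bvtv_rel_sd: float = 0.10
    ctth_rel_sd: float = 0.04
    bmd_rel_sd: float = 0.05
    tbn_rel_sd: float = 0.05
    # covariates, independent of group (clinical cohort: no sig. differences)
    age_mean: float = 65.3
    age_sd: float = 9.3
    height_mean: float = 161.2
    height_sd: float = 5.6
    weight_mean: float = 73.6
    weight_sd: float = 13.8
    # geometry
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = DEFAULT_SPACING
    outer_radius_mean: float = 2.2
    radius_flare: float = 0.05  # proximal widening fraction
    radius_scale_sd: float = 0.03
    radius_wobble_mm: float = 0.03  # band-limited profile perturbation
    lattice_kind: str = "plates"
    lattice_drift_periods: float = 1.0  # full periods of phase drift per stack
    bmd_marrow: float = 30.0
    noise_sd: float = 25.0
    blur_sigma: float = 0.06
    # latent parameter fields (template-space maps with a planted
    # axial correlation gradient between the BMD and BV/TV fields)
    latent_shape: tuple[int, int, int] = (10, 10, 12)
    rho_distal: float = 0.5
    rho_proximal: float = 0.5
    motion_grade_probs: tuple[float, ...] = (0.55, 0.25, 0.12, 0.05, 0.03)
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 4 or self.n_fracture < 4:
            raise ValueError("need at least 4 subjects per group")
        for name in ("effect_bvtv", "effect_ctth", "effect_bmd", "effect_tbn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "bvtv_rel_sd", "ctth_rel_sd", "bmd_rel_sd", "tbn_rel_sd",
            "age_sd", "height_sd", "weight_sd", "radius_scale_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (degenerate distribution)")


@dataclass
class SubjectRecord:
    id: str
    group: str  # control | fracture
    age: float
    height: float
    weight: float
    motion_grade: int
    volume: CalibratedVolume | None
    truth: dict
    latent_maps: dict = field(default_factory=dict)
    phantom_spec: PhantomSpec | None = None


def _radius_profile(
    nz: int, base: float, flare: float, scale: float, wobble_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    z = np.linspace(0.0, 1.0, nz)
    profile = base * (1.0 + flare * z) * scale
    if wobble_mm > 0:
        # smooth perturbation: a few low-frequency sinusoids
        for k in (1, 2, 3):
            amp = wobble_mm * rng.normal() / k
            phase = rng.uniform(0, 2 * np.pi)
            profile = profile + amp * np.sin(2 * np.pi * k * z + phase)
    return profile


def make_cohort(
    spec: CohortSpec, generate_volumes: bool = True
) -> list[SubjectRecord]:
    """Draw a two-group cohort of phantom subjects with known ground truth."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    n_total = spec.n_control + spec.n_fracture
    groups = ["control"] * spec.n_control + ["fracture"] * spec.n_fracture

    # latent fields: BMD-like and BV/TV-like maps sharing a factor whose
    # strength ramps along the axis (slice 0 = distal)
    rho = axial_rho_profile(spec.latent_shape, spec.rho_distal, spec.rho_proximal)
    lat_bmd, lat_bvtv = correlated_pair_cohort(n_total, spec.latent_shape, rho, rng)

    records: list[SubjectRecord] = []
    child_seeds = ss.spawn(n_total)
    for i, group in enumerate(groups):
        eff = group == "fracture"
        bvtv = rng.normal(
            spec.bvtv_mean * (spec.effect_bvtv if eff else 1.0),
            spec.bvtv_mean * spec.bvtv_rel_sd,
        )
        ctth = rng.normal(
            spec.ctth_mean * (spec.effect_ctth if eff else 1.0),
            spec.ctth_mean * spec.ctth_rel_sd,
        )
        bmd_bone = rng.normal(
            spec.bmd_bone_mean * (spec.effect_bmd if eff else 1.0),
            spec.bmd_bone_mean * spec.bmd_rel_sd,
        )
        tbn = rng.normal(
            spec.tbn_mean * (spec.effect_tbn if eff else 1.0),
            spec.tbn_mean * spec.tbn_rel_sd,
        )
        bvtv = float(np.clip(bvtv, 0.03, 0.6))
        ctth = float(np.clip(ctth, 3 * spec.spacing, None))
        tbn = float(np.clip(tbn, 0.5, 3.5))
        period = 1.0 / tbn
        thickness = float(np.clip(bvtv * period, 1.2 * spec.spacing, 0.9 * period))

        scale = float(np.clip(rng.normal(1.0, spec.radius_scale_sd), 0.9, 1.1))
        profile = _radius_profile(
            spec.grid_shape[2], spec.outer_radius_mean, spec.radius_flare,
            scale, spec.radius_wobble_mm, rng,
        )
        phase = (rng.uniform(0, period), rng.uniform(0, period))

        pspec = PhantomSpec(
            grid_shape=spec.grid_shape,
            spacing=spec.spacing,
            outer_radius_profile=profile,
            cortical_thickness_profile=ctth,
            trabecular_period=period,
            trabecular_thickness=thickness,
            lattice_kind=spec.lattice_kind,
            lattice_drift=spec.lattice_drift_periods
            * period
            / (spec.grid_shape[2] * spec.spacing),
            bmd_bone=bmd_bone,
            bmd_marrow=spec.bmd_marrow,
            noise_sd=spec.noise_sd,
            blur_sigma=spec.blur_sigma,
            lattice_phase=phase,
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
        )
        volume = make_phantom(pspec) if generate_volumes else None

        # covariates drawn independently of group
        age = float(rng.normal(spec.age_mean, spec.age_sd))
        height = float(rng.normal(spec.height_mean, spec.height_sd))
        weight = float(rng.normal(spec.weight_mean, spec.weight_sd))
        grade = int(rng.choice(np.arange(1, 6), p=spec.motion_grade_probs))

        records.append(
            SubjectRecord(
                id=f"sub-{i:03d}",
                group=group,
                age=age,
                height=height,
                weight=weight,
                motion_grade=grade,
                volume=volume,
                truth={
                    "bv_tv": bvtv,
                    "ct_th": ctth,
                    "bmd_bone": bmd_bone,
                    "tb_n": 1.0 / period,
                    "tb_period": period,
                    "tb_thickness": thickness,
                    "radius_scale": scale,
                },
                latent_maps={"bmd": lat_bmd[i], "bvtv": lat_bvtv[i]},
                phantom_spec=pspec,
            )
        )
    return records


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, tuple):
        return list(value)
    return value


def spec_to_json(spec) -> str:
    d = {k: _jsonable(v) for k, v in dataclasses.asdict(spec).items()}
    d["__class__"] = type(spec).__name__
    return json.dumps(d, indent=1, sort_keys=True)


def spec_from_json(text: str):
    d = json.loads(text)
    cls = {"PhantomSpec": PhantomSpec, "CohortSpec": CohortSpec}[d.pop("__class__")]
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in list(d.items()):
        if isinstance(v, list):
            d[k] = tuple(v) if k in ("grid_shape", "latent_shape", "lattice_phase",
                                     "motion_grade_probs") else np.asarray(v)
    return cls(**d)


def cohort_manifest(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "id": rec.id,
            "group": rec.group,
            "age": rec.age,
            "height": rec.height,
            "weight": rec.weight,
            "motion_grade": rec.motion_grade,
        }
        row.update({f"truth_{k}": v for k, v in rec.truth.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: list[SubjectRecord], outdir) -> pd.DataFrame:
    """Write volumes as NIfTI plus a manifest/ground-truth CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(records)
    paths = []
    for rec in records:
        path = outdir / f"{rec.id}.nii.gz"
        if rec.volume is not None:
            rec.volume.save(path)
        paths.append(path.name)
    manifest["volume_file"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
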