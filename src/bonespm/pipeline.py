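"""Pipeline orchestration: synth -> segment -> metrics -> fea -> maps ->
normalize -> stats, with config validation, stage caching, exclusion
bookkeeping and a text report.

Outputs per run directory: ``cohort/`` (volumes + manifest), ``seg/``,
``fea/``, ``maps/``, ``normalized/``, ``stats/``, ``cohort_table.csv``,
``run_manifest.json`` and ``report.txt``. Subjects with motion grade > 3
are excluded before analysis and counted in the manifest.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fea as fea_mod
from . import maps as maps_mod
from . import metrics as metrics_mod
from . import normalize as norm_mod
from . import segmentation as seg_mod
from . import stats as stats_mod
from .core import CalibratedVolume, save_map
from .synthetic import CohortSpec, make_cohort, write_cohort

STAGES = ("synth", "segment", "metrics", "fea", "maps", "normalize", "stats")

DEFAULT_CONFIG: dict = {
    "outdir": "bonespm_run",
    "seed": 0,
    "stages": {name: True for name in STAGES},
    "synth": {
        "n_control": 12,
        "n_fracture": 12,
        "grid": [64, 64, 64],
        "spacing": 0.082,
        "outer_radius": None,  # mm; None = cohort default (must fit the grid)
        "cortical_thickness": None,  # mm; None = cohort default
    },
    "segment": {
        "closing_radius": 3,
        "min_cortex_voxels": 27,
    },
    "metrics": {
        "compute_tbn": True,
    },
    "fea": {
        "elastic_modulus": 6829.0,  # MPa
        "poisson_ratio": 0.3,
        "applied_strain": 0.01,
        "critical_strain": 0.007,
        "critical_volume_fraction": 0.02,
        "coarsen": 2,  # voxel binning factor for the demo-scale solve
        "tol": 1e-6,
    },
    "maps": {
        "radius_large": 11,
        "radius_small": 5,
        "target_vertices": 3000,
    },
    "normalize": {
        "deformable": True,
        "shape_pcs": 4,
    },
    "stats": {
        "q": 0.05,
        "min_fraction": 0.9,
        "covariate_df_correction": True,
    },
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge over defaults; unknown keys are rejected."""
    merged = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(dst, src, path=""):
        for key, val in src.items():
            if key not in dst:
                raise ConfigError(f"unknown config key: {path}{key}")
            if isinstance(dst[key], dict) and isinstance(val, dict):
                _merge(dst[key], val, f"{path}{key}.")
            else:
                dst[key] = val

    _merge(merged, config)
    return merged


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)  # name -> status/hash/time
    excluded_subjects: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "stages": self.stages,
                    "excluded_subjects": self.excluded_subjects,
                    "warnings": self.warnings,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_done(manifest_path: Path, name: str, key: str) -> bool:
    if not manifest_path.exists():
        return False
    try:
        data = json.loads(manifest_path.read_text())
    except json.JSONDecodeError:
        return False
    entry = data.get("stages", {}).get(name)
    return bool(entry) and entry.get("hash") == key and entry.get("status") == "done"


def run_pipeline(config: dict | None = None) -> RunManifest:
    cfg = validate_config(config or {})
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "run_manifest.json"
    manifest = RunManifest(config=cfg)
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            manifest.stages = old.get("stages", {})
        except json.JSONDecodeError:
            pass

    prev_hash = ""
    try:
        for name in STAGES:
            key = _hash([cfg.get(name), cfg["seed"], prev_hash])
            prev_hash = key
            if not cfg["stages"].get(name, True):
                manifest.stages[name] = {"status": "disabled", "hash": key}
                continue
            if _stage_done(manifest_path, name, key):
                manifest.stages[name] = {"status": "cached", "hash": key}
                continue
            t0 = time.time()
            _RUNNERS[name](cfg, out, manifest)
            manifest.stages[name] = {
                "status": "done",
                "hash": key,
                "seconds": round(time.time() - t0, 2),
            }
            manifest.save(manifest_path)
    except Exception as exc:  # record partial completion before re-raising
        manifest.stages[name] = {"status": f"failed: {exc}", "hash": key}
        manifest.save(manifest_path)
        raise
    manifest.save(manifest_path)
    return manifest


# --------------------------------------------------------------------------
# stage runners
# --------------------------------------------------------------------------


def _cohort_spec(cfg) -> CohortSpec:
    s = cfg["synth"]
    kwargs = {}
    if s.get("outer_radius") is not None:
        kwargs["outer_radius_mean"] = float(s["outer_radius"])
    if s.get("cortical_thickness") is not None:
        kwargs["ctth_mean"] = float(s["cortical_thickness"])
    return CohortSpec(
        n_control=s["n_control"],
        n_fracture=s["n_fracture"],
        grid_shape=tuple(s["grid"]),
        spacing=s["spacing"],
        seed=cfg["seed"],
        **kwargs,
    )


def _run_synth(cfg, out: Path, manifest: RunManifest) -> None:
    records = make_cohort(_cohort_spec(cfg))
    write_cohort(records, out / "cohort")


def _load_cohort(out: Path) -> pd.DataFrame:
    df = pd.read_csv(out / "cohort" / "manifest.csv")
    return df


def _included(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["motion_grade"] <= 3].reset_index(drop=True)


def _run_segment(cfg, out: Path, manifest: RunManifest) -> None:
    df = _load_cohort(out)
    excluded = df[df["motion_grade"] > 3]["id"].tolist()
    manifest.excluded_subjects = excluded
    seg_dir = out / "seg"
    seg_dir.mkdir(exist_ok=True)
    for _, row in _included(df).iterrows():
        vol = CalibratedVolume.load(out / "cohort" / row["volume_file"])
        peri = seg_mod.find_periosteal_surface(
            vol, closing_radius=cfg["segment"]["closing_radius"]
        )
        seg = seg_mod.split_compartments(
            vol, peri, min_cortex_voxels=cfg["segment"]["min_cortex_voxels"]
        )
        seg_mod.attach_membership(seg, vol)
        for warning in seg.warnings:
            manifest.warnings.append(f"{row['id']}: {warning}")
        _save_masks_nifti(seg_dir / f"{row['id']}_seg.nii.gz", vol, seg)
        save_map(seg.membership, vol, seg_dir / f"{row['id']}_membership.nii.gz")


def _save_masks_nifti(path, vol, seg) -> None:
    import nibabel as nib

    stack = np.stack(
        [seg.periosteal_mask, seg.cortical_mask, seg.trabecular_mask, seg.bone_mask],
        axis=-1,
    ).astype(np.uint8)
    img = nib.Nifti1Image(stack, vol.affine())
    nib.save(img, str(path))


def _load_seg(out: Path, sid: str) -> seg_mod.CompartmentSegmentation:
    import nibabel as nib

    stack = np.asarray(
        nib.load(str(out / "seg" / f"{sid}_seg.nii.gz")).dataobj
    ).astype(bool)
    mem = np.asarray(
        nib.load(str(out / "seg" / f"{sid}_membership.nii.gz")).dataobj
    ).astype(np.float64)
    return seg_mod.CompartmentSegmentation(
        periosteal_mask=stack[..., 0],
        cortical_mask=stack[..., 1],
        trabecular_mask=stack[..., 2],
        bone_mask=stack[..., 3],
        membership=mem,
    )


def _run_metrics(cfg, out: Path, manifest: RunManifest) -> None:
    df = _included(_load_cohort(out))
    rows = []
    for _, row in df.iterrows():
        vol = CalibratedVolume.load(out / "cohort" / row["volume_file"])
        seg = _load_seg(out, row["id"])
        m = metrics_mod.standard_metrics(
            vol, seg, compute_tbn=cfg["metrics"]["compute_tbn"]
        )
        rows.append({"id": row["id"], **m.as_dict()})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False, float_format="%.8g")


def _coarsen_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return mask
    nx, ny, nz = (s // factor * factor for s in mask.shape)
    m = mask[:nx, :ny, :nz].reshape(
        nx // factor, factor, ny // factor, factor, nz // factor, factor
    )
    return m.mean(axis=(1, 3, 5)) >= 0.5


def _run_fea(cfg, out: Path, manifest: RunManifest) -> None:
    df = _included(_load_cohort(out))
    f = cfg["fea"]
    fdir = out / "fea"
    fdir.mkdir(exist_ok=True)
    rows = []
    for _, row in df.iterrows():
        vol = CalibratedVolume.load(out / "cohort" / row["volume_file"])
        seg = _load_seg(out, row["id"])
        factor = int(f["coarsen"])
        mask = _coarsen_mask(seg.bone_mask, factor)
        h = vol.spacing[0] * factor
        model = fea_mod.build_model(
            mask, h, f["elastic_modulus"], f["poisson_ratio"], f["applied_strain"]
        )
        result = fea_mod.solve_compression(model, tol=f["tol"])
        fl = fea_mod.failure_load(
            result, model, f["critical_strain"], f["critical_volume_fraction"]
        )
        sed_full = np.repeat(
            np.repeat(np.repeat(result.sed_map, factor, 0), factor, 1), factor, 2
        )
        pad = [(0, vol.shape[i] - sed_full.shape[i]) for i in range(3)]
        sed_full = np.pad(sed_full, pad, constant_values=np.nan)
        save_map(sed_full, vol, fdir / f"{row['id']}_sed.nii.gz")
        rows.append(
            {
                "id": row["id"],
                "mufea_stiffness": result.stiffness,
                "mufea_fl": fl,
                "fea_removed_elements": model.removed_elements,
            }
        )
    pd.DataFrame(rows).to_csv(out / "fea.csv", index=False, float_format="%.8g")


def _run_maps(cfg, out: Path, manifest: RunManifest) -> None:
    df = _included(_load_cohort(out))
    mdir = out / "maps"
    mdir.mkdir(exist_ok=True)
    mcfg = cfg["maps"]
    for _, row in df.iterrows():
        vol = CalibratedVolume.load(out / "cohort" / row["volume_file"])
        seg = _load_seg(out, row["id"])
        sed_path = out / "fea" / f"{row['id']}_sed.nii.gz"
        sed = (
            CalibratedVolume.load(sed_path).data.astype(np.float64)
            if sed_path.exists()
            else None
        )
        vms = maps_mod.voxel_map_set(
            vol, seg, sed,
            radius_large=mcfg["radius_large"],
            radius_small=mcfg["radius_small"],
        )
        for n in vms.names():
            save_map(getattr(vms, n), vol, mdir / f"{row['id']}_{n}.nii.gz")
        sms = maps_mod.surface_map_set(
            vol, seg, sed, target_vertices=mcfg["target_vertices"]
        )
        sms.save_ply(mdir / f"{row['id']}_surface.ply")


def _run_normalize(cfg, out: Path, manifest: RunManifest) -> None:
    df = _included(_load_cohort(out))
    ndir = out / "normalized"
    ndir.mkdir(exist_ok=True)
    h = cfg["synth"]["spacing"]
    segs = {row["id"]: _load_seg(out, row["id"]) for _, row in df.iterrows()}
    meshes = {}
    smaps = {}
    for sid in segs:
        mesh, m = maps_mod.read_vertex_maps_ply(out / "maps" / f"{sid}_surface.ply")
        meshes[sid] = mesh
        smaps[sid] = m
    ids = list(segs)
    template = norm_mod.build_template(
        [CalibratedVolume.load(out / "cohort" / row["volume_file"])
         for _, row in df.iterrows()],
        [segs[sid].periosteal_mask for sid in ids],
        [segs[sid].trabecular_mask for sid in ids],
        [meshes[sid] for sid in ids],
    )
    shape = template.periosteal_mask.shape

    vertex_sets = []
    for _, row in df.iterrows():
        sid = row["id"]
        tx = norm_mod.register_to_template(
            segs[sid].periosteal_mask, template, h,
            deformable=cfg["normalize"]["deformable"],
        )
        for name in _VOXEL_MAP_NAMES:
            src = out / "maps" / f"{sid}_{name}.nii.gz"
            if not src.exists():
                continue
            res = norm_mod.resample_map_to_template(
                CalibratedVolume.load(src).data.astype(np.float64), tx, shape, h
            )
            save_map(res, template.volume, ndir / f"{sid}_{name}.nii.gz")
        vertex_maps, dists = norm_mod.correspond_surfaces(
            meshes[sid], smaps[sid], template.mesh, tx
        )
        np.savez_compressed(
            ndir / f"{sid}_surfacemaps.npz",
            **{k: v.astype(np.float32) for k, v in vertex_maps.items()},
        )
        subj_pts = norm_mod.transform_points(tx, template.mesh.vertices)
        vertex_sets.append(subj_pts)
        np.save(ndir / f"{sid}_affine.npy", tx.affine)

    sc = norm_mod.shape_pca(vertex_sets, k=cfg["normalize"]["shape_pcs"])
    cols = {f"shape_pc{j+1}": sc.scores[:, j] for j in range(sc.k_used)}
    pd.DataFrame({"id": ids, **cols}).to_csv(
        out / "shape_scores.csv", index=False, float_format="%.8g"
    )
    with open(ndir / "template.json", "w") as fh:
        json.dump(
            {"provenance": template.provenance,
             "variance_explained": sc.variance_explained.tolist(),
             "k_90": sc.k_90},
            fh, indent=1,
        )


def build_cohort_table(out: Path) -> pd.DataFrame:
    """Merge manifest covariates with all computed per-subject results."""
    df = _included(_load_cohort(out))
    for name in ("metrics.csv", "fea.csv", "shape_scores.csv"):
        path = out / name
        if path.exists():
            df = df.merge(pd.read_csv(path), on="id", how="left")
    # subject-level means of parametric maps (global analysis uses
    # pre-normalization maps)
    rows = []
    for _, row in df.iterrows():
        sid = row["id"]
        entry = {"id": sid}
        for name in _VOXEL_MAP_NAMES:
            vm_path = out / "maps" / f"{sid}_{name}.nii.gz"
            if vm_path.exists():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    entry[name] = float(
                        np.nanmean(CalibratedVolume.load(vm_path).data)
                    )
        ply = out / "maps" / f"{sid}_surface.ply"
        if ply.exists():
            _, m = maps_mod.read_vertex_maps_ply(ply)
            for name, vals in m.items():
                entry[name] = float(np.nanmean(vals))
        rows.append(entry)
    if rows:
        df = df.merge(pd.DataFrame(rows), on="id", how="left")
    return df


_VOXEL_MAP_NAMES = ("h_tb_bmd", "l_tb_bvtv", "h_tb_1n", "h_tb_sed")

_TRAB_PAIRS = [
    ("h_tb_bmd", "l_tb_bvtv"),
    ("h_tb_bmd", "h_tb_1n"),
    ("h_tb_bmd", "h_tb_sed"),
    ("l_tb_bvtv", "h_tb_1n"),
    ("l_tb_bvtv", "h_tb_sed"),
    ("h_tb_1n", "h_tb_sed"),
]
_CORT_PAIRS = [
    ("surf_ct_bmd", "surf_app_ct_th"),
    ("surf_ct_bmd", "surf_ct_sit"),
    ("surf_ct_bmd", "surf_ct_sed"),
    ("surf_app_ct_th", "surf_ct_sit"),
    ("surf_app_ct_th", "surf_ct_sed"),
    ("surf_ct_sit", "surf_ct_sed"),
]


def _run_stats(cfg, out: Path, manifest: RunManifest) -> None:
    df = build_cohort_table(out)
    df.to_csv(out / "cohort_table.csv", index=False, float_format="%.8g")
    scfg = cfg["stats"]
    cov_cols = ["age", "height", "weight"]
    cov = df[cov_cols].to_numpy()
    group = df["group"].to_numpy()
    sdir = out / "stats"
    sdir.mkdir(exist_ok=True)

    # group comparisons (standard + parametric analogues)
    value_cols = [
        c
        for c in (
            "tb_bmd", "tb_bvtv", "tb_n", "tb_sp", "ct_bmd", "ct_th",
            "mufea_fl", "mufea_stiffness",
            "h_tb_bmd", "l_tb_bvtv", "h_tb_1n", "h_tb_sed",
            "surf_ct_bmd", "surf_app_ct_th", "surf_ct_sit", "surf_ct_sed",
        )
        if c in df.columns
    ]
    rows = []
    for col in value_cols:
        y = df[col].to_numpy(np.float64)
        ok = ~np.isnan(y)
        if ok.sum() < 8 or len(np.unique(group[ok])) < 2:
            continue
        coef, p = stats_mod.adjusted_group_difference(y[ok], group[ok], cov[ok])
        g = group[ok]
        rows.append(
            {
                "parameter": col,
                "control_mean": float(y[ok][g == "control"].mean()),
                "control_sd": float(y[ok][g == "control"].std(ddof=1)),
                "fracture_mean": float(y[ok][g == "fracture"].mean()),
                "fracture_sd": float(y[ok][g == "fracture"].std(ddof=1)),
                "adjusted_difference": coef,
                "p_value": p,
            }
        )
    pd.DataFrame(rows).to_csv(
        sdir / "group_comparisons.csv", index=False, float_format="%.8g"
    )

    # global partial correlations per group + Fisher-Z between groups
    def _corr_table(pairs, extra_target=None):
        recs = []
        targets = pairs if extra_target is None else [
            (a, extra_target) for a in pairs
        ]
        for a, b in targets:
            if a not in df.columns or b not in df.columns:
                continue
            entry = {"x": a, "y": b}
            rho_n = {}
            for gname in ("control", "fracture"):
                sel = (group == gname) & ~df[a].isna() & ~df[b].isna()
                if sel.sum() < 8:
                    rho_n[gname] = (np.nan, 0)
                    continue
                rho, p = stats_mod.partial_spearman(
                    df.loc[sel, a], df.loc[sel, b], cov[sel]
                )
                entry[f"{gname}_rho"] = rho
                entry[f"{gname}_p"] = p
                rho_n[gname] = (rho, int(sel.sum()))
            (r1, n1), (r2, n2) = rho_n.get("control", (np.nan, 0)), rho_n.get(
                "fracture", (np.nan, 0)
            )
            if n1 > 8 and n2 > 8 and np.isfinite(r1) and np.isfinite(r2) \
                    and abs(r1) < 1 and abs(r2) < 1:
                z, p = stats_mod.fisher_z_compare(r1, n1, r2, n2, n_covariates=3)
                entry["between_group_p"] = p
            recs.append(entry)
        return pd.DataFrame(recs)

    _corr_table(_TRAB_PAIRS + _CORT_PAIRS).to_csv(
        sdir / "global_correlations.csv", index=False, float_format="%.8g"
    )
    if "mufea_fl" in df.columns:
        singles = [
            p for p in (
                "h_tb_bmd", "l_tb_bvtv", "h_tb_1n", "h_tb_sed",
                "surf_ct_bmd", "surf_app_ct_th", "surf_ct_sit", "surf_ct_sed",
            ) if p in df.columns
        ]
        _corr_table(singles, extra_target="mufea_fl").to_csv(
            sdir / "failure_load_correlations.csv", index=False, float_format="%.8g"
        )

    # voxel-wise SPM on normalized maps
    ndir = out / "normalized"
    if ndir.exists():
        shape_cols = [c for c in df.columns if c.startswith("shape_pc")]
        cov_spm = df[cov_cols + shape_cols].to_numpy(np.float64)
        stacks: dict = {}
        for _, row in df.iterrows():
            for name in _VOXEL_MAP_NAMES:
                path = ndir / f"{row['id']}_{name}.nii.gz"
                if not path.exists():
                    continue
                stacks.setdefault(name, {})[row["id"]] = CalibratedVolume.load(
                    path
                ).data.astype(np.float64)
        if stacks:
            names = list(stacks)
            ids = df["id"].tolist()
            shp = next(iter(stacks[names[0]].values())).shape
            flat = {
                name: np.stack(
                    [stacks[name].get(sid, np.full(shp, np.nan)).ravel() for sid in ids]
                )
                for name in names
            }
            summary = []
            for a, b in _TRAB_PAIRS:
                if a not in flat or b not in flat:
                    continue
                per_group = {}
                try:
                    for gname in ("control", "fracture"):
                        sel = group == gname
                        per_group[gname] = stats_mod.correlation_map(
                            flat[a][sel], flat[b][sel], cov_spm[sel],
                            q=scfg["q"], min_fraction=scfg["min_fraction"],
                        )
                    diff = stats_mod.correlation_difference_map(
                        per_group["control"], per_group["fracture"], q=scfg["q"],
                        covariate_df_correction=scfg["covariate_df_correction"],
                    )
                except ValueError as exc:
                    manifest.warnings.append(f"SPM {a}-{b}: {exc}")
                    continue
                np.savez_compressed(
                    sdir / f"spm_{a}_{b}.npz",
                    rho_control=per_group["control"].rho.reshape(shp).astype(np.float32),
                    rho_fracture=per_group["fracture"].rho.reshape(shp).astype(np.float32),
                    delta_rho=diff.delta_rho.reshape(shp).astype(np.float32),
                    p_diff=diff.p.reshape(shp).astype(np.float32),
                    sig_diff=diff.significant.reshape(shp),
                )
                summary.append(
                    {
                        "pair": f"{a}-{b}",
                        "control_mean_rho": float(np.nanmean(per_group["control"].rho)),
                        "fracture_mean_rho": float(np.nanmean(per_group["fracture"].rho)),
                        "significant_fraction": float(diff.significant.mean()),
                    }
                )
            pd.DataFrame(summary).to_csv(
                sdir / "spm_summary.csv", index=False, float_format="%.8g"
            )

    report(out)


_RUNNERS = {
    "synth": _run_synth,
    "segment": _run_segment,
    "metrics": _run_metrics,
    "fea": _run_fea,
    "maps": _run_maps,
    "normalize": _run_normalize,
    "stats": _run_stats,
}


# --------------------------------------------------------------------------
# report and input validation
# --------------------------------------------------------------------------


def report(out: Path | str) -> str:
    """Human-readable summary of group comparisons and correlations."""
    out = Path(out)
    lines = ["bonespm run report", "=" * 60]
    missing = []
    for title, name in (
        ("Group comparisons (adjusted for age, height, weight)",
         "stats/group_comparisons.csv"),
        ("Within-group partial correlations (Controls vs. Fracture cases)",
         "stats/global_correlations.csv"),
        ("Correlations with failure load", "stats/failure_load_correlations.csv"),
        ("Voxel-wise SPM summary", "stats/spm_summary.csv"),
    ):
        path = out / name
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        if not path.exists():
            lines.append("unavailable (outputs missing)")
            missing.append(name)
            continue
        try:
            table = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            lines.append("unavailable (no rows)")
            continue
        if table.empty:
            lines.append("unavailable (no rows)")
            continue
        lines.append(table.round(4).to_string(index=False))
    mpath = out / "run_manifest.json"
    if mpath.exists():
        data = json.loads(mpath.read_text())
        lines.append("")
        lines.append(f"excluded subjects (motion grade > 3): "
                     f"{len(data.get('excluded_subjects', []))}")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text


def validate_inputs(directory: Path | str) -> pd.DataFrame:
    """Check a cohort directory (volumes + manifest.csv) for analyzability."""
    directory = Path(directory)
    manifest_csv = directory / "manifest.csv"
    if not manifest_csv.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    df = pd.read_csv(manifest_csv)
    results = []
    for _, row in df.iterrows():
        sid = row.get("id", "?")
        reasons = []
        for covariate in ("age", "height", "weight"):
            if covariate not in row or pd.isna(row[covariate]):
                reasons.append(f"missing {covariate}")
        path = directory / str(row.get("volume_file", f"{sid}.nii.gz"))
        if not path.exists():
            reasons.append("volume file missing")
        else:
            try:
                vol = CalibratedVolume.load(path)
                if not vol.is_isotropic:
                    reasons.append("anisotropic")
                if vol.shape[2] < 8:
                    reasons.append("too few slices")
                finite = np.asarray(vol.data)[np.isfinite(vol.data)]
                if finite.size == 0 or finite.max() < 200:
                    reasons.append("implausible calibration range")
            except Exception as exc:
                reasons.append(f"unreadable volume: {exc}")
        results.append(
            {"id": sid, "pass": not reasons, "reasons": "; ".join(reasons)}
        )
    return pd.DataFrame(results)
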