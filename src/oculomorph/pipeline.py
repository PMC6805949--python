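"""End-to-end orchestration: simulate -> measure -> template -> stats -> ROC.

Everything is driven by a serializable :class:`PipelineConfig`; a run writes
standard formats (NIfTI masks, CSV tables, JSON reports) plus a manifest
with the seed, config, and SHA-256 hashes of every output, so a run is
reproducible and auditable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import phantom, stats as cstats, template as tpl
from .morphometry import EyeMask, measure_eye

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "read_mask",
    "write_mask",
    "report",
]

ALL_STAGES = ("simulate", "measure", "template", "stats", "roc")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full configuration of a pipeline run (JSON-serializable)."""

    seed: int = 0
    voxel_size: float = 0.7
    group_params: list = field(default_factory=phantom.default_group_params)
    correlation: pd.DataFrame = field(default_factory=phantom.default_correlation)
    smoothing_sigma_mm: float = 0.7
    template_threshold: float = 0.5
    n_splits: int = 200
    roc_predictors: tuple = ("volume", "etiv")
    roc_label: str = "glaucoma"
    out_dir: str = "oculomorph_run"
    save_masks: bool = False
    stages: tuple = ALL_STAGES
    template_groups: tuple = ("control", "myopia", "glaucoma", "glaucoma_myopia")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["group_params"] = [dataclasses.asdict(g) for g in self.group_params]
        d["correlation"] = {
            "variables": list(self.correlation.columns),
            "rho": self.correlation.to_numpy().tolist(),
        }
        return json.dumps(d, indent=2, default=str)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["group_params"] = [phantom.GroupParams(**g) for g in d["group_params"]]
        corr = d["correlation"]
        d["correlation"] = pd.DataFrame(np.asarray(corr["rho"]),
                                        index=corr["variables"],
                                        columns=corr["variables"])
        for key in ("roc_predictors", "stages", "template_groups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# NIfTI mask I/O (RAS affine, anterior = +y; sidecar JSON for landmarks)
# ---------------------------------------------------------------------------

def write_mask(mask: EyeMask, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    if mask.landmarks:
        side = {k: np.asarray(v).tolist() for k, v in mask.landmarks.items()}
        side["eye_side"] = mask.eye_side
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
        Path(str(sidecar) + ".json").write_text(json.dumps(side))


def read_mask(path, eye_side: str | None = None) -> EyeMask:
    """Load a NIfTI binary mask; the affine must be axis-aligned (not oblique).

    Non-binary volumes are binarized at 0.5 with a warning.  A sidecar
    ``<name>.json`` with mm landmarks is picked up automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-4 * max(1.0, np.max(np.abs(rot))):
        raise ValueError(f"oblique affine not supported: {path}")
    if np.any(np.diag(rot) <= 0):
        raise ValueError(f"non-RAS (negative/zero spacing) affine: {path}")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        warnings.warn(f"non-binary volume {path}: binarizing at 0.5", stacklevel=2)
    binary = data >= 0.5

    landmarks = {}
    side = eye_side
    sidecar = Path(str(path).removesuffix(".nii.gz").removesuffix(".nii") + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        side = side or meta.pop("eye_side", None)
        landmarks = {k: np.asarray(v, float) for k, v in meta.items()
                     if isinstance(v, (list, tuple))}
    return EyeMask(binary, voxel_size=tuple(np.diag(rot)),
                   origin=tuple(affine[:3, 3]), eye_side=side or "right",
                   landmarks=landmarks)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, out, manifest):
    cohort = phantom.sample_cohort(cfg.group_params, cfg.correlation, seed=cfg.seed)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    masks = phantom.masks_from_cohort(cohort, seed=cfg.seed,
                                      voxel_size=cfg.voxel_size)
    if not masks:
        raise ValueError("no masks")
    if cfg.save_masks:
        mask_dir = out / "masks"
        mask_dir.mkdir(exist_ok=True)
        for (sid, side), m in masks.items():
            write_mask(m, mask_dir / f"{sid}_{side}.nii.gz")
    manifest["n_eyes_simulated"] = len(masks)
    return cohort, masks


def _stage_measure(cfg, out, manifest, cohort, masks):
    rows = []
    for (sid, side), m in masks.items():
        res = measure_eye(m)
        rows.append({
            "subject_id": sid, "eye_side": side,
            "measured_volume": round(res.volume, 0),
            "measured_axial": round(res.axial_length, 1),
            "measured_transverse": round(res.transverse_length, 1),
            "measured_anisotropy": res.axial_length / res.transverse_length,
            "apex_x": res.frame.apex[0], "apex_y": res.frame.apex[1],
            "apex_z": res.frame.apex[2],
            "disk_x": res.frame.disk[0], "disk_y": res.frame.disk[1],
            "disk_z": res.frame.disk[2],
        })
    morpho = pd.DataFrame(rows)
    morpho.to_csv(out / "morphometry.csv", index=False)
    joined = cohort.merge(morpho, on=["subject_id", "eye_side"], how="inner")
    joined.to_csv(out / "cohort_morphometry.csv", index=False)
    manifest["n_eyes_measured"] = len(morpho)
    return joined


def _stage_template(cfg, out, manifest, cohort, masks):
    spacing = cfg.voxel_size
    info = {}
    for side in ("right", "left"):
        side_keys = [k for k in masks if k[1] == side]
        if len(side_keys) < 2:
            continue
        side_masks = [masks[k] for k in side_keys]
        shape = tpl._common_shape(side_masks)
        blurry = tpl.voxelwise_average(side_masks, shape=shape)
        from scipy import ndimage
        blurry = ndimage.gaussian_filter(blurry, 1.0)
        aligned = [tpl.resample_mask(m, tpl.rigid_align(m, blurry), shape)
                   for m in side_masks]
        refined = np.mean(aligned, axis=0)
        group_of = dict(zip(zip(cohort["subject_id"], cohort["eye_side"]),
                            cohort["group"]))
        for group in cfg.template_groups:
            keys = [k for k in side_keys if group_of[k] == group]
            if len(keys) < 2:
                continue
            t = tpl.build_group_template(
                [masks[k] for k in keys], group, side,
                smoothing_sigma_mm=cfg.smoothing_sigma_mm,
                threshold=cfg.template_threshold,
                initial_template=refined)
            base = out / f"template_{group}_{side}"
            nib.save(nib.Nifti1Image(t.probability_volume.astype(np.float32),
                                     np.diag([spacing] * 3 + [1.0])),
                     str(base) + "_prob.nii.gz")
            nib.save(nib.Nifti1Image(t.final_mask.astype(np.uint8),
                                     np.diag([spacing] * 3 + [1.0])),
                     str(base) + "_mask.nii.gz")
            tpl.export_surface(t, str(base) + ".ply")
            info[f"{group}_{side}"] = {"n_contributing": t.n_contributing}
    manifest["templates"] = info


_CORR_VARS = ("age", "sex", "height", "etiv", "se", "stage", "md",
              "axial", "transverse", "anisotropy", "volume")


def _use_measured(table: pd.DataFrame) -> pd.DataFrame:
    """Prefer mask-measured morphometry over the sampled ground truth."""
    t = table.copy()
    for var in ("volume", "axial", "transverse", "anisotropy"):
        mcol = f"measured_{var}"
        if mcol in t.columns:
            t[var] = t[mcol]
    return t


def _stage_stats(cfg, out, manifest, table):
    table = _use_measured(table)
    corr = cstats.spearman_matrix(table, _CORR_VARS)
    corr.rho.to_csv(out / "correlations_rho.csv")
    corr.p_values.to_csv(out / "correlations_p.csv")
    anova_report = {}
    for outcome in ("volume", "axial", "transverse", "anisotropy"):
        res = cstats.two_factor_anova(table, outcome)
        anova_report[outcome] = {
            "effects": res.effects,
            "tukey": res.tukey.to_dict(orient="records"),
            "dunnett": res.dunnett.to_dict(orient="records"),
        }
    (out / "anova.json").write_text(json.dumps(anova_report, indent=2, default=str))
    manifest["anova_outcomes"] = list(anova_report)


def _stage_roc(cfg, out, manifest, table):
    table = _use_measured(table)
    sub = table[~table["ppg"]]
    summ = cstats.bootstrap_roc(sub, list(cfg.roc_predictors), cfg.roc_label,
                                n_splits=cfg.n_splits, seed=cfg.seed)
    pd.DataFrame({"fpr": summ.fpr_grid, "mean_tpr": summ.mean_tpr,
                  "tpr_sd": summ.tpr_sd}).to_csv(out / "roc_curve.csv", index=False)
    (out / "roc.json").write_text(json.dumps({
        "predictors": summ.predictors,
        "label": cfg.roc_label,
        "auc_of_mean_curve": summ.auc_of_mean_curve,
        "n_splits": summ.n_splits,
        "n_ridge_fallbacks": summ.n_ridge_fallbacks,
        "fpr_at_80_sensitivity": summ.fpr_at_sensitivity(0.80),
    }, indent=2))
    manifest["roc_auc"] = summ.auc_of_mean_curve


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": list(config.stages)}
    (out / "config.json").write_text(config.to_json())

    cohort = masks = joined = None
    try:
        stage = "simulate"
        if "simulate" in config.stages:
            cohort, masks = _stage_simulate(config, out, manifest)
        stage = "measure"
        if "measure" in config.stages:
            joined = _stage_measure(config, out, manifest, cohort, masks)
        stage = "template"
        if "template" in config.stages:
            _stage_template(config, out, manifest, cohort, masks)
        stage = "stats"
        if "stats" in config.stages:
            _stage_stats(config, out, manifest, joined if joined is not None else cohort)
        stage = "roc"
        if "roc" in config.stages:
            _stage_roc(config, out, manifest, joined if joined is not None else cohort)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    import oculomorph
    manifest["versions"] = {
        "oculomorph": oculomorph.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# summary report (group table + figures)
# ---------------------------------------------------------------------------

_TABLE_ROWS = [
    ("Number of eyes", None),
    ("IOP (mmHg) (mean ± SD)", "iop"),
    ("Age (years), (mean ± SD)", "age"),
    ("Height (cm), (mean ± SD)", "height"),
    ("eTIV (mm³ × 10³)(mean ± SD)", "etiv"),
    ("SE (D), mean (SD)", "se"),
    ("Visual sensitivity (MD) (mean ± SD)", "md"),
    ("Eye volume (mm³) (mean ± SD)", "volume"),
    ("Axial length (mm) (mean ± SD)", "axial"),
    ("Transverse length (mm) (mean ± SD)", "transverse"),
    ("Anisotropic ratio, (mean ± SD)", "anisotropy"),
]


def _group_table(cohort: pd.DataFrame) -> pd.DataFrame:
    groups = [g for g in phantom.GROUP_LABELS if (cohort["group"] == g).any()]
    data = {}
    for g in groups:
        sub = cohort[cohort["group"] == g]
        col = {}
        for name, var in _TABLE_ROWS:
            if var is None:
                col[name] = str(len(sub))
            else:
                col[name] = f"{sub[var].mean():.1f} ± {sub[var].std():.1f}" \
                    if var != "anisotropy" else \
                    f"{sub[var].mean():.2f} ± {sub[var].std():.2f}"
        data[g] = col
    return pd.DataFrame(data)


def report(run_dir) -> dict:
    """Render the summary artifacts of a finished (or partial) run.

    Produces a group summary table (CSV), a correlation heatmap, group bar
    charts, and the ROC curve plot; missing stage outputs are listed in the
    returned dict rather than raising.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    produced, missing = [], []

    cohort_path = run_dir / "cohort.csv"
    if cohort_path.exists():
        cohort = pd.read_csv(cohort_path)
        gt = _group_table(cohort)
        gt.to_csv(run_dir / "report_group_table.csv")
        produced.append("report_group_table.csv")

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, var, title in zip(axes, ("volume", "anisotropy"),
                                  ("Eye volume (mm^3)", "Anisotropy ratio")):
            means = cohort.groupby("group")[var].mean()
            sds = cohort.groupby("group")[var].std()
            means.plot.bar(yerr=sds, ax=ax, capsize=3)
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(run_dir / "report_group_bars.png", dpi=100)
        plt.close(fig)
        produced.append("report_group_bars.png")
    else:
        missing.append("cohort")

    rho_path = run_dir / "correlations_rho.csv"
    if rho_path.exists():
        rho = pd.read_csv(rho_path, index_col=0)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(rho.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(rho)), rho.columns, rotation=90)
        ax.set_yticks(range(len(rho)), rho.index)
        fig.colorbar(im, ax=ax, label="Spearman rho")
        fig.tight_layout()
        fig.savefig(run_dir / "report_correlations.png", dpi=100)
        plt.close(fig)
        produced.append("report_correlations.png")
    else:
        missing.append("stats")

    roc_path = run_dir / "roc_curve.csv"
    if roc_path.exists():
        roc = pd.read_csv(roc_path)
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(roc["fpr"], roc["mean_tpr"], label="mean curve")
        ax.fill_between(roc["fpr"], roc["mean_tpr"] - roc["tpr_sd"] / 2,
                        roc["mean_tpr"] + roc["tpr_sd"] / 2, alpha=0.3,
                        label="half-SD band")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False-positive rate")
        ax.set_ylabel("True-positive rate")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "report_roc.png", dpi=100)
        plt.close(fig)
        produced.append("report_roc.png")
    else:
        missing.append("roc")

    summary = {"produced": produced, "missing_sections": missing}
    (run_dir / "report.json").write_text(json.dumps(summary, indent=2))
    return summary
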