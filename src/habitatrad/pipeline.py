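"""End-to-end orchestration: simulate -> preprocess -> regions -> extract
-> select -> train -> evaluate, with a per-stage manifest for resumable,
reproducible runs.

Each stage reads its inputs from the run directory and writes its
outputs there; the manifest records the config hash and output list per
stage, and a completed stage whose outputs still exist is skipped on
re-run. Deleting a stage's outputs re-runs that stage only.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import RunConfig
from .evaluation import evaluate_models, operating_point
from .features import DiscretizationSpec, extract_sample_features, tidy_table
from .models import build_nomogram, clinical_analysis, dtl_placeholder_signature, train_signature
from .preprocess import clip_intensities, resample_isotropic
from .regions import build_region_set
from .selection import run_cascade
from .synthetic import CohortSpec, generate_cohort, write_cohort
from .volume import AnnotatedVolume, load_nifti_pair, save_nifti_pair

__all__ = ["PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("habitatrad.pipeline")

STAGES = ("simulate", "preprocess", "regions", "extract", "select", "train", "evaluate")

#: signature sources: region-tag prefixes feeding each signature
SIGNATURE_REGIONS = {
    "intra": ("intra",),
    "peri1": ("peri1",),
    "peri3": ("peri3",),
    "peri5": ("peri5",),
    "habitat": ("habitat1", "habitat2", "habitat3"),
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ------------------------------------------------------------ manifest

def _load_manifest(run_dir: Path) -> dict:
    path = run_dir / "manifest.json"
    return json.loads(path.read_text()) if path.exists() else {}


def _save_manifest(run_dir: Path, manifest: dict) -> None:
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _stage_done(run_dir: Path, manifest: dict, stage: str, digest: str) -> bool:
    entry = manifest.get(stage)
    if not entry or entry.get("digest") != digest or not entry.get("completed"):
        return False
    return all((run_dir / p).exists() for p in entry.get("outputs", []))


def _mark_done(run_dir: Path, manifest: dict, stage: str, digest: str, outputs: list[str]) -> None:
    manifest[stage] = {"digest": digest, "completed": True, "outputs": outputs,
                       "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    _save_manifest(run_dir, manifest)


# -------------------------------------------------------------- stages

def _sample_ids(run_dir: Path) -> list[str]:
    return list(pd.read_csv(run_dir / "data" / "manifest.csv")["sample_id"])


def _stage_simulate(cfg: RunConfig, run_dir: Path) -> list[str]:
    spec = CohortSpec(seed=cfg.seed, **{k: tuple(v) if isinstance(v, list) else v
                                        for k, v in cfg.cohort.items()})
    samples = generate_cohort(spec)
    write_cohort(samples, run_dir / "data")
    # freeze the stratified train/validation split at generation time so
    # downstream stages never re-derive it (no-leakage audit relies on this)
    labels = pd.Series({r.sample_id: int(r.egfr == "mutant") for _, r in samples})
    rng = np.random.default_rng(cfg.seed + 1)
    train_ids: list[str] = []
    for cls in (0, 1):
        ids = list(labels.index[labels == cls])
        rng.shuffle(ids)
        train_ids += ids[: int(round(cfg.models["train_fraction"] * len(ids)))]
    part = pd.Series(["train" if i in set(train_ids) else "val" for i in labels.index],
                     index=labels.index, name="partition")
    part.rename_axis("sample_id").to_csv(run_dir / "data" / "partition.csv")
    return ["data/manifest.csv", "data/clinical.csv", "data/partition.csv"]


def _stage_preprocess(cfg: RunConfig, run_dir: Path) -> list[str]:
    out = run_dir / "preproc"
    out.mkdir(exist_ok=True)
    outputs = []
    for sid in _sample_ids(run_dir):
        vol = load_nifti_pair(run_dir / "data" / f"{sid}_image.nii.gz",
                              run_dir / "data" / f"{sid}_mask.nii.gz")
        vol = clip_intensities(vol, cfg.preprocess["clip_lo_hu"], cfg.preprocess["clip_hi_hu"])
        vol = resample_isotropic(vol, cfg.preprocess["target_spacing_mm"], sample_name=sid)
        save_nifti_pair(vol, out / f"{sid}_image.nii.gz", out / f"{sid}_mask.nii.gz")
        outputs += [f"preproc/{sid}_image.nii.gz", f"preproc/{sid}_mask.nii.gz"]
    (out / "params.json").write_text(json.dumps(cfg.preprocess, indent=2))
    return outputs + ["preproc/params.json"]


def _load_preproc(run_dir: Path, sid: str) -> AnnotatedVolume:
    vol = load_nifti_pair(run_dir / "preproc" / f"{sid}_image.nii.gz",
                          run_dir / "preproc" / f"{sid}_mask.nii.gz")
    vol.meta["sample_id"] = sid
    return vol


def _stage_regions(cfg: RunConfig, run_dir: Path) -> list[str]:
    out = run_dir / "regions"
    out.mkdir(exist_ok=True)
    outputs = []
    for sid in _sample_ids(run_dir):
        vol = _load_preproc(run_dir, sid)
        rs = build_region_set(vol, tuple(cfg.regions["shell_radii_mm"]),
                              k=cfg.regions["k"], seed=cfg.seed)
        lab = AnnotatedVolume(rs.habitat_labels.astype(float), vol.spacing_mm, vol.mask)
        save_nifti_pair(lab, out / f"{sid}_habitats.nii.gz", out / f"{sid}_tumor.nii.gz")
        outputs += [f"regions/{sid}_habitats.nii.gz", f"regions/{sid}_tumor.nii.gz"]
    return outputs


def _perturbed_mask(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask)
    return eroded if eroded.any() else ndimage.binary_dilation(mask)


def _region_set_from_files(cfg, run_dir, vol, sid):
    from .regions import RegionSet, peritumoral_shell

    hab = load_nifti_pair(run_dir / "regions" / f"{sid}_habitats.nii.gz",
                          run_dir / "regions" / f"{sid}_tumor.nii.gz")
    habitat_labels = hab.intensities.astype(np.int32)
    shells = {float(r): peritumoral_shell(vol.mask, vol.spacing_mm, float(r))
              for r in cfg.regions["shell_radii_mm"]}
    return RegionSet(vol.mask.copy(), shells, habitat_labels, cfg.regions["k"])


def _extract_table(cfg: RunConfig, run_dir: Path, perturb: bool) -> pd.DataFrame:
    disc = DiscretizationSpec(bin_width=cfg.features["bin_width_hu"])
    sigmas = tuple(cfg.features["log_sigmas_mm"] or ())
    wavelet = cfg.features["wavelet"]
    rows = []
    for sid in _sample_ids(run_dir):
        vol = _load_preproc(run_dir, sid)
        if perturb:
            vol = vol.with_(mask=_perturbed_mask(vol.mask))
            rs = build_region_set(vol, tuple(cfg.regions["shell_radii_mm"]),
                                  k=cfg.regions["k"], seed=cfg.seed)
        else:
            rs = _region_set_from_files(cfg, run_dir, vol, sid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(extract_sample_features(vol, rs, disc, sigmas, wavelet))
    return pd.DataFrame(rows)


def _stage_extract(cfg: RunConfig, run_dir: Path) -> list[str]:
    out = run_dir / "features"
    out.mkdir(exist_ok=True)
    wide = _extract_table(cfg, run_dir, perturb=False)
    wide.index.name = "sample_id"
    wide.to_csv(out / "features_wide.csv")
    tidy_table(wide).to_csv(out / "features_tidy.csv", index=False)
    outputs = ["features/features_wide.csv", "features/features_tidy.csv"]
    if cfg.selection["icc"]:
        retest = _extract_table(cfg, run_dir, perturb=True)
        retest.index.name = "sample_id"
        retest.to_csv(out / "features_retest_wide.csv")
        outputs.append("features/features_retest_wide.csv")
    return outputs


def _partitions(cfg: RunConfig, run_dir: Path) -> tuple[pd.Index, pd.Index, pd.Series]:
    clinical = pd.read_csv(run_dir / "data" / "clinical.csv", index_col=0)
    labels = (clinical["egfr"] == "mutant").astype(int)
    part = pd.read_csv(run_dir / "data" / "partition.csv", index_col=0)["partition"]
    train = pd.Index(sorted(part.index[part == "train"]))
    val = pd.Index(sorted(part.index[part == "val"]))
    return train, val, labels


def _stage_select(cfg: RunConfig, run_dir: Path) -> list[str]:
    out = run_dir / "selection"
    out.mkdir(exist_ok=True)
    wide = pd.read_csv(run_dir / "features" / "features_wide.csv", index_col=0)
    retest = None
    if cfg.selection["icc"]:
        retest = pd.read_csv(run_dir / "features" / "features_retest_wide.csv", index_col=0)
    train, _, labels = _partitions(cfg, run_dir)

    outputs = []
    chosen: dict[str, list[str]] = {}
    scalers: dict[str, dict] = {}
    for tag, prefixes in SIGNATURE_REGIONS.items():
        cols = [c for c in wide.columns if c.split("|")[0] in prefixes]
        sub = wide.loc[train, cols]
        sub_retest = retest.loc[train, cols] if retest is not None else None
        survivors, scaler, report = run_cascade(
            sub, sub_retest, labels.loc[train].to_numpy(),
            icc_threshold=cfg.selection["icc_threshold"],
            alpha=cfg.selection["alpha"],
            r_threshold=cfg.selection["r_threshold"],
            mrmr_k=cfg.selection["mrmr_k"],
            lasso_folds=cfg.selection["lasso_folds"],
            seed=cfg.seed,
        )
        chosen[tag] = survivors
        scalers[tag] = {"mean": scaler.mean.to_dict(), "std": scaler.std.to_dict()}
        report.to_json(out / f"{tag}_report.json")
        for stage in report.stages:
            pd.Series(report.survivors[stage]).to_csv(
                out / f"{tag}_{stage}_survivors.csv", index=False, header=["feature"])
        outputs.append(f"selection/{tag}_report.json")
    (out / "selected.json").write_text(json.dumps(chosen, indent=2))
    (out / "scalers.json").write_text(json.dumps(scalers, indent=2))
    return outputs + ["selection/selected.json", "selection/scalers.json"]


def _standardized(wide: pd.DataFrame, scaler: dict, cols: list[str]) -> pd.DataFrame:
    mu = pd.Series(scaler["mean"])
    sd = pd.Series(scaler["std"])
    return (wide[cols] - mu[cols]) / sd[cols]


def _stage_train(cfg: RunConfig, run_dir: Path) -> list[str]:
    out = run_dir / "models"
    out.mkdir(exist_ok=True)
    wide = pd.read_csv(run_dir / "features" / "features_wide.csv", index_col=0)
    chosen = json.loads((run_dir / "selection" / "selected.json").read_text())
    scalers = json.loads((run_dir / "selection" / "scalers.json").read_text())
    train, val, labels = _partitions(cfg, run_dir)

    scores = pd.DataFrame(index=wide.index)
    scores["partition"] = ["train" if i in train else "val" for i in wide.index]
    scores["label"] = labels
    provenance = {}
    for tag, survivors in chosen.items():
        if not survivors:
            log.warning("signature %s: empty selection, skipped", tag)
            continue
        z = _standardized(wide, scalers[tag], survivors)
        algo = cfg.models["algorithms"].get(tag, "svm")
        model = train_signature(z.loc[train], labels.loc[train].to_numpy(), algo,
                                seed=cfg.seed, cv_folds=cfg.models["cv_folds"],
                                region_tag=tag)
        scores[tag] = model.scores(z)
        provenance[tag] = {"algorithm": algo, "best_params": model.best_params,
                           "cv_auc": model.cv_auc, "features": survivors}
    if cfg.models.get("dtl", True):
        vols = [_load_preproc(run_dir, sid) for sid in wide.index]
        tr_pos = np.array([i for i, sid in enumerate(wide.index) if sid in train])
        scores["dtl"] = dtl_placeholder_signature(vols, labels.to_numpy(), tr_pos, cfg.seed)
    scores.to_csv(out / "scores.csv")
    (out / "models.json").write_text(json.dumps(provenance, indent=2))
    return ["models/scores.csv", "models/models.json"]


def _stage_evaluate(cfg: RunConfig, run_dir: Path) -> list[str]:
    out = run_dir / "evaluation"
    out.mkdir(exist_ok=True)
    scores = pd.read_csv(run_dir / "models" / "scores.csv", index_col=0)
    clinical = pd.read_csv(run_dir / "data" / "clinical.csv", index_col=0)
    train_mask = scores["partition"] == "train"
    labels = scores["label"]
    model_cols = [c for c in scores.columns if c not in ("partition", "label")]

    # nomogram: P3 + habitat (+ DTL) signatures + smoking, trained on train
    nomo_cols = [c for c in ("peri3", "habitat", "dtl") if c in model_cols]
    smoking = (clinical.loc[scores.index, "smoking"] == "yes").astype(float).to_numpy()
    if nomo_cols:
        nomo = build_nomogram(scores.loc[train_mask, nomo_cols],
                              smoking[train_mask.to_numpy()],
                              labels[train_mask].to_numpy())
        X_all = scores[nomo_cols].copy()
        X_all["smoking"] = smoking
        scores["nomogram"] = nomo.predict_proba(X_all)
        model_cols.append("nomogram")

    try:
        ca = clinical_analysis(clinical.loc[scores.index], labels.to_numpy())
        ca.univariable.to_csv(out / "clinical_univariable.csv")
        ca.multivariable.to_csv(out / "clinical_multivariable.csv")
    except ValueError as e:
        log.warning("clinical analysis skipped: %s", e)

    report = {}
    thresholds = {
        m: operating_point(scores.loc[train_mask, m], labels[train_mask])["threshold"]
        for m in model_cols
    }
    for part in ("train", "val"):
        sel = scores["partition"] == part
        rep = evaluate_models({m: scores.loc[sel, m].to_numpy() for m in model_cols},
                              labels[sel].to_numpy(), thresholds)
        report[part] = rep.to_dict()
        rep.dca.to_csv(out / f"dca_{part}.csv", index=False)
        _figures(rep, scores.loc[sel], model_cols, labels[sel], out, part)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    scores.to_csv(out / "scores_with_nomogram.csv")
    return ["evaluation/report.json"]


def _figures(rep, scores, model_cols, labels, out: Path, part: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))
    for m in model_cols:
        fpr, tpr, _ = roc_curve(labels, scores[m])
        axes[0].plot(fpr, tpr, label=f"{m} (AUC {rep.auc[m]:.3f})")
        cal = rep.calibration[m]
        axes[1].plot(cal["mean_predicted"], cal["observed"], marker="o", label=m)
        axes[2].plot(rep.dca["threshold"], rep.dca[m], label=m)
    axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
    axes[0].set(xlabel="1 - specificity", ylabel="sensitivity", title=f"ROC ({part})")
    axes[1].plot([0, 1], [0, 1], "k--", lw=0.8)
    axes[1].set(xlabel="mean predicted", ylabel="observed", title="calibration")
    axes[2].plot(rep.dca["threshold"], rep.dca["treat_all"], "k:", label="treat all")
    axes[2].axhline(0.0, color="k", lw=0.8)
    axes[2].set(xlabel="threshold probability", ylabel="net benefit", title="decision curves",
                ylim=(-0.1, max(0.6, float(labels.mean()) + 0.1)))
    for ax in axes:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / f"evaluation_{part}.svg")
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "regions": _stage_regions,
    "extract": _stage_extract,
    "select": _stage_select,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES, force: bool = False) -> Path:
    """Execute the pipeline; returns the run directory.

    Completed stages (per the manifest) are skipped unless ``force``.
    A failing stage preserves partial results and raises
    :class:`PipelineError` naming the stage.
    """
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    digest = cfg.digest()
    manifest = _load_manifest(run_dir)
    for stage in STAGES:
        if stage not in stages:
            continue
        if not force and _stage_done(run_dir, manifest, stage, digest):
            log.info("stage %s: up to date, skipped", stage)
            continue
        t0 = time.time()
        log.info("stage %s: running", stage)
        try:
            outputs = _STAGE_FUNCS[stage](cfg, run_dir)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        _mark_done(run_dir, manifest, stage, digest, outputs)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    return run_dir
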