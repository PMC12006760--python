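"""End-to-end drivers: simulate -> fit -> phasor -> features -> classify.

Two entry points:

* :func:`run_synthetic_study` — in-memory benchmark over conditions x
  batches x fields, returning the QC-filtered feature table, the phasor
  table and the pooled ground truth. This is what the statistical
  benchmarks and the acceptance script use.
* :func:`run_pipeline` — staged, disk-backed driver behind the CLI:
  each stage reads the previous stage's files from the run directory and
  a manifest records versions, seeds, outputs and file hashes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    aggregate_cell_features,
    apply_qc_filters,
    assign_cd69_labels,
    normalize_orr,
    segment_cd69,
    segment_cells,
    OMI_FEATURES,
    NADH_FEATURES,
)
from .fitting import FitImageResult, default_fit_config, fit_image
from .io import (
    read_field,
    sha256_file,
    write_field,
    write_fit_maps,
    write_json,
    write_table,
)
from .phasor import phasor_feature_table, phasor_qc_filter
from .simulate import CONDITIONS, FieldData, SimConfig, simulate_field
from .statsml import (
    coefficient_of_variation,
    glass_delta,
    train_activation_classifier,
    train_phasor_classifier,
)

__all__ = [
    "StudyConfig", "StudyResult", "RunConfig", "PipelineError",
    "analyze_field", "run_synthetic_study", "run_pipeline",
]

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "fit", "phasor", "features", "classify", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _default_study_sim() -> SimConfig:
    # 55 cells/field x 3 batches x 2 conditions x 2 fields ~= 600 labeled cells
    return SimConfig(n_cells=55)


@dataclass(frozen=True)
class StudyConfig:
    """A multi-batch two-condition synthetic study."""

    sim: SimConfig = field(default_factory=_default_study_sim)
    n_batches: int = 3
    fields_per_batch: int = 2  # per condition
    conditions: tuple[str, ...] = CONDITIONS
    use_truth_masks: bool = False
    min_photons: float = 5000.0
    min_area_px: int = 250
    max_chi2: float = 1.3


@dataclass
class StudyResult:
    features: pd.DataFrame  # QC-filtered CellRecord table with orr_norm
    phasors: pd.DataFrame  # QC-filtered cell-level phasor table with labels
    ground_truth: pd.DataFrame
    exclusions: dict[str, int]


@dataclass
class FieldAnalysis:
    features: pd.DataFrame
    phasors: pd.DataFrame
    nadh_fit: FitImageResult
    fad_fit: FitImageResult
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray


def analyze_field(
    field_data: FieldData,
    use_truth_masks: bool = False,
    max_chi2: float = 1.3,
) -> FieldAnalysis:
    """Fit, segment and feature-extract one field of view.

    Segmentation runs on the NAD(P)H intensity image (ground-truth masks
    can be substituted for ablation); CD69 status comes from thresholded
    marker-mask overlap; the phasor table carries the same per-cell labels
    as the feature table so both classifiers see identical cells.
    """
    if use_truth_masks:
        cells, nuclei = field_data.cell_mask, field_data.nucleus_mask
    else:
        cells, nuclei, _ = segment_cells(field_data.nadh.intensity())
    nadh_fit = fit_image(field_data.nadh, field_data.irf, default_fit_config("nadh"))
    fad_fit = fit_image(field_data.fad, field_data.irf, default_fit_config("fad"))
    cd69 = assign_cd69_labels(segment_cd69(field_data.cd69_image), cells)
    feats = aggregate_cell_features(
        nadh_fit, fad_fit,
        field_data.nadh.intensity(), field_data.fad.intensity(),
        cells, nuclei,
        condition=field_data.condition, batch_id=field_data.batch_id,
        cd69_positive=cd69, chi2_max=max_chi2,
    )
    ph = phasor_feature_table(field_data.nadh, field_data.fad, cells, irf=field_data.irf)
    ph = ph.merge(
        feats[["cell_id", "batch_id", "condition", "cd69_positive", "activation"]],
        on="cell_id", how="left",
    )
    return FieldAnalysis(
        features=feats, phasors=ph, nadh_fit=nadh_fit, fad_fit=fad_fit,
        cell_labels=cells, nucleus_labels=nuclei,
    )


def _field_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def iter_field_specs(config: StudyConfig) -> list[tuple[str, str, int]]:
    """(batch_id, condition, field index) for every field of the study."""
    return [
        (f"batch{b}", cond, f)
        for b in range(config.n_batches)
        for cond in config.conditions
        for f in range(config.fields_per_batch)
    ]


def run_synthetic_study(config: StudyConfig, seed: int = 0) -> StudyResult:
    """Simulate and analyze a full study in memory.

    Field seeds derive deterministically from ``seed``; cell ids are made
    unique across fields. The returned feature table is QC-filtered and
    ORR-normalized per batch; the phasor table is QC-filtered with the
    phasor pipeline's own cutoffs (5,000 photons, 50 pixels).
    """
    specs = iter_field_specs(config)
    seeds = _field_seeds(seed, len(specs))
    feats, phs, truths = [], [], []
    for (batch, cond, idx), field_seed in zip(specs, seeds):
        fd = simulate_field(config.sim, cond, seed=field_seed, batch_id=batch)
        ana = analyze_field(fd, config.use_truth_masks, config.max_chi2)
        tag = f"{batch}_{cond}_f{idx}"
        for df in (ana.features, ana.phasors, fd.ground_truth):
            df.insert(0, "field_id", tag)
        feats.append(ana.features)
        phs.append(ana.phasors)
        truths.append(fd.ground_truth)
        log.info("analyzed %s: %d cells", tag, len(ana.features))
    features = pd.concat(feats, ignore_index=True)
    phasors = pd.concat(phs, ignore_index=True)
    features, excl = apply_qc_filters(
        features, config.min_photons, config.min_area_px, config.max_chi2
    )
    features = normalize_orr(features)
    phasors = phasor_qc_filter(phasors, min_photons=config.min_photons)
    return StudyResult(
        features=features, phasors=phasors,
        ground_truth=pd.concat(truths, ignore_index=True), exclusions=excl,
    )


# ---------------------------------------------------------------------------
# staged, disk-backed pipeline


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a staged pipeline run rooted at ``out_dir``."""

    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    study: StudyConfig = field(default_factory=StudyConfig)
    classifier_test_size: float = 0.3
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        sim = SimConfig(**raw.pop("sim", {}))
        study_kw = raw.pop("study", {})
        study = StudyConfig(sim=sim, **study_kw)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return RunConfig(study=study, **raw)


def _validate(config: RunConfig) -> None:
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError("config", f"unknown stages {sorted(unknown)}")
    out = Path(config.out_dir)
    if "simulate" not in config.stages:
        fields_dir = out / "fields"
        if not fields_dir.is_dir() or not any(fields_dir.iterdir()):
            raise PipelineError(
                "config", f"stage inputs missing: no simulated fields under {fields_dir}"
            )
        for d in sorted(fields_dir.iterdir()):
            if d.is_dir() and not (d / "irf.json").exists():
                raise PipelineError("config", f"missing IRF file {d / 'irf.json'}")


def _field_dirs(out: Path) -> list[Path]:
    return sorted(p for p in (out / "fields").iterdir() if p.is_dir())


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order and write a run manifest.

    Stage outputs land under ``out_dir``; a failure raises
    :class:`PipelineError` naming the stage, leaving completed-stage
    outputs intact. The manifest records package/library versions, the
    seed, per-stage output paths with SHA-256 hashes, and exclusion
    counts, so identical configs and seeds reproduce identical manifests
    (timestamps aside, none are stored).
    """
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "versions": _library_versions(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": [str(p.relative_to(out)) for p in paths],
            "sha256": {str(p.relative_to(out)): sha256_file(p) for p in paths},
        }

    ordered = [s for s in ALL_STAGES if s in config.stages]
    for stage in ordered:
        try:
            paths = _STAGE_RUNNERS[stage](config, out, manifest)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc
        record(stage, paths)
        log.info("stage %s: %d outputs", stage, len(paths))

    write_json(manifest, out / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, out: Path, manifest: dict) -> list[Path]:
    specs = iter_field_specs(config.study)
    seeds = _field_seeds(config.seed, len(specs))
    paths = []
    for (batch, cond, idx), field_seed in zip(specs, seeds):
        fd = simulate_field(config.study.sim, cond, seed=field_seed, batch_id=batch)
        d = write_field(fd, out / "fields" / f"{batch}_{cond}_f{idx}")
        paths.extend(sorted(d.iterdir()))
    return paths


def _ensure_masks(config: RunConfig, field_dir: Path) -> tuple[np.ndarray, np.ndarray]:
    from .io import read_decay_stack, read_mask, write_mask

    seg_cell = field_dir / "seg_cell_mask.tif"
    seg_nuc = field_dir / "seg_nucleus_mask.tif"
    if seg_cell.exists() and seg_nuc.exists():
        return read_mask(seg_cell), read_mask(seg_nuc)
    if config.study.use_truth_masks:
        cells = read_mask(field_dir / "cell_mask.tif")
        nuclei = read_mask(field_dir / "nucleus_mask.tif")
    else:
        nadh = read_decay_stack(field_dir / "nadh.tif")
        cells, nuclei, _ = segment_cells(nadh.intensity())
    write_mask(cells, seg_cell)
    write_mask(nuclei, seg_nuc)
    return cells, nuclei


def _stage_fit(config: RunConfig, out: Path, manifest: dict) -> list[Path]:
    from .io import read_decay_stack, read_irf

    paths = []
    for d in _field_dirs(out):
        irf = read_irf(d / "irf.json")
        for chan in ("nadh", "fad"):
            image = read_decay_stack(d / f"{chan}.tif")
            fit = fit_image(image, irf, default_fit_config(chan))
            paths.extend(write_fit_maps(fit, d / "fit", chan))
    return paths


def _stage_phasor(config: RunConfig, out: Path, manifest: dict) -> list[Path]:
    from .io import read_decay_stack, read_irf

    rows = []
    for d in _field_dirs(out):
        cells, _ = _ensure_masks(config, d)
        ph = phasor_feature_table(
            read_decay_stack(d / "nadh.tif"), read_decay_stack(d / "fad.tif"),
            cells, irf=read_irf(d / "irf.json"),
        )
        ph.insert(0, "field_id", d.name)
        rows.append(ph)
    table = phasor_qc_filter(pd.concat(rows, ignore_index=True),
                             min_photons=config.study.min_photons)
    return [write_table(table, out / "phasors.csv")]


def _stage_features(config: RunConfig, out: Path, manifest: dict) -> list[Path]:
    import tifffile

    from .io import read_decay_stack, read_json

    feats = []
    for d in _field_dirs(out):
        meta = read_json(d / "nadh.json")
        cells, nuclei = _ensure_masks(config, d)
        nadh = read_decay_stack(d / "nadh.tif")
        fad = read_decay_stack(d / "fad.tif")
        fit_maps = {}
        for chan in ("nadh", "fad"):
            maps = {
                name: tifffile.imread(d / "fit" / f"{chan}_{name}.tif")
                for name in ("tau1", "tau2", "a1", "tau_m", "chi2", "photons")
            }
            fit_maps[chan] = FitImageResult(
                tau1=maps["tau1"], tau2=maps["tau2"], a1=maps["a1"],
                a1_raw=maps["a1"], a2_raw=1 - maps["a1"], C=np.zeros_like(maps["a1"]),
                tau_m=maps["tau_m"], chi2=maps["chi2"], photons=maps["photons"],
                bin_factor=np.zeros(maps["a1"].shape, np.int16),
                converged=np.isfinite(maps["tau_m"]),
            )
        cd69_img = tifffile.imread(d / "cd69.tif")
        cd69 = assign_cd69_labels(segment_cd69(cd69_img), cells)
        t = aggregate_cell_features(
            fit_maps["nadh"], fit_maps["fad"], nadh.intensity(), fad.intensity(),
            cells, nuclei, condition=meta["condition"], batch_id=meta["batch_id"],
            cd69_positive=cd69, chi2_max=config.study.max_chi2,
        )
        t.insert(0, "field_id", d.name)
        feats.append(t)
    table = pd.concat(feats, ignore_index=True)
    table, excl = apply_qc_filters(
        table, config.study.min_photons, config.study.min_area_px, config.study.max_chi2
    )
    table = normalize_orr(table)
    manifest["exclusions"] = excl
    return [write_table(table, out / "features.csv"), write_json(excl, out / "exclusions.json")]


def _stage_classify(config: RunConfig, out: Path, manifest: dict) -> list[Path]:
    from .io import read_table

    features = read_table(out / "features.csv")
    paths = []
    rep = train_activation_classifier(
        features, test_size=config.classifier_test_size, seed=config.seed
    )
    paths.append(write_json(rep.to_dict(), out / "classify_omi_rf.json"))
    nadh_rep = train_activation_classifier(
        features, features=NADH_FEATURES, feature_set="nadh",
        test_size=config.classifier_test_size, seed=config.seed,
    )
    paths.append(write_json(nadh_rep.to_dict(), out / "classify_omi_rf_nadh.json"))
    roc = pd.DataFrame({"fpr": rep.roc_fpr, "tpr": rep.roc_tpr})
    paths.append(write_table(roc, out / "classify_omi_rf_roc.csv"))

    ph_path = out / "phasors.csv"
    if ph_path.exists():
        phasors = read_table(ph_path)
        labels = features[["field_id", "cell_id", "activation"]]
        phasors = phasors.merge(labels, on=["field_id", "cell_id"], how="inner")
        for model in ("random_forest", "logistic"):
            rep_p = train_phasor_classifier(phasors, model=model, seed=config.seed)
            paths.append(write_json(rep_p.to_dict(), out / f"classify_phasor_{model}.json"))
    return paths


def _stage_report(config: RunConfig, out: Path, manifest: dict) -> list[Path]:
    from .io import read_table

    features = read_table(out / "features.csv")
    q = features[features["activation"] == "quiescent"]
    a = features[features["activation"] == "activated"]
    report: dict = {"n_quiescent": len(q), "n_activated": len(a), "effect_sizes": {}, "cv": {}}
    for var in OMI_FEATURES:
        if len(q) >= 2 and len(a) >= 1:
            es = glass_delta(q[var].to_numpy(), a[var].to_numpy())
            report["effect_sizes"][var] = {"delta": es.delta, "magnitude": es.magnitude}
        report["cv"][var] = {
            "quiescent": coefficient_of_variation(q[var].to_numpy()) if len(q) > 1 else None,
            "activated": coefficient_of_variation(a[var].to_numpy()) if len(a) > 1 else None,
        }
    return [write_json(report, out / "report.json")]


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "phasor": _stage_phasor,
    "features": _stage_features,
    "classify": _stage_classify,
    "report": _stage_report,
}


def _library_versions() -> dict[str, str]:
    import importlib

    out = {}
    for lib in ("numpy", "scipy", "pandas", "sklearn", "skimage", "tifffile"):
        try:
            out[lib] = importlib.import_module(lib).__version__
        except Exception:  # noqa: BLE001
            out[lib] = "unavailable"
    return out
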