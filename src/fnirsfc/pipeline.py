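"""Stage orchestration: simulate -> qc -> preprocess -> fc -> features ->
stats -> classify, with file-based handoff between stages.

Each stage consumes only the declared outputs of the previous stage, so
any stage can be rerun from disk; a missing intermediate raises a
FileNotFoundError naming the file.  Every numeric output gets a
provenance sidecar (stage, parameters, seed, software version), and
``run_all`` writes a manifest listing every artifact.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from . import stats as fstats
from .classifier import GridSpec, MddClassifier, RfConfig
from .connectivity import dynamic_fc, pair_labels, static_fc
from .features import extract_features
from .montage import Montage, load_default_montage
from .preprocess import PreprocessParams, RoiTimeSeries, preprocess_recording
from .qc import DEFAULT_SNR_THRESHOLD_DB, cohort_qc
from .synthetic import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the reference analysis values."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    snr_threshold_db: float = DEFAULT_SNR_THRESHOLD_DB
    preprocess: PreprocessParams = dataclasses.field(default_factory=PreprocessParams)
    window_s: float = 20.0
    step_s: float = 1.0
    ccr_lo: float = 90.0
    ccr_hi: float = 95.0
    fdr_alpha: float = 0.05
    cv_folds: int = 10
    cv_seed: int = 0
    grid: str = "reduced"  # "full", "reduced" or "none"
    #: used when grid == "none"; the reference optimum configuration
    fixed_config: tuple[int, int, float] = (70, 1, 0.8)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        obj = yaml.safe_load(text) or {}
        cfg = cls()
        sim = obj.pop("simulation", {})
        if sim:
            cfg.simulation = SimulationConfig(
                **{k: v for k, v in sim.items()}
            )
        for k, v in obj.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if k == "fixed_config" else v)
        return cfg

    def provenance(self) -> dict:
        return {
            "window_s": self.window_s,
            "step_s": self.step_s,
            "band_hz": list(self.preprocess.band_hz),
            "snr_threshold_db": self.snr_threshold_db,
            "ccr_band_pct": [self.ccr_lo, self.ccr_hi],
            "fdr_alpha": self.fdr_alpha,
            "cv_folds": self.cv_folds,
            "grid": self.grid,
            "simulation_seed": self.simulation.seed,
            "cv_seed": self.cv_seed,
        }


def _participants(workdir: Path) -> pd.DataFrame:
    clinical = fio.read_table(workdir / "clinical.csv").set_index("participant_id")
    return clinical


# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    montage = load_default_montage()
    cohort = simulate_cohort(config.simulation, montage)
    written = []
    for rec in cohort.recordings:
        p = outdir / "recordings" / f"{rec.participant_id}.csv"
        fio.write_recording_csv(rec, p)
        written.append(p)
    cohort.clinical.to_csv(outdir / "clinical.csv")
    fio.write_json(cohort.truth, outdir / "truth.json")
    (outdir / "montage.json").write_text(montage.to_json())
    fio.write_provenance(
        outdir / "simulate_provenance.json",
        "simulate",
        {"n_per_group": config.simulation.n_per_group},
        seed=config.simulation.seed,
    )
    written += [outdir / "clinical.csv", outdir / "truth.json", outdir / "montage.json"]
    logger.info("simulated %d recordings", len(cohort.recordings))
    return written


def stage_qc(config: PipelineConfig, workdir: str | Path) -> list[Path]:
    workdir = Path(workdir)
    montage = Montage.from_json((workdir / "montage.json").read_text())
    clinical = _participants(workdir)
    baselines = []
    for pid in clinical.index:
        rec = fio.read_recording_csv(workdir / "recordings" / f"{pid}.csv", pid)
        baselines.append(rec.baseline_segment())
    retained, reports = cohort_qc(baselines, montage, config.snr_threshold_db)
    frames = []
    for pid, rep in zip(clinical.index, reports):
        f = rep.to_frame()
        f.insert(0, "participant_id", pid)
        frames.append(f)
    pd.concat(frames).to_csv(workdir / "qc_report.tsv", sep="\t", index=False)
    (workdir / "montage_qc.json").write_text(retained.to_json())
    fio.write_provenance(
        workdir / "qc_provenance.json",
        "qc",
        {"threshold_db": config.snr_threshold_db,
         "retained_channels": retained.n_channels},
    )
    logger.info("QC retained %d channels", retained.n_channels)
    return [workdir / "qc_report.tsv", workdir / "montage_qc.json"]


def stage_preprocess(config: PipelineConfig, workdir: str | Path) -> list[Path]:
    workdir = Path(workdir)
    montage_path = workdir / "montage_qc.json"
    if not montage_path.exists():
        raise FileNotFoundError(f"missing input file: {montage_path} (run qc first)")
    montage = Montage.from_json(montage_path.read_text())
    clinical = _participants(workdir)
    out = workdir / "roi_timeseries"
    out.mkdir(exist_ok=True)
    written = []
    for pid in clinical.index:
        rec = fio.read_recording_csv(
            workdir / "recordings" / f"{pid}.csv", pid, group=clinical.loc[pid, "group"]
        )
        roi = preprocess_recording(rec, montage, config.preprocess)
        t = np.arange(roi.traces.shape[1]) / roi.sampling_rate
        fio.write_matrix(
            np.column_stack([t, roi.traces.T]),
            np.arange(roi.traces.shape[1]),
            ["time_s", *roi.roi_order],
            out / f"{pid}.csv",
            index_name="sample",
        )
        written.append(out / f"{pid}.csv")
    fio.write_provenance(
        workdir / "preprocess_provenance.json", "preprocess",
        config.preprocess.provenance(),
    )
    return written


def _read_roi_series(workdir: Path, pid: str, group: str) -> RoiTimeSeries:
    path = workdir / "roi_timeseries" / f"{pid}.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path} (run preprocess first)")
    df = fio.read_matrix(path)
    t = df["time_s"].to_numpy(float)
    rate = 1.0 / float(np.median(np.diff(t)))
    rois = tuple(c for c in df.columns if c != "time_s")
    return RoiTimeSeries(
        traces=df[list(rois)].to_numpy(float).T,
        roi_order=rois,
        sampling_rate=rate,
        participant_id=pid,
        group=group,
    )


def stage_fc(config: PipelineConfig, workdir: str | Path) -> list[Path]:
    workdir = Path(workdir)
    clinical = _participants(workdir)
    sdir, ddir = workdir / "static_fc", workdir / "dynamic_fc"
    sdir.mkdir(exist_ok=True)
    ddir.mkdir(exist_ok=True)
    written = []
    for pid in clinical.index:
        roi = _read_roi_series(workdir, pid, clinical.loc[pid, "group"])
        sfc = static_fc(roi)
        fio.write_matrix(sfc.z, roi.roi_order, roi.roi_order, sdir / f"{pid}.csv",
                         index_name="roi")
        dfc = dynamic_fc(roi, config.window_s, config.step_s)
        fio.write_matrix(
            dfc.X, dfc.pair_names,
            [f"{s:g}" for s in dfc.window_starts_s],
            ddir / f"{pid}.csv", index_name="pair",
        )
        written += [sdir / f"{pid}.csv", ddir / f"{pid}.csv"]
    fio.write_provenance(
        workdir / "fc_provenance.json", "fc",
        {"window_s": config.window_s, "step_s": config.step_s},
    )
    return written


def stage_features(config: PipelineConfig, workdir: str | Path) -> list[Path]:
    workdir = Path(workdir)
    clinical = _participants(workdir)
    series = [
        _read_roi_series(workdir, pid, clinical.loc[pid, "group"])
        for pid in clinical.index
    ]
    fx = extract_features(
        series, window_s=config.window_s, step_s=config.step_s,
        ccr_lo=config.ccr_lo, ccr_hi=config.ccr_hi,
    )
    fx.table.to_csv(workdir / "features.csv", float_format=fio.FLOAT_FMT)
    fio.write_json(
        {
            "n_components": fx.n_components,
            "shift_constant": fx.shift_constant,
            "mean_ccr_curve_pct": fx.mean_ccr_curve[:14],
            "ccr_band_pct": [config.ccr_lo, config.ccr_hi],
        },
        workdir / "features_meta.json",
    )
    fio.write_provenance(
        workdir / "features_provenance.json", "features", config.provenance()
    )
    return [workdir / "features.csv", workdir / "features_meta.json"]


def _read_features(workdir: Path) -> pd.DataFrame:
    path = workdir / "features.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path} (run features first)")
    return fio.read_table(path).set_index("participant_id")


def stage_stats(config: PipelineConfig, workdir: str | Path) -> list[Path]:
    workdir = Path(workdir)
    clinical = _participants(workdir)
    features = _read_features(workdir)
    groups = clinical["group"]
    gc = fstats.group_compare_features(features, groups)
    gc.to_csv(workdir / "group_stats.tsv", sep="\t", float_format=fio.FLOAT_FMT)
    fstats.demographics_table(clinical).to_csv(
        workdir / "demographics.tsv", sep="\t", float_format=fio.FLOAT_FMT
    )
    corr = fstats.spearman_feature_symptoms(features, clinical)
    corr.to_csv(workdir / "correlations.tsv", sep="\t", index=False,
                float_format=fio.FLOAT_FMT)
    regs = fstats.regression_per_outcome(features, clinical, corr, config.fdr_alpha)
    fio.write_json(
        {
            score: {
                "beta": res.beta.to_dict(),
                "t": res.tvalues.to_dict(),
                "p": res.pvalues.to_dict(),
                "r_squared": res.r_squared,
                "adj_r_squared": res.adj_r_squared,
                "model_p": res.model_p,
                "vif": res.vif.to_dict(),
                "diagnostics": res.diagnostics_ok,
                "n": res.n_obs,
            }
            for score, res in regs.items()
        },
        workdir / "regression.json",
    )
    fio.write_provenance(
        workdir / "stats_provenance.json", "stats", {"fdr_alpha": config.fdr_alpha}
    )
    return [workdir / "group_stats.tsv", workdir / "demographics.tsv",
            workdir / "correlations.tsv", workdir / "regression.json"]


def stage_classify(config: PipelineConfig, workdir: str | Path) -> list[Path]:
    workdir = Path(workdir)
    clinical = _participants(workdir)
    features = _read_features(workdir)
    labels = clinical.loc[features.index, "group"]
    pc_cols = [c for c in features.columns if c.startswith("pc")]
    model = MddClassifier(features, labels, fold_shift_columns=pc_cols)
    if config.grid == "none":
        grid = RfConfig(*config.fixed_config)
    elif config.grid == "reduced":
        grid = GridSpec.reduced()
    else:
        grid = GridSpec()
    result = model.fit(grid=grid, k=config.cv_folds, seed=config.cv_seed)
    fio.write_json(
        {
            "config": dataclasses.asdict(result.config),
            "metrics": result.metrics,
            "ci95": result.ci95,
            "fold_mean_accuracy_pct": result.fold_mean_accuracy_pct,
            "per_fold": result.per_fold.to_dict(orient="records"),
            "majority_baseline": result.majority_baseline,
        },
        workdir / "cv_result.json",
    )
    result.importances.rename("importance").to_frame().to_csv(
        workdir / "importances.tsv", sep="\t", float_format=fio.FLOAT_FMT
    )
    result.predictions.to_csv(workdir / "predictions.csv", index=False)
    fio.write_provenance(
        workdir / "classify_provenance.json", "classify",
        {"grid": config.grid, "folds": config.cv_folds}, seed=config.cv_seed,
    )
    return [workdir / "cv_result.json", workdir / "importances.tsv",
            workdir / "predictions.csv"]


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "preprocess": stage_preprocess,
    "fc": stage_fc,
    "features": stage_features,
    "stats": stage_stats,
    "classify": stage_classify,
}


def run_all(config: PipelineConfig, workdir: str | Path) -> dict:
    """Execute every stage in order and write a manifest of artifacts."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for name, fn in STAGES.items():
        try:
            if name == "simulate":
                paths = fn(config, workdir)
            else:
                paths = fn(config, workdir)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest[name] = [str(p.relative_to(workdir)) for p in paths]
        logger.info("stage %s: %d artifacts", name, len(paths))
    fio.write_json(
        {"stages": manifest, "parameters": config.provenance()},
        workdir / "manifest.json",
    )
    return manifest
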