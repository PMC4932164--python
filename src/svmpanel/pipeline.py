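"""End-to-end orchestration: discover -> validate -> report, from a config.

A :class:`PipelineConfig` describes one analysis run: either file inputs
(expression matrix + metadata + optional pool/probe map) or a synthetic
cohort spec, the preprocessing switches, the SVM and selection settings,
the repeated-split scheme, and optional validation cohorts. ``run_discovery``
and ``run_validation`` execute the stages and write plain-text artifacts
(TSV tables, JSON sidecars, a provenance manifest) into a run directory.

One master seed governs the synthetic generator and every resampling
stream; per-stage seeds are derived deterministically from it, so every
number in every output table is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    SplitScheme,
    cross_cohort_validate,
    fit_banded,
    grouped_loocv,
    match_panel_features,
    panel_correlations,
    repeated_split_cv,
)
from .io_data import (
    ExpressionDataset,
    annotate_genes,
    filter_diagnoses,
    read_expression,
    read_gene_pool,
    read_probe_map,
    restrict_to_pool,
    write_expression,
)
from .preprocess import correct_age_gender, floor_log_transform
from .selection import SvmSpec, rank_single_features, svmfs, svmtfs
from .synthetic import SyntheticSpec, generate_cohort, generate_cohort_pair

logger = logging.getLogger(__name__)

_STAGE_SEED_OFFSETS = {"generator": 0, "discovery_cv": 1, "validation_cv": 2}


@dataclass
class PipelineConfig:
    """Validated flat configuration of a pipeline run.

    Exactly one of ``inputs`` (paths) or ``synthetic`` (a SyntheticSpec)
    must be given. Unknown config keys are errors, not warnings.
    """

    output_dir: Path
    seed: int = 0
    inputs: Optional[dict[str, str]] = None        # matrix, meta, [pool, probe_map]
    synthetic: Optional[SyntheticSpec] = None
    keep_diagnoses: tuple[str, ...] = ("AD", "CONTROL")
    correction: bool = True
    correct_before_filter: bool = False
    svm: SvmSpec = field(default_factory=SvmSpec)
    methods: tuple[str, ...] = ("svmfs", "svmtfs")
    threshold: float = 0.0
    max_size: Optional[int] = None
    top_k: int = 20
    split: SplitScheme = field(default_factory=SplitScheme)
    validation_split: SplitScheme = field(default_factory=lambda: SplitScheme(
        n_train_pos=20, n_train_neg=20))
    fixed_panels: dict[str, list[str]] = field(default_factory=dict)
    validation_inputs: Optional[dict[str, str]] = None
    group_field: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("config must set exactly one of 'inputs' and 'synthetic'")
        unknown = [m for m in self.methods if m not in ("svmfs", "svmtfs")]
        if unknown:
            raise ValueError(f"unknown selection methods: {unknown}")
        self.output_dir = Path(self.output_dir)

    # -- YAML loading --------------------------------------------------------

    _KEYS = ("output_dir", "seed", "inputs", "synthetic", "keep_diagnoses",
             "correction", "correct_before_filter", "svm", "methods", "threshold",
             "max_size", "top_k", "split", "validation_split", "fixed_panels",
             "validation_inputs", "group_field")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - set(cls._KEYS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict[str, Any] = dict(raw)
        if kw.get("synthetic") is not None and not isinstance(kw["synthetic"], SyntheticSpec):
            syn = dict(kw["synthetic"])
            extra = set(syn) - {f.name for f in dataclasses.fields(SyntheticSpec)}
            if extra:
                raise ValueError(f"unknown synthetic keys: {sorted(extra)}")
            kw["synthetic"] = SyntheticSpec(**syn)
        if kw.get("svm") is not None and not isinstance(kw["svm"], SvmSpec):
            kw["svm"] = SvmSpec(**kw["svm"])
        for key in ("split", "validation_split"):
            if kw.get(key) is not None and not isinstance(kw[key], SplitScheme):
                kw[key] = SplitScheme(**kw[key])
        for key in ("keep_diagnoses", "methods"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 8 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)

    def manifest(self) -> dict[str, Any]:
        cfg = dataclasses.asdict(self)
        cfg["output_dir"] = str(self.output_dir)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": json.loads(blob),
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "svmpanel_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
        }


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _load_discovery(cfg: PipelineConfig) -> ExpressionDataset:
    if cfg.synthetic is not None:
        ds, truth = generate_cohort(cfg.synthetic, seed=cfg.stage_seed("generator"))
        cfg.output_dir.mkdir(parents=True, exist_ok=True)
        truth.to_json(cfg.output_dir / "ground_truth.json")
        return ds
    assert cfg.inputs is not None
    ds = read_expression(cfg.inputs["matrix"], cfg.inputs["meta"])
    if "probe_map" in cfg.inputs:
        ds = annotate_genes(ds, read_probe_map(cfg.inputs["probe_map"]))
    return ds


def _preprocess(cfg: PipelineConfig, ds: ExpressionDataset) -> ExpressionDataset:
    ds = floor_log_transform(ds)
    if cfg.correction and cfg.correct_before_filter:
        ds, _ = correct_age_gender(ds)
    ds = filter_diagnoses(ds, cfg.keep_diagnoses)
    if cfg.correction and not cfg.correct_before_filter:
        ds, _ = correct_age_gender(ds)
    return ds


def _restrict(cfg: PipelineConfig, ds: ExpressionDataset) -> ExpressionDataset:
    if cfg.inputs is not None and "pool" in cfg.inputs:
        return restrict_to_pool(ds, read_gene_pool(cfg.inputs["pool"]))
    return ds


def prepare_discovery(cfg: PipelineConfig) -> ExpressionDataset:
    """Load (or simulate), preprocess and pool-restrict the discovery cohort."""
    return _restrict(cfg, _preprocess(cfg, _load_discovery(cfg)))


def _write_failed_marker(outdir: Path, stage: str, exc: Exception) -> None:
    (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def run_discovery(cfg: PipelineConfig) -> Path:
    """Execute the discovery pipeline and write all artifacts.

    Stages: load/simulate -> floor+log2 -> diagnosis filter -> covariate
    correction -> pool restriction -> single-feature ranking (top_k table)
    -> SVMFS/SVMTFS traces -> repeated-split metrics for every discovered
    and fixed panel. Returns the run directory.
    """
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(cfg.manifest(), indent=1))
    stage = "load"
    try:
        ds = prepare_discovery(cfg)
        write_expression(ds, outdir / "discovery_matrix.tsv", outdir / "discovery_meta.tsv")

        stage = "ranking"
        ranking = rank_single_features(ds, cfg.svm)
        ranking.head(cfg.top_k).to_csv(outdir / "rank_table.tsv", sep="\t",
                                       index=False, float_format="%.10g")

        stage = "selection"
        panels: dict[str, list[str]] = {}
        for method in cfg.methods:
            fn = svmfs if method == "svmfs" else svmtfs
            trace = fn(ds, cfg.svm, threshold=cfg.threshold, max_size=cfg.max_size)
            trace.save(outdir / f"trace_{method}.tsv", ds, cfg.svm, cfg.seed)
            panels[method] = trace.selected
        for name, features in cfg.fixed_panels.items():
            missing = [f for f in features if f not in ds.feature_ids]
            if missing:
                raise ValueError(f"fixed panel {name!r} features missing: {missing}")
            panels[name] = list(features)

        stage = "evaluation"
        scheme = dataclasses.replace(cfg.split, seed=cfg.stage_seed("discovery_cv"))
        rows = []
        for name, panel in panels.items():
            res = repeated_split_cv(ds, panel, cfg.svm, scheme)
            res.per_repeat.to_csv(outdir / f"per_repeat_{name}.tsv", sep="\t",
                                  index=False, float_format="%.10g")
            rows.append({"panel": name, "features": ",".join(panel),
                         **res.mean_metrics.as_dict()})
        pd.DataFrame(rows).to_csv(outdir / "metrics_table.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        (outdir / "panels.json").write_text(json.dumps(panels, indent=1))
    except Exception as exc:
        _write_failed_marker(outdir, stage, exc)
        raise RuntimeError(f"discovery failed at stage {stage!r}: {exc}") from exc
    return outdir


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _load_validation(cfg: PipelineConfig) -> ExpressionDataset:
    if cfg.synthetic is not None:
        _, val, _ = generate_cohort_pair(cfg.synthetic, seed=cfg.stage_seed("generator"))
        return val
    if not cfg.validation_inputs:
        raise ValueError("no validation cohort configured")
    ds = read_expression(cfg.validation_inputs["matrix"], cfg.validation_inputs["meta"])
    if "probe_map" in cfg.validation_inputs:
        ds = annotate_genes(ds, read_probe_map(cfg.validation_inputs["probe_map"]))
    return ds


def run_validation(cfg: PipelineConfig, panel: Sequence[str],
                   discovery: Optional[ExpressionDataset] = None) -> Path:
    """Validate a panel on the configured validation cohort.

    Runs cross-cohort train/test, within-validation-cohort repeated CV
    (20+20 training samples by default), per-group LOOCV when a group field
    is configured, banded fits and panel correlations in both cohorts.
    """
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(cfg.manifest(), indent=1))
    panel = list(panel)
    stage = "load"
    try:
        if discovery is None:
            discovery = prepare_discovery(cfg)
        val = _preprocess(cfg, _load_validation(cfg))

        stage = "cross_cohort"
        metrics, roc_points = cross_cohort_validate(discovery, val, panel, cfg.svm)
        pd.DataFrame([{"panel": ",".join(panel), **metrics.as_dict()}]).to_csv(
            outdir / "cross_cohort_metrics.tsv", sep="\t", index=False,
            float_format="%.10g")
        roc_points.to_csv(outdir / "cross_cohort_roc.tsv", sep="\t", index=False,
                          float_format="%.10g")

        stage = "validation_cv"
        val_panel = match_panel_features(discovery, val, panel)
        scheme = dataclasses.replace(cfg.validation_split,
                                     seed=cfg.stage_seed("validation_cv"))
        res = repeated_split_cv(val, val_panel, cfg.svm, scheme)
        pd.DataFrame([{"panel": ",".join(val_panel), **res.mean_metrics.as_dict()}]).to_csv(
            outdir / "validation_cv_metrics.tsv", sep="\t", index=False,
            float_format="%.10g")

        stage = "grouped_loocv"
        if cfg.group_field and cfg.group_field in val.sample_meta.columns \
                and val.sample_meta[cfg.group_field].notna().any():
            table = grouped_loocv(val, val_panel, cfg.svm, cfg.group_field)
            table.to_csv(outdir / "grouped_loocv.tsv", sep="\t", index=False,
                         float_format="%.10g")

        stage = "banded"
        rows = []
        for cohort_name, cohort, feats in (("discovery", discovery, panel),
                                           ("validation", val, val_panel)):
            y = cohort.binary_labels(cfg.svm.positive_label)
            for f in feats:
                try:
                    bf = fit_banded(cohort.values[f].to_numpy(), y)
                    rows.append({"cohort": cohort_name, "feature_id": f,
                                 "lower": bf.lower, "upper": bf.upper,
                                 "interval_accuracy": bf.interval_accuracy,
                                 "single_threshold_accuracy":
                                     bf.best_single_threshold_accuracy,
                                 "is_banded": bf.is_banded})
                except ValueError:
                    rows.append({"cohort": cohort_name, "feature_id": f,
                                 "lower": np.nan, "upper": np.nan,
                                 "interval_accuracy": np.nan,
                                 "single_threshold_accuracy": np.nan,
                                 "is_banded": False})
        pd.DataFrame(rows).to_csv(outdir / "banded_fits.tsv", sep="\t", index=False,
                                  float_format="%.10g")

        stage = "correlations"
        if len(panel) >= 2:
            for name, corr in panel_correlations(discovery, panel).items():
                corr.to_csv(outdir / f"correlations_discovery_{name}.tsv", sep="\t",
                            float_format="%.10g")
    except Exception as exc:
        _write_failed_marker(outdir, stage, exc)
        raise RuntimeError(f"validation failed at stage {stage!r}: {exc}") from exc
    return outdir


def summarize_run(run_dir: str | Path) -> str:
    """Human-readable summary of a run directory's tables."""
    run_dir = Path(run_dir)
    lines = [f"run directory: {run_dir}"]
    for name in ("rank_table", "metrics_table", "cross_cohort_metrics",
                 "validation_cv_metrics", "grouped_loocv", "banded_fits"):
        path = run_dir / f"{name}.tsv"
        if path.exists():
            lines.append(f"\n== {name} ==")
            lines.append(pd.read_csv(path, sep="\t").to_string(index=False))
    if (run_dir / "FAILED").exists():
        lines.append("\nRUN FAILED:\n" + (run_dir / "FAILED").read_text())
    return "\n".join(lines)
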