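"""End-to-end orchestration of the cleaning stages.

Fixed stage order (each stage can be toggled off):

    roi_filter -> impute -> batch_correct -> drop QC -> blank_filter
    -> fingerprints -> validate_samples

Every enabled stage can write its output triplet with a stage suffix, a
machine-readable run log records per-stage feature/sample counts, and the
final matrix is emitted in up to three variants: ``imputed`` (as computed),
``zeros`` and ``NA`` (imputed-cell positions re-blanked with the respective
marker, so all variants agree exactly on measured cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch_correction, feature_filters, sample_validation
from .feature_filters import ROIParams
from .imputation import ImputationParams, impute
from .sample_validation import ValidityParams
from .w4m_io import FeatureTable, Role, read_triplet, write_triplet

__all__ = ["PipelineConfig", "PipelineResult", "run", "load_config"]

STAGE_ORDER = ("input", "roi_filter", "impute", "batch_correct", "drop_qc",
               "blank_filter", "fingerprints", "validate_samples")


@dataclass
class PipelineConfig:
    # stage toggles
    do_roi_filter: bool = True
    do_impute: bool = True
    do_batch_correct: bool = True
    do_blank_filter: bool = True
    do_validate: bool = True
    # parameters
    roi: ROIParams = field(default_factory=ROIParams)
    imputation: ImputationParams = field(default_factory=ImputationParams)
    #: components to remove; None -> choose by scree up to scree_k_max
    k: int | None = 6
    scree_k_max: int = 12
    min_blank_detections: int = 1
    fingerprint_min_fraction: float = 0.25
    fingerprint_min_count: int = 8
    validity: ValidityParams = field(default_factory=ValidityParams)
    # I/O
    out_dir: str | None = None
    write_stages: bool = False
    output_variants: tuple[str, ...] = ("imputed", "zeros", "NA")
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.output_variants) - {"imputed", "zeros", "NA"}
        if bad:
            raise ValueError(f"unknown output variants: {sorted(bad)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a config from a YAML file; nested blocks map to param objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "roi" in kwargs:
        kwargs["roi"] = ROIParams(**kwargs["roi"])
    if "imputation" in kwargs:
        kwargs["imputation"] = ImputationParams(**kwargs["imputation"])
    if "validity" in kwargs:
        kwargs["validity"] = ValidityParams(**kwargs["validity"])
    if "output_variants" in kwargs:
        kwargs["output_variants"] = tuple(kwargs["output_variants"])
    return PipelineConfig(**kwargs)


@dataclass
class PipelineResult:
    stages: dict[str, FeatureTable]
    final: FeatureTable
    variants: dict[str, FeatureTable]
    log: pd.DataFrame
    fingerprints: dict | None = None
    validity_report: object | None = None
    removed_features: list[str] = field(default_factory=list)
    chosen_k: int | None = None
    scree_curve: pd.DataFrame | None = None


def _counts(table: FeatureTable) -> dict:
    roles = table.sample_meta["role"].value_counts()
    return {
        "n_features": table.n_features,
        "n_samples": table.n_samples,
        "n_study": int(roles.get(Role.STUDY.value, 0)),
        "n_qc": int(roles.get(Role.QC_POOL.value, 0)),
        "n_blank": int(roles.get(Role.BLANK.value, 0)),
    }


def _variant(table: FeatureTable, kind: str) -> FeatureTable:
    """Re-blank imputed-cell positions with the requested marker."""
    if kind == "imputed" or table.imputed_mask is None:
        return table.copy()
    matrix = table.matrix.copy()
    mask = table.imputed_mask.to_numpy()
    values = matrix.to_numpy(dtype=float).copy()
    values[mask] = np.nan if kind == "NA" else 0.0
    matrix = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    return FeatureTable(matrix=matrix, sample_meta=table.sample_meta.copy(),
                        feature_meta=table.feature_meta.copy(),
                        missing_convention="NA" if kind == "NA" else "zero")


def run(config: PipelineConfig, table: FeatureTable | None = None,
        triplet_paths: tuple[str, str, str] | None = None) -> PipelineResult:
    """Execute the enabled stages in fixed order.

    Provide the input either in memory (``table``) or as triplet paths.
    Raises from any stage propagate tagged with the stage name; the run log
    accumulated so far is flushed to ``out_dir`` first when one is set.
    """
    if table is None:
        if triplet_paths is None:
            raise ValueError("provide a table or triplet paths")
        table = read_triplet(*triplet_paths)
    out_dir = Path(config.out_dir) if config.out_dir else None
    log_rows: list[dict] = []
    stages: dict[str, FeatureTable] = {}
    result = PipelineResult(stages=stages, final=table, variants={},
                            log=pd.DataFrame())

    def record(stage: str, t: FeatureTable, **extra) -> None:
        log_rows.append({"stage": stage, **_counts(t), **extra})
        stages[stage] = t
        if out_dir and config.write_stages:
            write_triplet(t, out_dir, prefix=f"{stage}_")

    def flush_log() -> pd.DataFrame:
        log = pd.DataFrame(log_rows)
        if out_dir:
            out_dir.mkdir(parents=True, exist_ok=True)
            log.to_csv(out_dir / "run_log.tsv", sep="\t", index=False)
        return log

    record("input", table)
    current = table
    detection_source = current  # pre-imputation detection information
    try:
        if config.do_roi_filter:
            current = feature_filters.roi_filter(current, config.roi)
            detection_source = current
            record("roi_filter", current)
        if config.do_impute:
            current = impute(current, config.imputation)
            record("impute", current)
        if config.do_batch_correct:
            if config.k is None:
                k, curve = batch_correction.scree_select_k(
                    current, config.scree_k_max)
                result.chosen_k = k
                result.scree_curve = curve
                if out_dir:
                    out_dir.mkdir(parents=True, exist_ok=True)
                    curve.to_csv(out_dir / "scree_curve.tsv", sep="\t",
                                 index=False)
            else:
                k = config.k
                result.chosen_k = k
            model = batch_correction.fit(current, k)
            current = batch_correction.transform(current, model)
            record("batch_correct", current, k=k)
            # the QC pool has served its purpose
            keep = current.sample_meta.index[
                current.sample_meta["role"] != Role.QC_POOL.value]
            current = current.subset(samples=keep)
            detection_source = detection_source.subset(
                samples=[s for s in detection_source.matrix.columns
                         if s in set(keep)])
            record("drop_qc", current)
        if config.do_blank_filter:
            current, removed = feature_filters.blank_filter(
                current, config.min_blank_detections)
            result.removed_features = removed
            detection_source = detection_source.subset(
                features=current.matrix.index,
                samples=[s for s in detection_source.matrix.columns
                         if s in set(current.matrix.columns)])
            record("blank_filter", current, features_removed=len(removed))
        if config.do_validate:
            fingerprints = feature_filters.build_fingerprints(
                detection_source,
                min_fraction=config.fingerprint_min_fraction,
                min_count=config.fingerprint_min_count)
            result.fingerprints = fingerprints
            record("fingerprints", current,
                   n_fingerprints=len(fingerprints))
            report, current = sample_validation.validate_samples(
                current, fingerprints, config.validity,
                detection_table=detection_source)
            result.validity_report = report
            record("validate_samples", current,
                   samples_failed=len(report.failures()))
            if out_dir:
                out_dir.mkdir(parents=True, exist_ok=True)
                report.table.to_csv(out_dir / "validity_report.tsv",
                                    sep="\t")
    except Exception as exc:  # tag the failing stage, flush partial log
        stage = log_rows[-1]["stage"] if log_rows else "input"
        result.log = flush_log()
        raise RuntimeError(
            f"pipeline aborted after stage {stage!r}: {exc}") from exc

    result.final = current
    for kind in config.output_variants:
        variant = _variant(current, kind)
        result.variants[kind] = variant
        if out_dir:
            write_triplet(variant, out_dir, prefix=f"final_{kind}_")
    result.log = flush_log()
    return result
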