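"""Synthetic LC-MS feature tables with the structure the cleaning stages assume.

The generator emulates the statistical shape of the study's exported feature
table rather than raw spectra: every species owns a fingerprint of features
drawn from a log-normal intensity baseline, features outside a sample's
fingerprint are absent, detection within the fingerprint is thinned by a
dropout probability, intensities below the instrument noise floor are
censored to missing, batches multiply intensities by a feature-wise
log-normal factor, pooled-QC injections carry the average of all study
extracts, and blanks contain only procedural contaminants.  A
:class:`GroundTruth` sidecar records what was planted so downstream stages
can be scored exactly.

Default parameters are calibrated to the study conditions: ~90% empty cells
overall, pooled QCs detecting roughly a third of all features (pool dilution
pushes species-specific features below the noise floor), and a pre-correction
QC inter-batch distance ratio of order ten.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design_model import (StudyDesign, build_injection_sequence,
                           enumerate_study_samples)
from .w4m_io import FeatureTable, Role, SampleRecord, records_to_frame

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "realized_zero_fraction",
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults reproduce the study conditions.

    Intensity baselines are parameterised on the log10 scale (the usual way
    LC-MS intensities are summarised); batch effects are feature-wise factors
    ``exp(effect)`` with ``effect ~ N(0, batch_effect_sd)`` on the natural-log
    scale, constant within a batch.
    """

    n_features_per_species: int = 70
    n_shared_features: int = 25
    n_contaminant_features: int = 20
    #: mean / sd of the per-feature log10 baseline intensity
    baseline_log_mean: float = 2.7
    baseline_log_sd: float = 0.8
    #: baselines are truncated below at this log10 intensity (2x the noise
    #: floor) so that a planted fingerprint feature is actually detectable
    baseline_log_min: float = math.log10(200.0)
    #: per-cell biological/technical spread around the baseline (log10)
    residual_log_sd: float = 0.15
    #: per-cell injection noise of the pooled QC (log10)
    qc_log_sd: float = 0.02
    #: sd of the per-batch, per-feature multiplicative effect (natural log)
    batch_effect_sd: float = 0.4
    #: if set, batch-effect vectors live in a subspace of this rank
    batch_effect_rank: int | None = None
    #: probability that a fingerprint feature goes undetected in a sample
    detection_dropout: float = 0.35
    #: intensities below this are censored to missing (instrument noise floor)
    detection_threshold: float = 100.0
    target_zero_fraction: float = 0.90
    n_outlier_samples: int = 0
    #: fraction of an outlier's detected features swapped for foreign ones
    outlier_swap_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detection_dropout", "target_zero_fraction",
                     "outlier_swap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_features_per_species", "n_shared_features",
                     "n_contaminant_features", "n_outlier_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_effect_sd < 0:
            raise ValueError("batch_effect_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring the cleaning stages."""

    #: species -> set of fingerprint feature ids (exclusive + shared)
    fingerprints: dict[str, set[str]]
    #: feature ids planted as procedural contaminants
    contaminant_features: set[str]
    #: sample ids whose profiles were corrupted
    outlier_samples: set[str]
    #: batches x features, natural-log scale effects
    batch_effects: pd.DataFrame
    #: rank of the planted batch-effect subspace
    batch_effect_rank: int = 0

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Tabular form for TSV sidecar export."""
        rows = [(sp, f) for sp, feats in self.fingerprints.items()
                for f in sorted(feats)]
        membership = pd.DataFrame(rows, columns=["species_code", "feature_id"])
        flags = pd.DataFrame({
            "feature_id": sorted(self.contaminant_features),
            "contaminant": True,
        })
        outliers = pd.DataFrame({"sample_id": sorted(self.outlier_samples)})
        return {"membership": membership, "contaminants": flags,
                "outliers": outliers, "batch_effects": self.batch_effects}

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            frame.to_csv(out / f"groundtruth_{name}.tsv", sep="\t",
                         index=(name == "batch_effects"))


def _batch_effects(rng: np.random.Generator, n_batches: int, n_features: int,
                   sd: float, rank: int | None) -> np.ndarray:
    if sd == 0.0:
        return np.zeros((n_batches, n_features))
    if rank is None or rank >= min(n_batches, n_features):
        return rng.normal(0.0, sd, size=(n_batches, n_features))
    loadings = rng.normal(0.0, sd, size=(n_batches, rank))
    basis = rng.normal(size=(rank, n_features))
    # unit-norm columns keep the per-feature marginal sd at `sd`
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return loadings @ basis


def simulate(design: StudyDesign, cfg: SimulationConfig,
             records: list[SampleRecord] | None = None,
             ) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table (NA missing convention) plus its ground truth.

    ``records`` defaults to the full factorial enumeration of ``design``;
    pass the output of :func:`~metaboclean.design_model.apply_known_losses`
    to emulate the 511 measured samples.  All randomness flows from
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if records is None:
        records = enumerate_study_samples(design)
    records = [replace_record(r) for r in records]
    species = design.species_codes()

    # --- feature space ---------------------------------------------------
    feature_ids: list[str] = []
    owner: dict[str, list[str]] = {}
    for sp in species:
        ids = [f"F{len(feature_ids) + i + 1:04d}"
               for i in range(cfg.n_features_per_species)]
        feature_ids += ids
        owner[sp] = ids
    shared = [f"F{len(feature_ids) + i + 1:04d}"
              for i in range(cfg.n_shared_features)]
    feature_ids += shared
    contaminants = [f"F{len(feature_ids) + i + 1:04d}"
                    for i in range(cfg.n_contaminant_features)]
    feature_ids += contaminants
    n_feat = len(feature_ids)
    feat_pos = {f: i for i, f in enumerate(feature_ids)}

    fingerprints = {sp: set(owner[sp]) | set(shared) for sp in species}
    contaminant_set = set(contaminants)

    # per-(species, feature) log10 baselines, truncated below
    def draw_baseline(size):
        mu = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=size)
        # redraw below-floor baselines (truncation, not clipping)
        low = mu < cfg.baseline_log_min
        while low.any():
            mu[low] = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                 size=int(low.sum()))
            low = mu < cfg.baseline_log_min
        return mu

    baseline = {}  # species -> vector over its fingerprint features
    fp_index = {}
    for sp in species:
        feats = sorted(fingerprints[sp], key=feat_pos.__getitem__)
        fp_index[sp] = np.array([feat_pos[f] for f in feats])
        baseline[sp] = draw_baseline(len(feats))
    contam_baseline = draw_baseline(len(contaminants))
    contam_index = np.array([feat_pos[f] for f in contaminants], dtype=int)

    # --- injection layout --------------------------------------------------
    seq_seed = int(rng.integers(0, 2**31 - 1))
    sequence = build_injection_sequence(records, design, seed=seq_seed)

    # --- study sample base profiles (pre batch effect) ---------------------
    study = sequence.study_samples()
    n_study = len(study)
    base = np.full((n_feat, n_study), np.nan)
    for j, rec in enumerate(study):
        sp = rec.species_code
        idx = fp_index[sp]
        keep = rng.random(idx.size) >= cfg.detection_dropout
        logs = baseline[sp][keep] + rng.normal(0, cfg.residual_log_sd,
                                               size=int(keep.sum()))
        base[idx[keep], j] = 10.0 ** logs
        ckeep = rng.random(contam_index.size) >= cfg.detection_dropout
        clogs = contam_baseline[ckeep] + rng.normal(0, cfg.residual_log_sd,
                                                    size=int(ckeep.sum()))
        base[contam_index[ckeep], j] = 10.0 ** clogs

    # --- outliers: swap a fraction of detected features for foreign ones ---
    outlier_ids: set[str] = set()
    if cfg.n_outlier_samples:
        chosen = rng.choice(n_study, size=min(cfg.n_outlier_samples, n_study),
                            replace=False)
        for j in chosen:
            rec = study[j]
            outlier_ids.add(rec.sample_id)
            own = fp_index[rec.species_code]
            detected = own[~np.isnan(base[own, j])]
            n_swap = int(round(cfg.outlier_swap_fraction * detected.size))
            if n_swap == 0:
                continue
            drop = rng.choice(detected, size=n_swap, replace=False)
            base[drop, j] = np.nan
            donors = [sp for sp in species
                      if sp != rec.species_code
                      and sp not in design.species_pools(rec.species_code)]
            donor = donors[int(rng.integers(len(donors)))] if donors else None
            if donor is None:
                continue
            foreign = np.setdiff1d(fp_index[donor], fp_index[rec.species_code])
            pick = rng.choice(foreign, size=min(n_swap, foreign.size),
                              replace=False)
            order = {p: i for i, p in enumerate(fp_index[donor])}
            logs = np.array([baseline[donor][order[p]] for p in pick])
            base[pick, j] = 10.0 ** (logs + rng.normal(
                0, cfg.residual_log_sd, size=pick.size))

    # --- pooled QC: mean of all study extracts (absence pools as zero) -----
    qc_base = np.nanmean(np.where(np.isnan(base), 0.0, base), axis=1)

    # --- batch effects ------------------------------------------------------
    effects = _batch_effects(rng, design.n_batches, n_feat,
                             cfg.batch_effect_sd, cfg.batch_effect_rank)
    batch_ids = [b.batch_id for b in sequence.batches]
    batch_pos = {b: i for i, b in enumerate(batch_ids)}

    # --- assemble columns in injection order --------------------------------
    study_pos = {rec.sample_id: j for j, rec in enumerate(study)}
    columns: dict[str, np.ndarray] = {}
    meta_records: list[SampleRecord] = []
    for batch in sequence.batches:
        mult = np.exp(effects[batch_pos[batch.batch_id]])
        for rec in batch.entries:
            if rec.role is Role.SOLVENT:
                continue  # run-in injections are not exported to the matrix
            if rec.role is Role.STUDY:
                col = base[:, study_pos[rec.sample_id]] * mult
                col[col < cfg.detection_threshold] = np.nan
            elif rec.role is Role.QC_POOL:
                noise = 10.0 ** rng.normal(0, cfg.qc_log_sd, size=n_feat)
                col = qc_base * noise * mult
                col[col < cfg.detection_threshold] = np.nan
            else:  # blank: contaminants only, always detected
                col = np.full(n_feat, np.nan)
                clogs = contam_baseline + rng.normal(
                    0, cfg.residual_log_sd, size=contam_index.size)
                col[contam_index] = 10.0 ** clogs * mult[contam_index]
            columns[rec.sample_id] = col
            meta_records.append(rec)

    matrix = pd.DataFrame(
        {sid: columns[sid] for sid in (r.sample_id for r in meta_records)},
        index=pd.Index(feature_ids, name="feature_id"))
    sample_meta = records_to_frame(meta_records)
    feature_meta = pd.DataFrame({
        "mz": np.round(rng.uniform(100.0, 1000.0, size=n_feat), 4),
        "rt": np.round(rng.uniform(85.0, 835.0, size=n_feat), 1),
    }, index=matrix.index)

    table = FeatureTable(matrix=matrix, sample_meta=sample_meta,
                         feature_meta=feature_meta, missing_convention="NA")
    truth = GroundTruth(
        fingerprints=fingerprints,
        contaminant_features=contaminant_set,
        outlier_samples=outlier_ids,
        batch_effects=pd.DataFrame(effects, index=batch_ids,
                                   columns=feature_ids),
        batch_effect_rank=(cfg.batch_effect_rank
                           if cfg.batch_effect_rank is not None
                           else min(design.n_batches, n_feat)),
    )
    return table, truth


def replace_record(rec: SampleRecord) -> SampleRecord:
    """Shallow copy so the generator never mutates caller-owned records."""
    import copy

    return copy.copy(rec)


def realized_zero_fraction(table: FeatureTable) -> float:
    """Fraction of empty (missing) cells in the matrix.

    Defined for the ``zero`` and ``NA`` conventions only; once a table is
    imputed the notion of an empty cell no longer applies.
    """
    if table.missing_convention == "imputed":
        raise ValueError("zero fraction is undefined for an imputed table")
    values = table.matrix.to_numpy(dtype=float)
    if values.size == 0:
        return 0.0
    if table.missing_convention == "NA":
        return float(np.isnan(values).mean())
    return float((values == 0).mean())
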