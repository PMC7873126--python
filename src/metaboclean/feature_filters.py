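"""Feature-level cleaning: retention-time cut, blank removal, fingerprints.

Three feature-level rules operate on the table:

* **ROI filter** — features eluting in the injection front (before 80 s) or
  the column wash (after 840 s) carry no usable chromatography and are cut.
* **Blank filter** — blanks contain no biology, so anything detected in a
  blank is a procedural contaminant and is removed everywhere; the blank
  columns themselves are then dropped.
* **Species fingerprints** — a feature belongs to a species when it is
  detected in at least 25% of that species' samples (with an absolute floor
  of 8 samples); the fingerprints anchor the sample validity check.

Detection is always judged on pre-imputation information: the zero/NA matrix
directly, or the imputation mask carried by an imputed table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .w4m_io import FeatureTable, Role

__all__ = [
    "ROIParams",
    "SpeciesFingerprint",
    "roi_filter",
    "blank_filter",
    "build_fingerprints",
]


@dataclass
class ROIParams:
    """Retention-time region of interest, in seconds, inclusive bounds."""

    rt_min: float = 80.0
    rt_max: float = 840.0

    def __post_init__(self) -> None:
        if not 0 <= self.rt_min < self.rt_max:
            raise ValueError("require 0 <= rt_min < rt_max")


@dataclass
class SpeciesFingerprint:
    """Features reproducibly detected within one species."""

    species_code: str
    #: detection fraction per member feature
    detection_fraction: pd.Series
    min_detection_fraction: float
    min_detection_count: int
    n_samples: int

    @property
    def features(self) -> pd.Index:
        return self.detection_fraction.index

    def __len__(self) -> int:
        return len(self.detection_fraction)


def roi_filter(table: FeatureTable, params: ROIParams) -> FeatureTable:
    """Keep features with rt in ``[rt_min, rt_max]`` (both bounds kept)."""
    if "rt" not in table.feature_meta.columns:
        raise ValueError("feature metadata carries no rt column")
    rt = table.feature_meta["rt"]
    if rt.isna().any():
        raise ValueError("some features have missing rt")
    keep = table.feature_meta.index[(rt >= params.rt_min)
                                    & (rt <= params.rt_max)]
    return table.subset(features=keep)


def blank_filter(table: FeatureTable, min_blank_detections: int = 1
                 ) -> tuple[FeatureTable, list[str]]:
    """Remove blank-derived features, then drop the blank samples.

    A feature is removed when it is detected in at least
    ``min_blank_detections`` blanks (default 1 — "detected in at least one
    blank"; set 3 for a 25%-of-12-blanks rule).  Returns the filtered table
    and the removed feature ids.
    """
    blank_ids = table.sample_ids(Role.BLANK)
    if len(blank_ids) == 0:
        raise ValueError("table contains no blank samples")
    detected = table.detected()  # raises for imputed tables without a mask
    counts = detected[blank_ids].sum(axis=1)
    removed = list(table.matrix.index[counts >= min_blank_detections])
    keep_features = table.matrix.index.difference(removed, sort=False)
    keep_samples = table.matrix.columns.difference(blank_ids, sort=False)
    return table.subset(features=keep_features, samples=keep_samples), removed


def build_fingerprints(table: FeatureTable,
                       min_fraction: float = 0.25,
                       min_count: int = 8,
                       ) -> dict[str, SpeciesFingerprint]:
    """Per-species feature fingerprints from pre-imputation detections.

    A feature joins the fingerprint of species *s* when it is detected in at
    least ``max(min_count, ceil(min_fraction * n_s))`` of the *n_s* study
    samples of that species.
    """
    detected = table.detected()
    study = table.sample_meta[table.sample_meta["role"] == Role.STUDY.value]
    fingerprints: dict[str, SpeciesFingerprint] = {}
    for species, group in study.groupby("species_code", sort=True):
        n = len(group)
        if n == 0:
            raise ValueError(f"species {species} has zero samples")
        threshold = max(min_count, math.ceil(min_fraction * n))
        counts = detected[group.index].sum(axis=1)
        members = counts[counts >= threshold]
        fingerprints[str(species)] = SpeciesFingerprint(
            species_code=str(species),
            detection_fraction=(members / n).astype(float),
            min_detection_fraction=min_fraction,
            min_detection_count=threshold,
            n_samples=n,
        )
    return fingerprints
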