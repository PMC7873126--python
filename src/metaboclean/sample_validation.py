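"""Per-species sample validity: Mahalanobis distances and shared features.

Within a species the metabolic profiles are far more alike than between
species, so a contaminated or mislabelled sample shows up in two ways: its
covariance-scaled distance from the species centroid is large relative to
its peers, and it detects too few of the features that define the species.
A sample is kept only when it is no further than ``distance_multiplier``
(default 3) times the average distance of the *other* samples of its species
AND it shares strictly more than ``min_shared_fraction`` (default 25%) of the
species fingerprint.

The species covariance is singular whenever features outnumber samples, so
by default profiles are projected onto the leading principal components
(``n_components = min(n - 2, 10)``) and the Mahalanobis distance is taken in
that score space; pseudo-inverse and Ledoit-Wolf shrinkage covariances are
available as alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_filters import SpeciesFingerprint
from .w4m_io import FeatureTable, Role

__all__ = [
    "ValidityParams",
    "ValidityReport",
    "mahalanobis_per_species",
    "shared_fraction",
    "validate_samples",
]

_EIG_TOL = 1e-10


@dataclass
class ValidityParams:
    distance_multiplier: float = 3.0
    min_shared_fraction: float = 0.25
    covariance_regularization: str = "pca_projection"
    #: None = min(n_species_samples - 2, 10)
    n_components: int | None = None
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.distance_multiplier <= 0:
            raise ValueError("distance_multiplier must be > 0")
        if not 0.0 <= self.min_shared_fraction <= 1.0:
            raise ValueError("min_shared_fraction must be in [0, 1]")
        if self.covariance_regularization not in {
                "pca_projection", "pseudo_inverse", "shrinkage"}:
            raise ValueError(
                f"unknown regularization {self.covariance_regularization!r}")


@dataclass
class ValidityReport:
    """Per-sample distances, shared fractions and pass/fail decisions."""

    table: pd.DataFrame  # sample_id-indexed: species, distance, peer_avg, ...

    def failures(self) -> pd.DataFrame:
        return self.table[self.table["decision"] != "pass"]

    def passing_ids(self) -> pd.Index:
        return self.table.index[self.table["decision"] == "pass"]


def mahalanobis_per_species(table: FeatureTable, species_code: str,
                            params: ValidityParams) -> pd.Series:
    """Distance of each sample of one species to the species centroid.

    Expects a dense (imputed, batch-corrected) matrix.  The centroid and
    covariance are estimated from all samples of the species; with
    ``pca_projection`` the covariance is the (diagonal) score covariance in
    an ``n_components``-dimensional principal subspace.
    """
    meta = table.sample_meta
    ids = meta.index[(meta["role"] == Role.STUDY.value)
                     & (meta["species_code"] == species_code)]
    n = len(ids)
    if n < 4:
        raise ValueError(f"species {species_code}: need >= 4 samples, got {n}")
    X = table.matrix[ids].to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ValueError("matrix contains missing cells; impute first")
    if params.log_transform:
        if X.min() <= 0:
            raise ValueError("log transform requires positive intensities")
        X = np.log(X)
    Xc = X - X.mean(axis=0)
    reg = params.covariance_regularization
    if reg == "pca_projection":
        m = params.n_components or min(n - 2, 10)
        m = min(m, n - 1, X.shape[1])
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ vt[:m].T
        var = (s[:m] ** 2) / (n - 1)
        keep = var > _EIG_TOL * max(var.max(initial=0.0), 1.0)
        if not keep.any():
            d2 = np.zeros(n)
        else:
            d2 = ((scores[:, keep] ** 2) / var[keep]).sum(axis=1)
    elif reg == "pseudo_inverse":
        cov = np.cov(Xc, rowvar=False)
        inv = np.linalg.pinv(cov, hermitian=True)
        d2 = np.einsum("ij,jk,ik->i", Xc, inv, Xc)
    else:  # shrinkage
        from sklearn.covariance import LedoitWolf

        lw = LedoitWolf().fit(Xc)
        inv = np.linalg.pinv(lw.covariance_, hermitian=True)
        d2 = np.einsum("ij,jk,ik->i", Xc, inv, Xc)
    return pd.Series(np.sqrt(np.maximum(d2, 0.0)), index=ids,
                     name="mahalanobis_distance")


def shared_fraction(detected_features, fingerprint: SpeciesFingerprint
                    ) -> float:
    """``|detected ∩ fingerprint| / |fingerprint|`` for one sample."""
    if len(fingerprint) == 0:
        raise ValueError(
            f"species {fingerprint.species_code}: empty fingerprint")
    detected = set(detected_features)
    members = set(fingerprint.features)
    return len(detected & members) / len(members)


def validate_samples(table: FeatureTable,
                     fingerprints: dict[str, SpeciesFingerprint],
                     params: ValidityParams | None = None,
                     detection_table: FeatureTable | None = None,
                     ) -> tuple[ValidityReport, FeatureTable]:
    """Flag invalid study samples and return the filtered table.

    ``table`` supplies the profiles for the distance check (batch-corrected,
    imputed); detection sets for the shared-feature check come from
    ``table``'s own imputation mask or, if given, from ``detection_table``
    (the pre-imputation matrix).  A sample passes when its distance is at
    most ``distance_multiplier`` times the mean distance of the remaining
    samples of its species (leave-one-out peer average) and its shared
    fraction strictly exceeds ``min_shared_fraction``.
    """
    params = params or ValidityParams()
    det_source = detection_table if detection_table is not None else table
    detected = det_source.detected()
    meta = table.sample_meta
    study = meta[meta["role"] == Role.STUDY.value]
    rows = []
    for species, group in study.groupby("species_code", sort=True):
        species = str(species)
        if species not in fingerprints:
            raise KeyError(f"species {species} absent from fingerprints")
        fp = fingerprints[species]
        dist = mahalanobis_per_species(table, species, params)
        total = float(dist.sum())
        n = len(dist)
        for sid in dist.index:
            d = float(dist[sid])
            peer_avg = (total - d) / (n - 1)
            sf = shared_fraction(
                detected.index[detected[sid].to_numpy()], fp)
            fail_d = d > params.distance_multiplier * peer_avg
            fail_s = not sf > params.min_shared_fraction
            decision = ("pass" if not (fail_d or fail_s)
                        else "fail_both" if (fail_d and fail_s)
                        else "fail_distance" if fail_d
                        else "fail_shared")
            rows.append({
                "sample_id": sid, "species_code": species,
                "mahalanobis_distance": d,
                "peer_average_distance": peer_avg,
                "shared_fraction": sf, "decision": decision,
            })
    report = ValidityReport(
        table=pd.DataFrame(rows).set_index("sample_id"))
    failing = set(report.failures().index)
    keep = table.matrix.columns[~table.matrix.columns.isin(failing)]
    return report, table.subset(samples=keep)
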