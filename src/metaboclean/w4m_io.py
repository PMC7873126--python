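"""Reading and writing the W4M three-table exchange format.

Workflow4Metabolomics (W4M) exports an untargeted LC-MS experiment as three
tab-separated tables that share identifiers:

* ``dataMatrix``      -- feature intensities, features in rows, samples in columns;
* ``sampleMetadata``  -- one row per injected sample (role, batch, design factors);
* ``variableMetadata``-- one row per feature (m/z, retention time, annotation).

The triplet is held in memory as a :class:`FeatureTable`, the object every
cleaning stage consumes and produces.  Missing intensities can be encoded in
three conventions: ``"NA"`` (literal NA tokens), ``"zero"`` (zeros mean
not-detected) and ``"imputed"`` (every cell holds a number; an imputation mask
records which cells were filled in).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "SampleRecord",
    "FeatureRecord",
    "FeatureTable",
    "TripletFormatError",
    "read_triplet",
    "write_triplet",
    "parse_lab_id",
    "records_to_frame",
    "frame_to_records",
]

SEASONS = ("A", "B", "C", "D")
LAB_ID_RE = re.compile(r"^(\d{3})_(\d{4})_([A-Z])$")

#: canonical sampleMetadata column order on write
SAMPLE_COLUMNS = [
    "role",
    "lab_id",
    "species_code",
    "pool",
    "diversity_level",
    "season",
    "replicate",
    "plot_id",
    "batch_id",
    "injection_index",
]

#: common aliases found in deposited sampleMetadata files, mapped to our schema
DEFAULT_SAMPLE_ALIASES = {
    "class": "role",
    "sampleType": "role",
    "sample_type": "role",
    "batch": "batch_id",
    "analytical_batch": "batch_id",
    "injectionOrder": "injection_index",
    "injection_order": "injection_index",
}

DEFAULT_FEATURE_ALIASES = {"mzmed": "mz", "rtmed": "rt"}


class TripletFormatError(ValueError):
    """Raised when a triplet violates the W4M format contract."""


class Role(str, enum.Enum):
    """What was injected: a study sample, a pooled QC, a blank or pure solvent."""

    STUDY = "study"
    QC_POOL = "qc_pool"
    BLANK = "blank"
    SOLVENT = "solvent"


@dataclass
class SampleRecord:
    """One injected sample and its position in the design and the run sequence."""

    sample_id: str
    role: Role
    lab_id: str | None = None
    species_code: str | None = None
    pool: str | None = None
    diversity_level: int | None = None
    season: str | None = None
    replicate: str | None = None
    plot_id: str | None = None
    batch_id: str | None = None
    injection_index: int | None = None

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        design = (self.species_code, self.pool, self.diversity_level,
                  self.season, self.replicate)
        if self.role is Role.STUDY:
            if any(v is None for v in design):
                raise ValueError(
                    f"study sample {self.sample_id!r} must carry species, pool, "
                    "diversity level, season and replicate"
                )
            if self.lab_id is not None:
                parse_lab_id(self.lab_id)
        else:
            if any(v is not None for v in design):
                raise ValueError(
                    f"{self.role.value} sample {self.sample_id!r} must not carry "
                    "design fields"
                )


@dataclass
class FeatureRecord:
    """A detected (m/z, retention time) pair."""

    feature_id: str
    mz: float
    rt: float
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id!r}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id!r}: rt must be >= 0")


def parse_lab_id(lab_id: str) -> dict:
    """Split a Lab-ID of the form ``NNN_YYYY_S`` into number, year and season.

    Numbers run 001-128 within each season; seasons are A (May), B (July),
    C (August) and D (October).
    """
    m = LAB_ID_RE.match(lab_id)
    if m is None:
        raise ValueError(f"malformed Lab-ID {lab_id!r}; expected NNN_YYYY_S")
    number, year, season = int(m.group(1)), int(m.group(2)), m.group(3)
    if not 1 <= number <= 128:
        raise ValueError(f"Lab-ID {lab_id!r}: number must be in 001..128")
    if season not in SEASONS:
        raise ValueError(f"Lab-ID {lab_id!r}: season must be one of {SEASONS}")
    return {"number": number, "year": year, "season": season}


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tabulate SampleRecords as a sampleMetadata frame indexed by sample_id."""
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "role": r.role.value,
            "lab_id": r.lab_id,
            "species_code": r.species_code,
            "pool": r.pool,
            "diversity_level": r.diversity_level,
            "season": r.season,
            "replicate": r.replicate,
            "plot_id": r.plot_id,
            "batch_id": r.batch_id,
            "injection_index": r.injection_index,
        })
    frame = pd.DataFrame(rows).set_index("sample_id")
    return frame[SAMPLE_COLUMNS]


def frame_to_records(sample_meta: pd.DataFrame) -> list[SampleRecord]:
    """Inverse of :func:`records_to_frame` (values only; NA becomes None)."""
    records = []
    for sid, row in sample_meta.iterrows():
        kw = {}
        for col in SAMPLE_COLUMNS:
            v = row.get(col)
            kw[col] = None if pd.isna(v) else v
        if kw["diversity_level"] is not None:
            kw["diversity_level"] = int(kw["diversity_level"])
        if kw["injection_index"] is not None:
            kw["injection_index"] = int(kw["injection_index"])
        records.append(SampleRecord(sample_id=str(sid), **kw))
    return records


@dataclass
class FeatureTable:
    """A W4M triplet in memory.

    Parameters
    ----------
    matrix
        Intensities, features in rows and samples in columns.  Non-missing
        values are finite and >= 0.
    sample_meta
        One row per sample, indexed by sample id, aligned with the matrix
        columns.
    feature_meta
        One row per feature, indexed by feature id, aligned with the matrix
        rows.  Must carry ``mz`` and ``rt`` columns.
    missing_convention
        ``"NA"`` (NaN cells are missing), ``"zero"`` (zeros are missing) or
        ``"imputed"`` (no missing cells; see ``imputed_mask``).
    imputed_mask
        Boolean frame aligned with ``matrix`` marking cells that were filled
        by imputation; required when the convention is ``"imputed"`` and the
        table is later used for detection-based steps.
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame
    missing_convention: str = "NA"
    imputed_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if self.missing_convention not in {"NA", "zero", "imputed"}:
            raise TripletFormatError(
                f"unknown missing convention {self.missing_convention!r}"
            )
        cols, rows = self.matrix.columns, self.matrix.index
        if cols.has_duplicates or rows.has_duplicates:
            raise TripletFormatError("duplicate sample or feature identifiers")
        if set(cols) != set(self.sample_meta.index):
            extra = set(cols) - set(self.sample_meta.index)
            missing = set(self.sample_meta.index) - set(cols)
            raise TripletFormatError(
                f"unmatched sample identifiers (matrix-only: {sorted(extra)[:5]}, "
                f"metadata-only: {sorted(missing)[:5]})"
            )
        if set(rows) != set(self.feature_meta.index):
            raise TripletFormatError("unmatched feature identifiers")
        # align metadata to matrix order
        self.sample_meta = self.sample_meta.loc[cols]
        self.feature_meta = self.feature_meta.loc[rows]
        values = self.matrix.to_numpy(dtype=float)
        if np.nanmin(values, initial=0.0) < 0:
            raise TripletFormatError("negative intensities are not allowed")
        has_na = bool(np.isnan(values).any())
        if has_na and self.missing_convention != "NA":
            raise TripletFormatError(
                f"NA cells present but convention is {self.missing_convention!r}"
            )
        if self.imputed_mask is not None:
            if (not self.imputed_mask.index.equals(rows)
                    or not self.imputed_mask.columns.equals(cols)):
                raise TripletFormatError("imputed mask not aligned with matrix")

    # -- convenience ------------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def sample_ids(self, role: Role | str | None = None) -> pd.Index:
        if role is None:
            return self.matrix.columns
        role = Role(role).value
        return self.sample_meta.index[self.sample_meta["role"] == role]

    def role_counts(self) -> pd.Series:
        return self.sample_meta["role"].value_counts()

    def detected(self) -> pd.DataFrame:
        """Boolean frame: True where a feature was measured (not missing).

        For an imputed table the stored mask is consulted; an imputed table
        without a mask no longer knows what was measured and raises.
        """
        if self.missing_convention == "NA":
            return self.matrix.notna()
        if self.missing_convention == "zero":
            return self.matrix > 0
        if self.imputed_mask is None:
            raise TripletFormatError(
                "imputed table without an imputation mask: detection unknown"
            )
        return ~self.imputed_mask

    def subset(self, features: pd.Index | None = None,
               samples: pd.Index | None = None) -> "FeatureTable":
        """Return a new table restricted to the given features/samples."""
        features = self.matrix.index if features is None else pd.Index(features)
        samples = self.matrix.columns if samples is None else pd.Index(samples)
        mask = None
        if self.imputed_mask is not None:
            mask = self.imputed_mask.loc[features, samples]
        return FeatureTable(
            matrix=self.matrix.loc[features, samples],
            sample_meta=self.sample_meta.loc[samples],
            feature_meta=self.feature_meta.loc[features],
            missing_convention=self.missing_convention,
            imputed_mask=mask,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            matrix=self.matrix.copy(),
            sample_meta=self.sample_meta.copy(),
            feature_meta=self.feature_meta.copy(),
            missing_convention=self.missing_convention,
            imputed_mask=None if self.imputed_mask is None
            else self.imputed_mask.copy(),
        )

    def equals(self, other: "FeatureTable", rtol: float = 1e-9) -> bool:
        if (list(self.matrix.index) != list(other.matrix.index)
                or list(self.matrix.columns) != list(other.matrix.columns)):
            return False
        if self.missing_convention != other.missing_convention:
            return False
        a = self.matrix.to_numpy(dtype=float)
        b = other.matrix.to_numpy(dtype=float)
        return bool(np.allclose(a, b, rtol=rtol, equal_nan=True))


def _read_tsv(path: str | Path, aliases: Mapping[str, str] | None = None
              ) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                        keep_default_na=False)
    frame.index = frame.index.astype(str)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise TripletFormatError(f"duplicate identifiers in {path.name}: {dupes[:5]}")
    if aliases:
        frame = frame.rename(columns={k: v for k, v in aliases.items()
                                      if k in frame.columns and v not in frame.columns})
    return frame


def read_triplet(dataMatrix_path: str | Path,
                 sampleMetadata_path: str | Path,
                 variableMetadata_path: str | Path,
                 missing_convention: str = "auto",
                 sample_aliases: Mapping[str, str] | None = None,
                 feature_aliases: Mapping[str, str] | None = None,
                 ) -> FeatureTable:
    """Load a W4M triplet from three TSV files.

    Identifier sets must agree exactly between the matrix and the metadata
    tables; mismatches raise instead of being silently intersected.  Deposited
    metadata headers vary, so common aliases (``class`` -> ``role``, ``batch``
    -> ``batch_id``, ...) are remapped; pass explicit alias mappings to extend.
    With ``missing_convention="auto"`` the convention is ``"NA"`` when NA
    tokens occur and ``"zero"`` otherwise.
    """
    matrix = _read_tsv(dataMatrix_path)
    sample_meta = _read_tsv(sampleMetadata_path,
                            {**DEFAULT_SAMPLE_ALIASES, **(sample_aliases or {})})
    feature_meta = _read_tsv(variableMetadata_path,
                             {**DEFAULT_FEATURE_ALIASES, **(feature_aliases or {})})
    matrix = matrix.astype(float)
    if missing_convention == "auto":
        missing_convention = "NA" if matrix.isna().any().any() else "zero"
    return FeatureTable(matrix=matrix, sample_meta=sample_meta,
                        feature_meta=feature_meta,
                        missing_convention=missing_convention)


def write_triplet(table: FeatureTable, out_dir: str | Path,
                  prefix: str = "") -> tuple[Path, Path, Path]:
    """Write ``<prefix>dataMatrix.tsv``, ``sampleMetadata.tsv`` and
    ``variableMetadata.tsv`` into ``out_dir`` and return the three paths.

    NA cells are serialized as the literal token ``NA``; the dialect is
    UTF-8, tab-separated, ``.`` decimal separator.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = (out_dir / f"{prefix}dataMatrix.tsv",
             out_dir / f"{prefix}sampleMetadata.tsv",
             out_dir / f"{prefix}variableMetadata.tsv")
    matrix = table.matrix.copy()
    matrix.index.name = matrix.index.name or "feature_id"
    matrix.to_csv(paths[0], sep="\t", na_rep="NA")
    sm = table.sample_meta.copy()
    sm.index.name = sm.index.name or "sample_id"
    sm.to_csv(paths[1], sep="\t", na_rep="NA")
    fm = table.feature_meta.copy()
    fm.index.name = fm.index.name or "feature_id"
    fm.to_csv(paths[2], sep="\t", na_rep="NA")
    return paths
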