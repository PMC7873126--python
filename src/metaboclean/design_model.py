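"""The factorial sampling design and the injection sequence.

The field study sampled 13 grassland species (7 grasses, 6 herbs) arranged in
two pools of eight species each (4 grasses + 4 herbs per pool; LEUVUL, PHLPRA
and PLALAN belong to both pools).  Shoots were collected in four seasons
(A-D), four diversity levels (1, 2, 4, 8 sown species per plot) and two
replicates per plot, giving 4 x 4 x 2 x 8 x 2 = 512 study samples.

Extracts were measured in 12 analytical batches.  A batch starts with a
run-in (three solvent injections and a pooled-QC injection) and then holds
four blocks of eleven study samples; each block is flanked by pooled-QC
injections and a single blank precedes the first block.  Samples are assigned
to batches in Lab-ID order and randomised within blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .w4m_io import Role, SampleRecord, records_to_frame

__all__ = [
    "StudyDesign",
    "InjectionBatch",
    "InjectionSequence",
    "default_design",
    "DOCUMENTED_LOSS",
    "enumerate_study_samples",
    "apply_known_losses",
    "build_injection_sequence",
]

#: the one sample lost before analysis (tube broke): season B, FESRUB in
#: pool 1, diversity level 1, replicate b.
DOCUMENTED_LOSS = {"season": "B", "species_code": "FESRUB", "pool": "P1",
              "diversity_level": 1, "replicate": "b"}


@dataclass
class StudyDesign:
    """Factor levels of the sampling design plus the batch layout."""

    seasons: tuple[str, ...] = ("A", "B", "C", "D")
    diversity_levels: tuple[int, ...] = (1, 2, 4, 8)
    #: pool -> functional group -> species codes
    pools: dict = field(default_factory=lambda: {
        "P1": {
            "grass": ("AVEPUB", "FESRUB", "PHLPRA", "POAPRA"),
            "herb": ("CENJAC", "KNAARV", "LEUVUL", "PLALAN"),
        },
        "P2": {
            "grass": ("ANTODO", "DACGLO", "HOLLAN", "PHLPRA"),
            "herb": ("GERPRA", "LEUVUL", "PLALAN", "RANACR"),
        },
    })
    replicates: tuple[str, ...] = ("a", "b")
    year: int = 2017
    n_batches: int = 12
    block_size: int = 11
    blocks_per_batch: int = 4
    #: run-in composition preceding the sample blocks
    runin_solvents: int = 3
    runin_qcs: int = 1
    blanks_per_batch: int = 1

    def __post_init__(self) -> None:
        for pool, groups in self.pools.items():
            for fg in ("grass", "herb"):
                if len(groups.get(fg, ())) != 4:
                    raise ValueError(f"pool {pool} must hold 4 {fg} species")

    @property
    def batch_capacity(self) -> int:
        return self.block_size * self.blocks_per_batch

    def pool_species(self, pool: str) -> list[str]:
        groups = self.pools[pool]
        return list(groups["grass"]) + list(groups["herb"])

    def species_codes(self) -> list[str]:
        seen: dict[str, None] = {}
        for pool in self.pools:
            for sp in self.pool_species(pool):
                seen.setdefault(sp)
        return list(seen)

    def functional_group(self, species_code: str) -> str:
        for groups in self.pools.values():
            if species_code in groups["grass"]:
                return "grass"
            if species_code in groups["herb"]:
                return "herb"
        raise KeyError(species_code)

    def species_pools(self, species_code: str) -> list[str]:
        return [p for p in self.pools if species_code in self.pool_species(p)]


def default_design() -> StudyDesign:
    """The study design as deployed in the field experiment."""
    return StudyDesign()


def enumerate_study_samples(design: StudyDesign) -> list[SampleRecord]:
    """Expand the factorial design into one record per study sample.

    Ordering is deterministic: season, pool, diversity level, species (grasses
    before herbs, each in pool order), replicate.  Lab-ID numbers (001-128 per
    season) are assigned in that order; the field study drew them at random,
    which matters only for which concrete samples share a batch, not for any
    statistical property of the downstream analysis.
    """
    per_season = (len(design.pools) * len(design.diversity_levels)
                  * 8 * len(design.replicates))
    if per_season > 128:
        raise ValueError("design exceeds the 128 Lab-ID numbers per season")
    records = []
    for season in design.seasons:
        number = 0
        for pool in design.pools:
            species = design.pool_species(pool)
            if len(species) != 8:
                raise ValueError(f"pool {pool} must hold exactly 8 species")
            for dl in design.diversity_levels:
                for sp in species:
                    for rep in design.replicates:
                        number += 1
                        lab_id = f"{number:03d}_{design.year}_{season}"
                        sample_id = f"{season}_{pool}_{sp}_DL{dl}_{rep}"
                        records.append(SampleRecord(
                            sample_id=sample_id,
                            role=Role.STUDY,
                            lab_id=lab_id,
                            species_code=sp,
                            pool=pool,
                            diversity_level=dl,
                            season=season,
                            replicate=rep,
                        ))
    return records


def apply_known_losses(records: list[SampleRecord],
                       losses: list[dict]) -> list[SampleRecord]:
    """Drop samples lost before measurement.

    Each loss is a mapping of SampleRecord fields to values (for example
    :data:`DOCUMENTED_LOSS`) and must match exactly one record; zero or multiple
    matches raise.
    """
    remaining = list(records)
    for loss in losses:
        matches = [r for r in remaining
                   if all(getattr(r, k) == v for k, v in loss.items())]
        if len(matches) != 1:
            raise ValueError(
                f"loss key {loss!r} matched {len(matches)} records, expected 1"
            )
        remaining.remove(matches[0])
    return remaining


@dataclass
class InjectionBatch:
    batch_id: str
    entries: list[SampleRecord]

    def study_samples(self) -> list[SampleRecord]:
        return [e for e in self.entries if e.role is Role.STUDY]

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.role.value] = counts.get(e.role.value, 0) + 1
        return counts


@dataclass
class InjectionSequence:
    batches: list[InjectionBatch]

    def study_samples(self) -> list[SampleRecord]:
        return [r for b in self.batches for r in b.study_samples()]

    def all_entries(self) -> list[SampleRecord]:
        return [e for b in self.batches for e in b.entries]

    def to_sample_metadata(self) -> pd.DataFrame:
        """Export the whole sequence as a sampleMetadata frame."""
        return records_to_frame(self.all_entries())


def _lab_order_key(record: SampleRecord) -> tuple[int, str]:
    from .w4m_io import parse_lab_id

    parts = parse_lab_id(record.lab_id)
    return (parts["number"], parts["season"])


def build_injection_sequence(records: list[SampleRecord],
                             design: StudyDesign,
                             seed: int = 0) -> InjectionSequence:
    """Assign study samples to batches and lay out every injection.

    Samples fill batches to capacity (44) in Lab-ID order — number first, then
    season, so batch 1 holds numbers 001-011 of all four seasons — and any
    shortfall is left in the final batch.  Within a batch, samples are shuffled
    under ``seed`` before being split into blocks, mirroring the random draw of
    block members.  Each batch is laid out as: run-in (solvents + QC), then QC,
    blank, and the blocks each followed by a QC.
    """
    capacity = design.n_batches * design.batch_capacity
    if len(records) > capacity:
        raise ValueError(f"{len(records)} records exceed capacity {capacity}")
    ordered = sorted(records, key=_lab_order_key)
    rng = np.random.default_rng(seed)
    batches = []
    idx = 0
    injection = 0
    for b in range(design.n_batches):
        batch_id = f"pos{b + 1:02d}"
        assigned = ordered[idx: idx + design.batch_capacity]
        idx += len(assigned)
        assigned = [assigned[i] for i in rng.permutation(len(assigned))]
        entries: list[SampleRecord] = []

        def add(role: Role, tag: str) -> None:
            nonlocal injection
            entries.append(SampleRecord(
                sample_id=f"{tag}_{batch_id}", role=role,
                batch_id=batch_id, injection_index=injection))
            injection += 1

        for i in range(design.runin_solvents):
            add(Role.SOLVENT, f"ACN{i + 1}")
        for i in range(design.runin_qcs):
            add(Role.QC_POOL, f"QCrunin{i + 1}")
        qc_counter = 0

        def add_qc() -> None:
            nonlocal qc_counter
            qc_counter += 1
            add(Role.QC_POOL, f"QC{qc_counter}")

        add_qc()
        for i in range(design.blanks_per_batch):
            add(Role.BLANK, f"blank{i + 1}")
        for block in range(design.blocks_per_batch):
            members = assigned[block * design.block_size:
                               (block + 1) * design.block_size]
            if not members:
                break
            for rec in members:
                rec.batch_id = batch_id
                rec.injection_index = injection
                injection += 1
                entries.append(rec)
            add_qc()
        batches.append(InjectionBatch(batch_id=batch_id, entries=entries))
    if idx != len(records):
        raise AssertionError("injection sequence lost records")
    return InjectionSequence(batches=batches)
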