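from collections import Counter
from itertools import product

import pytest

from metaboclean.design_model import (DOCUMENTED_LOSS, StudyDesign,
                                      apply_known_losses,
                                      build_injection_sequence,
                                      default_design,
                                      enumerate_study_samples)
from metaboclean.w4m_io import Role


class TestDesignInvariants:
    def test_pool_composition(self, design):
        for pool in ("P1", "P2"):
            assert len(design.pools[pool]["grass"]) == 4
            assert len(design.pools[pool]["herb"]) == 4
        shared = set(design.pool_species("P1")) & set(design.pool_species("P2"))
        assert shared == {"LEUVUL", "PHLPRA", "PLALAN"}

    def test_thirteen_species_by_functional_group(self, design):
        species = design.species_codes()
        assert len(species) == 13
        groups = Counter(design.functional_group(s) for s in species)
        assert groups == {"grass": 7, "herb": 6}

    def test_pool_size_enforced(self):
        bad = {"P1": {"grass": ("A1", "B1", "C1"), "herb": ("D1", "E1", "F1", "G1")}}
        with pytest.raises(ValueError):
            StudyDesign(pools=bad)


class TestEnumeration:
    def test_total_count_matches_brute_force(self, design):
        records = enumerate_study_samples(design)
        # independent oracle: nested loops over the factor levels
        expected = sum(1 for _ in product(
            design.seasons, design.pools, design.diversity_levels,
            range(8), design.replicates))
        assert len(records) == expected == 512

    @pytest.mark.parametrize("species, count", [
        ("PHLPRA", 64),   # member of both pools
        ("LEUVUL", 64),
        ("FESRUB", 32),   # single-pool species
        ("RANACR", 32),
    ])
    def test_per_species_counts(self, design, species, count):
        records = enumerate_study_samples(design)
        assert sum(r.species_code == species for r in records) == count

    def test_dual_pool_species_get_double_records(self, design):
        records = enumerate_study_samples(design)
        counts = Counter(r.species_code for r in records)
        for sp in design.species_codes():
            expected = 32 * len(design.species_pools(sp))
            assert counts[sp] == expected

    def test_lab_ids_valid_and_unique_per_season(self, design):
        records = enumerate_study_samples(design)
        per_season = Counter()
        for r in records:
            from metaboclean.w4m_io import parse_lab_id
            parts = parse_lab_id(r.lab_id)
            assert 1 <= parts["number"] <= 128
            per_season[(parts["season"], parts["number"])] += 1
        assert max(per_season.values()) == 1


class TestKnownLosses:
    def test_documented_loss_gives_511(self, design):
        records = enumerate_study_samples(design)
        remaining = apply_known_losses(records, [DOCUMENTED_LOSS])
        assert len(remaining) == 511

    def test_empty_loss_list_is_identity(self, design):
        records = enumerate_study_samples(design)
        assert apply_known_losses(records, []) == records

    def test_duplicate_loss_key_raises(self, design):
        records = enumerate_study_samples(design)
        with pytest.raises(ValueError):
            apply_known_losses(records, [DOCUMENTED_LOSS, DOCUMENTED_LOSS])

    def test_ambiguous_loss_key_raises(self, design):
        records = enumerate_study_samples(design)
        with pytest.raises(ValueError):
            apply_known_losses(records, [{"species_code": "PHLPRA"}])


class TestInjectionSequence:
    def test_batch_fill_and_conservation(self, design, measured_records):
        seq = build_injection_sequence(measured_records, design, seed=1)
        per_batch = [len(b.study_samples()) for b in seq.batches]
        assert per_batch == [44] * 11 + [27]
        assert sum(per_batch) == 511
        ids = [r.sample_id for r in seq.study_samples()]
        assert len(ids) == len(set(ids)) == 511  # no duplication, no loss

    def test_lab_id_order_across_batches(self, design, measured_records):
        """Batch 1 holds the 44 lowest Lab IDs in (number, season) order.

        With the one documented loss the 44th slot slides one record
        forward, so the expected set is computed from an independent sort
        rather than assumed to be numbers 1-11 exactly.
        """
        from metaboclean.w4m_io import parse_lab_id
        seq = build_injection_sequence(measured_records, design, seed=3)
        got = sorted(r.sample_id for r in seq.batches[0].study_samples())
        key = lambda r: (parse_lab_id(r.lab_id)["number"],
                         parse_lab_id(r.lab_id)["season"])
        expected = sorted(r.sample_id
                          for r in sorted(measured_records, key=key)[:44])
        assert got == expected

    def test_single_batch_layout(self, design, measured_records):
        one = StudyDesign(n_batches=1)
        seq = build_injection_sequence(measured_records[:44], one, seed=0)
        roles = [e.role for e in seq.batches[0].entries]
        # run-in: three solvents then a QC
        assert roles[:4] == [Role.SOLVENT] * 3 + [Role.QC_POOL]
        # equilibration QC and one blank before the first block
        assert roles[4:6] == [Role.QC_POOL, Role.BLANK]
        # four blocks of eleven, each followed by a QC
        for block in range(4):
            start = 6 + block * 12
            assert roles[start:start + 11] == [Role.STUDY] * 11
            assert roles[start + 11] == Role.QC_POOL

    def test_blocks_flanked_by_qc(self, design, measured_records):
        seq = build_injection_sequence(measured_records, design, seed=2)
        for batch in seq.batches:
            roles = [e.role for e in batch.entries]
            for i, role in enumerate(roles):
                if role is Role.STUDY:
                    before = [r for r in roles[:i]
                              if r in (Role.QC_POOL, Role.BLANK)]
                    assert before, "study sample before any QC"
            assert roles[-1] is Role.QC_POOL  # trailing flank

    def test_seeded_determinism(self, design, measured_records):
        a = build_injection_sequence(measured_records, design, seed=7)
        b = build_injection_sequence(measured_records, design, seed=7)
        assert ([r.sample_id for r in a.all_entries()]
                == [r.sample_id for r in b.all_entries()])
        c = build_injection_sequence(measured_records, design, seed=8)
        assert ([r.sample_id for r in a.all_entries()]
                != [r.sample_id for r in c.all_entries()])

    def test_capacity_error(self, design):
        records = enumerate_study_samples(design)
        small = StudyDesign(n_batches=2)
        with pytest.raises(ValueError):
            build_injection_sequence(records, small, seed=0)

    def test_sequence_exports_metadata(self, design, measured_records):
        seq = build_injection_sequence(measured_records, design, seed=1)
        meta = seq.to_sample_metadata()
        assert meta["role"].value_counts()["study"] == 511
        assert meta["injection_index"].is_monotonic_increasing
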