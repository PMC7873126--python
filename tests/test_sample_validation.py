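import numpy as np
import pandas as pd
import pytest

from metaboclean import sample_validation as sv
from metaboclean.feature_filters import SpeciesFingerprint, build_fingerprints
from metaboclean.sample_validation import (ValidityParams, shared_fraction,
                                           mahalanobis_per_species,
                                           validate_samples)

from conftest import make_table


def gaussian_cloud(n=40, f=60, seed=0, scale=1000.0, sd=0.1):
    rng = np.random.default_rng(seed)
    logs = np.log(scale) + rng.normal(0, sd, size=(f, n))
    return make_table(np.exp(logs))


def fingerprint_of(feature_ids, species="SPECIE", n_samples=32):
    frac = pd.Series(1.0, index=pd.Index(list(feature_ids),
                                         name="feature_id"))
    return SpeciesFingerprint(species_code=species, detection_fraction=frac,
                              min_detection_fraction=0.25,
                              min_detection_count=8, n_samples=n_samples)


class TestMahalanobis:
    def test_displaced_sample_has_largest_distance(self):
        table = gaussian_cloud(seed=3)
        table.matrix.iloc[:30, 0] *= 50.0  # shove s1 away on 30 features
        d = mahalanobis_per_species(table, "SPECIE", ValidityParams())
        assert d.idxmax() == "s1"
        # an in-sample point's distance is capped at (n-1)/sqrt(n) because
        # the outlier inflates its own covariance; a gross displacement
        # saturates that bound
        n = 40
        assert d["s1"] > 0.95 * (n - 1) / np.sqrt(n)

    def test_identical_samples_give_zero(self):
        table = make_table(np.tile(np.linspace(200, 900, 20), (30, 1)).T)
        d = mahalanobis_per_species(table, "SPECIE", ValidityParams())
        assert np.allclose(d.to_numpy(), 0.0)

    def test_mean_squared_distance_matches_chi_square(self):
        """For an i.i.d. Gaussian cloud the in-sample squared distance in an
        m-dimensional score space averages m * (n-1) / n."""
        n, m = 200, 10
        table = gaussian_cloud(n=n, f=80, seed=5)
        d = mahalanobis_per_species(
            table, "SPECIE", ValidityParams(n_components=m))
        expected = m * (n - 1) / n
        assert np.mean(d.to_numpy() ** 2) == pytest.approx(expected, rel=0.05)

    def test_scale_invariance(self):
        table = gaussian_cloud(seed=7)
        scaled = table.copy()
        scaled.matrix *= 1000.0
        a = mahalanobis_per_species(table, "SPECIE", ValidityParams())
        b = mahalanobis_per_species(scaled, "SPECIE", ValidityParams())
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    @pytest.mark.parametrize("reg", ["pseudo_inverse", "shrinkage"])
    def test_alternative_covariances_rank_outlier_first(self, reg):
        table = gaussian_cloud(n=30, f=20, seed=11)
        table.matrix.iloc[:10, 2] *= 40.0
        d = mahalanobis_per_species(
            table, "SPECIE", ValidityParams(covariance_regularization=reg))
        assert d.idxmax() == "s3"

    def test_too_few_samples_rejected(self):
        table = gaussian_cloud(n=3, f=10)
        with pytest.raises(ValueError):
            mahalanobis_per_species(table, "SPECIE", ValidityParams())

    def test_missing_cells_rejected(self):
        table = gaussian_cloud(n=10, f=10)
        table.matrix.iloc[0, 0] = np.nan
        table.missing_convention = "NA"
        with pytest.raises(ValueError):
            mahalanobis_per_species(table, "SPECIE", ValidityParams())


class TestSharedFraction:
    def test_full_overlap(self):
        fp = fingerprint_of(["f1", "f2", "f3"])
        assert shared_fraction(["f1", "f2", "f3", "f9"], fp) == 1.0

    def test_no_overlap(self):
        fp = fingerprint_of(["f1", "f2", "f3"])
        assert shared_fraction(["f8", "f9"], fp) == 0.0

    def test_partial_overlap(self):
        fp = fingerprint_of([f"f{i}" for i in range(1, 41)])  # 40 members
        detected = [f"f{i}" for i in range(1, 13)]            # 12 of them
        assert shared_fraction(detected, fp) == pytest.approx(0.30)

    def test_empty_fingerprint_rejected(self):
        fp = fingerprint_of([])
        with pytest.raises(ValueError):
            shared_fraction(["f1"], fp)


class TestValidateSamples:
    def cloud_with_fingerprints(self, seed=0):
        table = gaussian_cloud(n=32, f=60, seed=seed)
        fps = build_fingerprints(table)
        return table, fps

    def test_clean_cloud_all_pass(self):
        table, fps = self.cloud_with_fingerprints(seed=1)
        report, kept = validate_samples(table, fps)
        assert (report.table["decision"] == "pass").all()
        assert kept.n_samples == table.n_samples

    def test_low_shared_fraction_fails(self):
        table, fps = self.cloud_with_fingerprints(seed=2)
        # detection judged on a pre-imputation table: s1 detects almost
        # nothing of the fingerprint
        det = table.copy()
        det.matrix.iloc[5:, 0] = np.nan
        det.missing_convention = "NA"
        report, kept = validate_samples(table, fps, detection_table=det)
        assert report.table.loc["s1", "decision"] == "fail_shared"
        assert "s1" not in kept.matrix.columns
        assert set(report.passing_ids()) == set(kept.matrix.columns)

    def test_distance_boundary_is_inclusive(self, monkeypatch):
        """A sample at exactly distance_multiplier x peer average passes."""
        table, fps = self.cloud_with_fingerprints(seed=3)
        ids = table.matrix.columns
        dist = pd.Series(1.0, index=ids)
        # peers of s1 all at 1.0 -> peer average 1.0; s1 exactly at 3.0
        dist["s1"] = 3.0
        monkeypatch.setattr(sv, "mahalanobis_per_species",
                            lambda *a, **k: dist)
        report, kept = validate_samples(table, fps)
        assert report.table.loc["s1", "decision"] == "pass"
        just_over = dist.copy()
        just_over["s1"] = 3.0 + 1e-6
        monkeypatch.setattr(sv, "mahalanobis_per_species",
                            lambda *a, **k: just_over)
        report, _ = validate_samples(table, fps)
        assert report.table.loc["s1", "decision"] == "fail_distance"

    def test_fail_both_recorded(self, monkeypatch):
        table, fps = self.cloud_with_fingerprints(seed=4)
        det = table.copy()
        det.matrix.iloc[5:, 0] = np.nan
        det.missing_convention = "NA"
        dist = pd.Series(1.0, index=table.matrix.columns)
        dist["s1"] = 100.0
        monkeypatch.setattr(sv, "mahalanobis_per_species",
                            lambda *a, **k: dist)
        report, _ = validate_samples(table, fps, detection_table=det)
        assert report.table.loc["s1", "decision"] == "fail_both"

    def test_report_partitions_study_samples(self):
        table, fps = self.cloud_with_fingerprints(seed=5)
        report, kept = validate_samples(table, fps)
        study = set(table.sample_ids("study"))
        assert set(report.table.index) == study
        assert (set(report.passing_ids())
                | set(report.failures().index)) == study
        assert not set(report.passing_ids()) & set(report.failures().index)

    def test_unknown_species_rejected(self):
        table, fps = self.cloud_with_fingerprints(seed=6)
        del fps["SPECIE"]
        with pytest.raises(KeyError):
            validate_samples(table, fps)


class TestValidityParams:
    @pytest.mark.parametrize("kwargs", [
        {"distance_multiplier": 0.0},
        {"min_shared_fraction": 1.5},
        {"covariance_regularization": "banana"},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ValidityParams(**kwargs)
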