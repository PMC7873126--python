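import numpy as np
import pandas as pd
import pytest

from metaboclean import (FeatureTable, SimulationConfig, apply_known_losses,
                         default_design, enumerate_study_samples, simulate)
from metaboclean.design_model import DOCUMENTED_LOSS


def make_table(values, roles=None, species=None, batches=None, rts=None,
               missing_convention="NA"):
    """Hand-rolled FeatureTable from a 2D array (features x samples)."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    fids = [f"f{i + 1}" for i in range(n_feat)]
    sids = [f"s{j + 1}" for j in range(n_samp)]
    roles = roles or ["study"] * n_samp
    meta = {
        "role": roles,
        "lab_id": [None] * n_samp,
        "species_code": species or [("SPECIE" if r == "study" else None)
                                    for r in roles],
        "pool": [("P1" if r == "study" else None) for r in roles],
        "diversity_level": [(1 if r == "study" else None) for r in roles],
        "season": [("A" if r == "study" else None) for r in roles],
        "replicate": [("a" if r == "study" else None) for r in roles],
        "plot_id": [None] * n_samp,
        "batch_id": batches or ["pos01"] * n_samp,
        "injection_index": list(range(n_samp)),
    }
    sample_meta = pd.DataFrame(meta, index=pd.Index(sids, name="sample_id"))
    feature_meta = pd.DataFrame(
        {"mz": np.linspace(100, 900, n_feat),
         "rt": rts if rts is not None else np.linspace(100, 800, n_feat)},
        index=pd.Index(fids, name="feature_id"))
    return FeatureTable(matrix=pd.DataFrame(values, index=feature_meta.index,
                                            columns=sample_meta.index),
                        sample_meta=sample_meta, feature_meta=feature_meta,
                        missing_convention=missing_convention)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def measured_records(design):
    return apply_known_losses(enumerate_study_samples(design), [DOCUMENTED_LOSS])


@pytest.fixture(scope="session")
def study_table(design, measured_records):
    """One study-scale simulated table shared by read-only tests."""
    table, truth = simulate(design, SimulationConfig(seed=11),
                            records=measured_records)
    return table, truth
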