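import numpy as np
import pandas as pd
import pytest

from spectragp import stage1
from spectragp.pedigree import build_a_matrix
from spectragp.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study conditions shared across stage tests: enough
    records per HYS class (~30) for BLUE recovery, two traits, a short
    spectrum."""
    return SimConfig(n_sires=40, daughters_per_sire=5, n_herds=10, years=2,
                     n_wavenumbers=12, n_snps=150, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def edited_records(small_dataset) -> pd.DataFrame:
    records = stage1.assign_classes(small_dataset.records)
    return stage1.apply_editing(
        records, stage1.EditThresholds(min_cow_records=8, min_hys_size=8))


@pytest.fixture(scope="session")
def a_matrix(small_dataset):
    return build_a_matrix(small_dataset.pedigree)


@pytest.fixture(scope="session")
def mme(edited_records, a_matrix) -> stage1.MmeStructure:
    return stage1.build_mme_structure(edited_records, a_matrix)


@pytest.fixture(scope="session")
def my_fit(edited_records, a_matrix, mme):
    """Variance components and MME solutions for milk yield on the shared
    dataset (short, seeded chain)."""
    vc = stage1.gibbs_variance_components(
        edited_records, "my", a_matrix, stage1.ChainConfig(800, 300, 2, seed=5), mme=mme)
    fit = stage1.solve_mme_fixed_vc(edited_records, "my", a_matrix, vc, mme=mme)
    return vc, fit


def toy_records(rows, wvn=0):
    """Small hand-built test-day frames for editing / aggregation toys."""
    cols = ["cow_id", "sire_id", "herd_id", "hys_id", "nsl_id", "dim", "my"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    for w in range(wvn):
        df[f"wvn_{w + 1:04d}"] = np.linspace(-1, 1, len(df)) * (w + 1)
    return df
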