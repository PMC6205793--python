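import numpy as np
import pandas as pd
import pytest

from placmeth.data import BetaMatrix, SampleSheet
from placmeth.simulate import SimConfig, generate_cohort, generate_reference_samples


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort used by several suites: 2,000 CpGs, full design."""
    return SimConfig(n_cpg=2000, n_tissue_specific=30, n_celltype_specific=30,
                     n_ga_effect=20, n_sex_effect=20, seed=1234)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference_samples(small_config)


@pytest.fixture()
def toy_matrix() -> BetaMatrix:
    rng = np.random.default_rng(7)
    frame = pd.DataFrame(
        rng.uniform(0.05, 0.95, (10, 6)),
        index=[f"cg{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(6)],
    )
    return BetaMatrix(frame)


@pytest.fixture()
def toy_sheet(toy_matrix) -> SampleSheet:
    n = toy_matrix.n_samples
    return SampleSheet(pd.DataFrame({
        "sample_id": list(toy_matrix.sample_ids),
        "tissue": ["chorionic_villi"] * n,
        "aca_status": ["aCA", "aCA", "aCA", "non-aCA", "non-aCA", "non-aCA"],
        "ga_weeks": [30.0, 31.0, 29.5, 32.0, 33.0, 31.5],
        "fetal_sex": ["M", "F", "M", "F", "M", "F"],
        "chip_id": ["c1", "c1", "c2", "c2", "c1", "c2"],
        "chip_row": ["r1", "r2", "r1", "r2", "r3", "r3"],
    }))


def villi_subset(matrix, sheet):
    """Chorionic-villi columns of a cohort plus the matching sheet rows."""
    ids = sheet.frame.loc[sheet.frame["tissue"] == "chorionic_villi", "sample_id"]
    return matrix.select_samples(ids), sheet.subset(sheet.frame["sample_id"].isin(ids))
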