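import numpy as np
import pandas as pd
import pytest

import muriclock as mc


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale two-strain cohort: fast but structurally complete."""
    return mc.CohortSpec(
        n_probes=3000,
        n_aging_shared=40,
        n_aging_strain_private=20,
        n_antagonistic=10,
        n_strain_offset=200,
        n_xy=50,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return mc.generate_mouse_cohort(small_spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (12 B6 + 12 DBA, 20k probes)."""
    return mc.generate_mouse_cohort(mc.CohortSpec(seed=1))


@pytest.fixture()
def toy_matrix():
    values = pd.DataFrame(
        [[0.1, 0.2, 0.3], [0.5, np.nan, 0.7], [0.9, 0.8, 0.85]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3"],
    )
    return mc.BetaMatrix(values)


@pytest.fixture()
def toy_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "strain": ["B6", "B6", "B6"],
            "sex": ["F", "F", "F"],
            "age_weeks": [10.0, 60.0, 110.0],
        }
    )


def strain_samples(sheet: pd.DataFrame, strain: str) -> list[str]:
    return list(sheet.loc[sheet["strain"] == strain, "sample_id"])
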