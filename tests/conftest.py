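import dataclasses

import numpy as np
import pandas as pd
import pytest

import saltfort as sf


@pytest.fixture(scope="session")
def refs():
    return sf.NutrientReferences.default()


@pytest.fixture(scope="session")
def default_cfg():
    return sf.default_config(seed=7)


def scaled_config(factor: float, seed: int = 7) -> sf.PopulationConfig:
    """Default study conditions with stratum sizes scaled down for speed."""
    cfg = sf.default_config(seed=seed)
    n = {
        region: {stage: max(2, int(round(k * factor))) for stage, k in by.items()}
        for region, by in cfg.n_per_stratum.items()
    }
    return dataclasses.replace(cfg, n_per_stratum=n)


@pytest.fixture(scope="session")
def small_population():
    """~280-person survey under the default conditions (for fast tests)."""
    return sf.generate_population(scaled_config(0.125))


@pytest.fixture(scope="session")
def full_population(default_cfg):
    """The full 2271-person default survey."""
    return sf.generate_population(default_cfg)


def toy_participants(n_adults=4, n_children=2, region="AddisAbaba",
                     total_salt=8.0, adult_energy=2000.0, child_energy=900.0):
    """Tiny hand-checkable participant frame."""
    rows = []
    for i in range(n_adults):
        rows.append(dict(participant_id=f"a{i}", region=region,
                         life_stage="woman_15_49y", status="none",
                         residence="urban", ses_quintile=5,
                         energy_kcal_d=adult_energy, total_salt_g_d=total_salt,
                         weekend=False, sick=False, unusual=False))
    for i in range(n_children):
        rows.append(dict(participant_id=f"c{i}", region=region,
                         life_stage="child_1_3y", status="none",
                         residence="urban", ses_quintile=5,
                         energy_kcal_d=child_energy, total_salt_g_d=np.nan,
                         weekend=False, sick=False, unusual=False))
    return pd.DataFrame(rows)
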