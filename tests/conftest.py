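"""Shared fixtures: small planted cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from ftdpls import SimConfig, generate_cohort
from ftdpls.cohort import zscore_columns

ZERO_SHIFT = {"bvFTD": (0.0, 0.0), "svPPA": (0.0, 0.0), "nfvPPA": (0.0, 0.0)}


def planted_config(seed: int = 0, n: int = 150, rho=(0.7, 0.5), **kw) -> SimConfig:
    """A single-group planted-structure cohort with confounds switched off."""
    defaults = dict(
        seed=seed, rho=rho,
        n_per_group={"bvFTD": n, "svPPA": 1, "nfvPPA": 1, "control": 1},
        group_shift=ZERO_SHIFT, demo_effects={},
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def null_config(seed: int = 0, n: int = 100, **kw) -> SimConfig:
    defaults = dict(
        seed=seed, rho=(0.0, 0.0), group_shift=ZERO_SHIFT, demo_effects={},
        n_per_group={"bvFTD": n - 2 * (n // 3), "svPPA": n // 3, "nfvPPA": n // 3,
                     "control": 1},
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def planted_cohort():
    """One planted cohort plus its z-scored patient blocks."""
    cfg = planted_config(seed=11)
    cohort, truth = generate_cohort(cfg)
    pat = cohort.patients().baseline()
    Xz, _ = zscore_columns(pat.cognition())
    Yz, _ = zscore_columns(pat.brain())
    return {"config": cfg, "cohort": cohort, "truth": truth, "Xz": Xz, "Yz": Yz}


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-sized cohort (three patient groups + controls)."""
    cfg = SimConfig(seed=5)
    cohort, truth = generate_cohort(cfg)
    return {"config": cfg, "cohort": cohort, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_toy_cohort(n_per_group=4, seed=0, missing=None) -> pd.DataFrame:
    """Tiny hand-sized cohort table for I/O and preprocessing tests."""
    cfg = SimConfig(
        seed=seed, n_per_group={"bvFTD": n_per_group, "svPPA": n_per_group,
                                "nfvPPA": n_per_group, "control": n_per_group},
        p_cog=4, p_brain=6, n_latent=1, rho=(0.5,), salience_sparsity=0.5,
        group_shift={"bvFTD": (0.0,), "svPPA": (0.0,), "nfvPPA": (0.0,)})
    cohort, _ = generate_cohort(cfg)
    if missing:
        for (row, col) in missing:
            cohort.data.loc[row, col] = np.nan
    return cohort
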