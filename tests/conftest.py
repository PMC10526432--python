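"""Shared fixtures: small synthetic cohorts and feature tables.

Everything is generated at test time from fixed seeds; session scope
keeps the expensive cohorts to a single build per run.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from eegdiff import build_feature_table, generate_cohort, preprocess_recording
from eegdiff.synth import CohortConfig, CouplingSpec

GROUP_A, GROUP_B = "GAD", "DD"


def uniform_amp(a: float, b: float | None = None) -> dict:
    b = a if b is None else b
    return {GROUP_A: {k: a for k in ("theta", "alpha1", "alpha2", "beta")},
            GROUP_B: {k: b for k in ("theta", "alpha1", "alpha2", "beta")}}


def beta_power_config(seed: int, n: int = 10, duration: float = 60.0,
                      ratio: float = 2.0) -> CohortConfig:
    """Groups differ only in beta oscillator amplitude (B higher)."""
    amp = {GROUP_A: {"theta": 4.0, "alpha1": 6.0, "alpha2": 5.0, "beta": 3.0},
           GROUP_B: {"theta": 4.0, "alpha1": 6.0, "alpha2": 5.0,
                     "beta": 3.0 * ratio}}
    return CohortConfig(n_group_a=n, n_group_b=n, duration=duration,
                        band_amp=amp, seed=seed)


BETA_COUPLING_PAIRS = (("C4", "T4"), ("F7", "T3"), ("P3", "T5"))


def beta_coupling_config(seed: int, n: int = 10, duration: float = 60.0,
                         s_a: float = 0.1, s_b: float = 0.8) -> CohortConfig:
    """Groups differ only in beta-band coupling on three channel pairs."""
    coupling = [CouplingSpec(pair, "beta", np.pi / 3, {GROUP_A: s_a, GROUP_B: s_b})
                for pair in BETA_COUPLING_PAIRS]
    return CohortConfig(n_group_a=n, n_group_b=n, duration=duration,
                        coupling=coupling, seed=seed)


def null_config(seed: int, n: int = 10, duration: float = 60.0,
                amp_sigma: float = 0.2) -> CohortConfig:
    """Both groups share identical generative parameters."""
    return CohortConfig(n_group_a=n, n_group_b=n, duration=duration,
                        amp_sigma=amp_sigma, seed=seed)


def cohort_table(config: CohortConfig, families=("PSD", "FE", "PLI"),
                 ) -> pd.DataFrame:
    tables = [build_feature_table(preprocess_recording(rec), families=families)
              for rec in generate_cohort(config)]
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def tiny_cohort_table() -> pd.DataFrame:
    """4 + 4 subjects x 12 s, all families: fast, full column layout."""
    cfg = null_config(seed=5, n=4, duration=12.0)
    return cohort_table(cfg)


@pytest.fixture(scope="session")
def conn_table() -> pd.DataFrame:
    """Connectivity-only group difference: 8 + 8 subjects x 60 s, all
    families. Beta-band coupling raised in group B on four pairs; every
    other generative parameter identical across groups."""
    coupling = [
        CouplingSpec(("C4", "T4"), "beta", np.pi / 3, {GROUP_A: 0.1, GROUP_B: 0.8}),
        CouplingSpec(("F7", "T3"), "beta", np.pi / 4, {GROUP_A: 0.1, GROUP_B: 0.8}),
        CouplingSpec(("P3", "T5"), "beta", np.pi / 3, {GROUP_A: 0.1, GROUP_B: 0.8}),
        CouplingSpec(("F3", "C3"), "beta", np.pi / 3, {GROUP_A: 0.15, GROUP_B: 0.75}),
    ]
    cfg = CohortConfig(n_group_a=8, n_group_b=8, duration=60.0,
                       coupling=coupling, seed=11)
    return cohort_table(cfg)
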