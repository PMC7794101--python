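"""Shared fixtures: small synthetic cohorts and plate tables."""

import numpy as np
import pandas as pd
import pytest

from pylorimet.panel import PanelDefinition, default_panel
from pylorimet.synth import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_panel(panel):
    """40-metabolite subpanel: the seven feeding-affected species plus a
    class-diverse spread of the rest."""
    from pylorimet.synth import AFFECTED_DEFAULT
    keep = [e for e in panel.entries if e.name in AFFECTED_DEFAULT]
    rest = [e for e in panel.entries if e.name not in AFFECTED_DEFAULT]
    keep += rest[::12][:33]
    return PanelDefinition(keep)


@pytest.fixture(scope="session")
def tiny_dataset(small_panel):
    """20 pairs on 2 plates with designed QC failures, plus ground truth."""
    from pylorimet.synth import AFFECTED_DEFAULT
    other = [n for n in small_panel.names() if n not in AFFECTED_DEFAULT]
    cfg = SimConfig(
        n_pairs=20, n_plates=2, seed=42,
        fail_lod_metabolites=tuple(other[:3]),
        fail_cv_metabolites=tuple(other[3:5]),
    )
    samples, plates, truth = simulate_dataset(small_panel, cfg)
    return cfg, samples, plates, truth


def make_paired_samples(n_pairs: int, rng: np.random.Generator) -> pd.DataFrame:
    """Minimal matched sample sheet with the full covariate set."""
    pair = np.repeat(np.arange(n_pairs), 2)
    case = np.tile([1, 0], n_pairs)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(2 * n_pairs)],
        "pair_id": [f"p{i}" for i in pair],
        "case": case,
        "sex": np.repeat(rng.choice(["M", "F"], n_pairs, p=[0.87, 0.13]), 2),
        "year_of_birth": np.repeat(rng.integers(1997, 2015, n_pairs), 2),
        "parity": np.repeat(1 + rng.poisson(0.75, n_pairs), 2),
        "gestational_age_wk": np.repeat(
            np.round(rng.normal(40, 1.5, n_pairs), 1), 2),
        "cesarean": rng.integers(0, 2, 2 * n_pairs),
    })
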