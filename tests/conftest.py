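import numpy as np
import pandas as pd
import pytest

from mrmediate.summary_stats import (
    CANONICAL_COLUMNS,
    HARMONIZED_COLUMNS,
    HarmonizedSet,
    SummaryStatsTable,
)


def make_table(rows, trait_id="trait", trait_type="continuous"):
    """Build a SummaryStatsTable from a list of dicts with canonical keys."""
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return SummaryStatsTable(trait_id=trait_id, df=df, trait_type=trait_type)


def make_hset(
    bX,
    bY,
    seX=None,
    seY=None,
    snp_ids=None,
    exposure_id="exp",
    outcome_id="out",
    n_exposure=None,
    n_outcome=None,
):
    """Build a HarmonizedSet straight from effect arrays."""
    bX = np.asarray(bX, dtype=float)
    bY = np.asarray(bY, dtype=float)
    k = len(bX)
    seX = np.full(k, 0.01) if seX is None else np.asarray(seX, dtype=float)
    seY = np.full(k, 0.01) if seY is None else np.asarray(seY, dtype=float)
    rows = pd.DataFrame(
        {
            "snp_id": snp_ids if snp_ids is not None else [f"rs{i}" for i in range(k)],
            "beta_exposure": bX,
            "se_exposure": seX,
            "beta_outcome": bY,
            "se_outcome": seY,
            "eaf_exposure": np.full(k, 0.3),
            "eaf_outcome": np.full(k, 0.3),
            "pval_exposure": np.full(k, 1e-8),
            "pval_outcome": np.full(k, 0.5),
            "flipped": False,
            "palindromic": False,
            "dropped_reason": None,
        },
        columns=HARMONIZED_COLUMNS,
    )
    return HarmonizedSet(exposure_id, outcome_id, rows, n_exposure, n_outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture(scope="session")
def small_study():
    """One cached small three-node study for cheap cross-module tests."""
    from mrmediate.synthetic import SimulationConfig, simulate_three_node_study

    cfg = SimulationConfig(
        n_exposure=4000, n_mediator=4000, n_outcome=4000, seed=11
    )
    return simulate_three_node_study(cfg)
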