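import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import statetraits as st

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from statetraits.synthetic import InventorySpec, between_sd_for_icc


def make_response_table(rows, units, likert_min=1, likert_max=6):
    """Hand-built ResponseTable: rows = [(pid, item_id, value)], units = {pid: unit}."""
    pids = list(dict.fromkeys(units))
    participants = pd.DataFrame(
        {"unit": [units[p] for p in pids], "sample_id": "test"},
        index=pd.Index(pids, name="participant_id"),
    )
    responses = pd.DataFrame(rows, columns=["participant_id", "item_id", "value"])
    return st.ResponseTable(
        participants=participants,
        responses=responses,
        likert_min=likert_min,
        likert_max=likert_max,
    )


@pytest.fixture(scope="session")
def tiny_bank():
    """Hand-built two-inventory bank with known keying."""
    return pd.DataFrame(
        {
            "item_id": ["A1", "A2", "A3", "B1", "B2", "X1"],
            "inventory": ["inv1", "inv1", "inv1", "inv1", "inv1", "inv2"],
            "trait": ["T1", "T1", "T1", "T2", "T2", "T1"],
            "keying": np.array([1, 1, -1, 1, -1, 1], dtype=np.int8),
            "sampling_rate": 1.0,
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """Default-condition study at modest n for structural tests."""
    cfg = st.SyntheticConfig(
        n_participants=5000, seed=7, sociodemo_specs=st.default_sociodemo_specs()
    )
    bank = st.generate_item_bank(cfg)
    responses, truth = st.generate_responses(cfg, bank)
    return cfg, bank, responses, truth


@pytest.fixture(scope="session")
def recovery_study():
    """Large-sample study at the emulated between-unit effect size.

    51 units, n = 1e5, latent ICC1 calibrated to 0.0030 exactly, mid-scale
    trait means so Likert clipping is symmetric.
    """
    cfg = st.SyntheticConfig(
        n_participants=100_000,
        seed=42,
        trait_means=3.5,
        between_unit_sd=between_sd_for_icc(0.0030),
    )
    bank = st.generate_item_bank(cfg)
    responses, truth = st.generate_responses(cfg, bank)
    scores = st.score_scales(responses, bank, "BFFM")
    return cfg, scores, truth


@pytest.fixture(scope="session")
def quota_study():
    """Fixed-quota study with ~500 participants per unit for permutation nulls."""
    cfg = st.SyntheticConfig(
        n_participants=25_500,
        seed=7,
        assignment="quota",
        trait_means=3.5,
        between_unit_sd=between_sd_for_icc(0.0030),
    )
    bank = st.generate_item_bank(cfg)
    responses, _ = st.generate_responses(cfg, bank)
    return cfg, st.score_scales(responses, bank, "BFFM")


@pytest.fixture(scope="session")
def twin_inventory_study():
    """Two disjoint inventories measuring the same latent traits (ICC1 = 0.01)."""
    cfg = st.SyntheticConfig(
        n_participants=20_000,
        seed=3,
        trait_means=3.5,
        between_unit_sd=between_sd_for_icc(0.01),
        inventories=(InventorySpec("A", 20, 0.5), InventorySpec("B", 20, 0.5)),
    )
    bank = st.generate_item_bank(cfg)
    responses, truth = st.generate_responses(cfg, bank)
    census = st.generate_census(cfg)
    return cfg, bank, responses, truth, census


@pytest.fixture(scope="session")
def big_cheap_study():
    """1e5 participants with a near-empty item pool: cheap demographics at scale."""
    cfg = st.SyntheticConfig(
        n_participants=100_000,
        seed=13,
        inventories=(InventorySpec("stub", 1, 0.0),),
    )
    bank = st.generate_item_bank(cfg)
    responses, truth = st.generate_responses(cfg, bank)
    census = st.generate_census(cfg)
    return cfg, responses, census
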