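"""Shared fixtures: small synthetic datasets and reusable helpers."""

from dataclasses import replace

import numpy as np
import pytest

import motupipe as mp


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(**overrides) -> mp.SimConfig:
    """A scaled-down survey for fast unit tests."""
    cfg = mp.SimConfig(
        groups=(
            mp.GroupSimConfig("polychaete", s_true=40, n_individuals=45, german_share=0.78),
            mp.GroupSimConfig("isopod", s_true=20, n_individuals=20, german_share=0.51),
        ),
    )
    return replace(cfg, **overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_dataset() -> mp.SimulatedDataset:
    return mp.simulate_dataset(small_config(), seed=7)


@pytest.fixture(scope="session")
def default_dataset() -> mp.SimulatedDataset:
    """One draw at the generator's default (survey-scale) configuration."""
    return mp.simulate_dataset(mp.SimConfig(), seed=11)


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly n substitutions at distinct positions (never back to itself)."""
    out = list(seq)
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)
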