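"""Shared fixtures: small random instances with and without missing cells."""

from __future__ import annotations

import numpy as np
import pytest

from feeclust import MaskedDataset


def random_complete_dataset(rng: np.random.Generator, n: int, d: int) -> MaskedDataset:
    values = rng.normal(size=(n, d))
    return MaskedDataset(values=values, observed=np.ones((n, d), dtype=bool))


def random_masked_dataset(
    rng: np.random.Generator,
    n: int,
    d: int,
    incomplete_fraction: float = 0.25,
    k_missing: int = 1,
) -> MaskedDataset:
    values = rng.normal(size=(n, d))
    observed = np.ones((n, d), dtype=bool)
    n_incomplete = int(round(incomplete_fraction * n))
    rows = rng.choice(n, size=n_incomplete, replace=False)
    for r in rows:
        feats = rng.choice(d, size=k_missing, replace=False)
        observed[r, feats] = False
    return MaskedDataset(values=values, observed=observed)


def two_blob_dataset(
    rng: np.random.Generator, per_blob: int = 10, separation: float = 30.0
) -> tuple[MaskedDataset, np.ndarray]:
    a = rng.normal(size=(per_blob, 2))
    b = rng.normal(size=(per_blob, 2)) + np.array([separation, 0.0])
    values = np.vstack([a, b])
    labels = np.repeat([1, 2], per_blob)
    return (
        MaskedDataset(values=values, observed=np.ones_like(values, dtype=bool)),
        labels,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
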