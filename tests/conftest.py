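"""Shared fixtures: small random read sets built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from metasig.sequence_io import ReadSet

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_reads(
    rng: np.random.Generator,
    n_reads: int,
    length: int,
    base_probs=None,
    n_rate: float = 0.0,
) -> list[str]:
    """Generate iid reads; optionally sprinkle N at the given per-base rate."""
    p = np.asarray(base_probs) if base_probs is not None else np.full(4, 0.25)
    codes = rng.choice(4, size=(n_reads, length), p=p / p.sum())
    chars = BASES[codes]
    if n_rate > 0:
        mask = rng.random((n_reads, length)) < n_rate
        chars = np.where(mask, ord("N"), chars).astype(np.uint8)
    return [row.tobytes().decode("ascii") for row in chars]


def random_readset(seed: int, n_reads: int = 60, length: int = 50, **kw) -> ReadSet:
    rng = np.random.default_rng(seed)
    return ReadSet(sample_id=f"rand{seed}", reads=random_reads(rng, n_reads, length, **kw))


@pytest.fixture
def small_readset() -> ReadSet:
    return random_readset(7, n_reads=40, length=60)


@pytest.fixture
def readset_pair() -> tuple[ReadSet, ReadSet]:
    a = random_readset(11, base_probs=[0.4, 0.1, 0.1, 0.4])
    b = random_readset(12, base_probs=[0.15, 0.35, 0.35, 0.15])
    b.sample_id = "rand12"
    return a, b
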