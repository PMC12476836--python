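"""Shared builders for in-memory prediction records and tiny structures."""

from __future__ import annotations

import numpy as np
import pytest

from slimpae import ChainPartition, PredictionRecord


def make_record(
    pae: np.ndarray,
    chain_lengths=(2, 2),
    chain_ids=("A", "B"),
    plddt=None,
    ptm: float = 0.5,
    iptm: float = 0.5,
    record_id: str = "rec",
    max_pae: float = 31.75,
) -> PredictionRecord:
    pae = np.asarray(pae, dtype=float)
    L = sum(chain_lengths)
    if plddt is None:
        plddt = np.full(L, 70.0)
    return PredictionRecord(
        record_id=record_id,
        partition=ChainPartition(tuple(chain_ids), tuple(chain_lengths)),
        pae=pae,
        plddt=np.asarray(plddt, dtype=float),
        ptm=ptm,
        iptm=iptm,
        max_pae=max_pae,
    )


def record_with_candidate_profile(
    values, bait_len: int = 10, background: float = 30.0
) -> PredictionRecord:
    """A two-chain record whose candidate-chain min-inter-PAE profile equals
    ``values`` exactly (each candidate row carries its value against one bait
    column; every other inter cell sits at ``background``)."""
    values = np.asarray(values, dtype=float)
    assert np.all(values <= background)
    nc = len(values)
    L = bait_len + nc
    pae = np.full((L, L), background)
    pae[:bait_len, :bait_len] = 1.0
    pae[bait_len:, bait_len:] = 1.0
    for r, v in enumerate(values):
        pae[bait_len + r, 0] = v
    return make_record(pae, chain_lengths=(bait_len, nc))


def random_record(
    rng: np.random.Generator, bait_len: int, cand_len: int
) -> PredictionRecord:
    L = bait_len + cand_len
    pae = rng.uniform(0.2, 31.75, (L, L))
    plddt = rng.uniform(20, 100, L)
    return make_record(
        pae, chain_lengths=(bait_len, cand_len), plddt=plddt,
        ptm=float(rng.uniform()), iptm=float(rng.uniform()),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
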