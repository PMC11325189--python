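"""Shared fixtures: synthetic superfamilies at the standard study conditions.

The heavy planted-superfamily runs are session-scoped so the protocol
tests and the end-to-end acceptance checks share one computation.
"""

from __future__ import annotations

import pytest

from funfamkit.protocols import ProtocolConfig, run_single
from funfamkit.synthetic_data import SimConfig, generate_embeddings, generate_superfamily

#: Fixed seed for the planted-superfamily study conditions.
PLANTED_SEED = 7

#: The standard end-to-end fixture: 6 families x 40 sequences of length 80,
#: 3 planted SDP columns, 3% within-family mutation, embedding spread ratio 6.
PLANTED_CONFIG = SimConfig(
    n_families=6,
    seqs_per_family=40,
    seq_length=80,
    n_sdp=3,
    mutation_rate=0.03,
    between_sd=6.0,
    within_sd=1.0,
    seed=PLANTED_SEED,
)

#: Small, fast variant for determinism and CLI tests.
SMALL_CONFIG = SimConfig(
    n_families=3,
    seqs_per_family=8,
    seq_length=60,
    n_sdp=2,
    mutation_rate=0.03,
    embed_dim=8,
    seed=11,
)


def make_dataset(config: SimConfig):
    seqs, annotations, truth = generate_superfamily(config)
    vectors = {v.seq_id: v for v in generate_embeddings(truth, config)}
    return seqs, annotations, truth, vectors


@pytest.fixture(scope="session")
def planted():
    """(seqs, annotations, truth, vectors) at the standard conditions."""
    return make_dataset(PLANTED_CONFIG)


@pytest.fixture(scope="session")
def planted_single_run(planted):
    """Single-pass protocol result on the standard planted fixture."""
    seqs, annotations, truth, vectors = planted
    return run_single(seqs, annotations, vectors, ProtocolConfig(seed=PLANTED_SEED))


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(SMALL_CONFIG)
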