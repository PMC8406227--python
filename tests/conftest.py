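"""Shared fixtures: a small deterministic synthetic community and helpers."""

import numpy as np
import pytest

import lithoscreen as ls


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(seq: str, positions: list[int]) -> str:
    """Substitute a different base at each given position (deterministic)."""
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


@pytest.fixture(scope="session")
def community():
    """Separable default community, seed 7 (session-scoped: generation is costly)."""
    params = ls.GeneratorParams(seed=7)
    com = ls.make_community(params)
    table = ls.sample_counts(com, params)
    return params, com, table


@pytest.fixture(scope="session")
def calls(community):
    params, com, table = community
    seqs = {a.id: a for a in com.asvs}
    return ls.classify_table(table, seqs, com.controls, com.whitelist, com.environment)
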