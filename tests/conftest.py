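"""Shared fixtures: seeded sequences and a small synthetic cohort."""

import numpy as np
import pytest

from nrscout.simulate import CohortSpec, generate_cohort


def rand_seq(n: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    flip = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = flip[out[i]][rng.integers(0, 3)]
    return "".join(out)


SMALL_SPEC = CohortSpec(
    reference_length=400_000,
    n_assemblies=2,
    n_insertions=6,
    n_alternates=4,
    n_decoys=3,
    n_contaminants=2,
    n_gaps=1,
    n_alu=10,
    n_l1=1,
    n_simple_repeats=8,
    n_genes=5,
    n_rna_samples=2,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort shared across tests (deterministic, seed 1)."""
    return generate_cohort(SMALL_SPEC, seed=1)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    from nrscout.pipeline import run_pipeline

    return run_pipeline(small_cohort)
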