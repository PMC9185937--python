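"""Shared fixtures: small planted genomes and read mixtures."""

import numpy as np
import pytest

import mitoforms as mf
from mitoforms.conformations import Conformation, apply_recombination


@pytest.fixture(scope="session")
def planted_genome():
    """20 kb circle with one exact 150 bp direct repeat pair (plus truth)."""
    spec = mf.SimulationSpec(
        seed=101,
        genome_length=20_000,
        gc=0.44,
        repeat_plan=[mf.RepeatPlan(150, 100.0, "direct", 4_000, 12_000)],
    )
    circle, manifest = mf.generate_genome(spec)
    return circle, manifest


@pytest.fixture(scope="session")
def fission_mixture(planted_genome):
    """Master + its two fission products, with the ground-truth pair."""
    circle, manifest = planted_genome
    pair = mf.repeat_pairs_from_manifest(circle, manifest)[0]
    master = Conformation(circles=(circle,))
    split = apply_recombination(master, pair)
    return circle, pair, master, split


def random_circle(seed: int, length: int = 2_000, gc: float = 0.45) -> mf.CircularSequence:
    rng = np.random.default_rng(seed)
    return mf.CircularSequence(f"rand{seed}", mf.random_sequence(length, gc, rng))
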