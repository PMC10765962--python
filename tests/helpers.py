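"""Shared test utilities: parsing shortcuts and the seeded, stratified
random-instance generator used by the oracle-equivalence suites."""

from __future__ import annotations

import random

import sigmak as sk


def genome(text: str) -> sk.Genome:
    return sk.parse_genomes(text)[0]


def stratified_config(seed: int) -> sk.GeneratorConfig:
    """Deterministic instance parameters stratified over circular-only,
    linear-only and mixed genomes, sized so that a* <= 9."""
    rng = random.Random(seed)
    mode = seed % 3
    nf = rng.randint(4, 9)
    if mode == 0:
        nlin, ncirc = 0, rng.randint(1, 2)
    elif mode == 1:
        nlin, ncirc = rng.randint(1, 3), 0
    else:
        nlin, ncirc = rng.randint(1, 2), rng.randint(1, 2)
    nlin = min(nlin, nf - ncirc)
    return sk.GeneratorConfig(nf, nlin, ncirc, n_dcj=rng.randint(0, 8), seed=seed)


def random_pair(seed: int):
    return sk.random_instance(stratified_config(seed))


# Worked examples used throughout the suite: a canonical singular pair and a
# singular-vs-duplicated pair
PAIR_A = "(1 -3 2) [4]"
PAIR_B = "(1 2) [3 -4]"
WGD_S = "[1 2 3]"
WGD_D = "[1 2 -3 1] [-3 2]"
TRIPLET_S = "(1 2 3)"
TRIPLET_D_SATURATED = "(1) (1) (2) (2) (3) (3)"
TRIPLET_D_UNSATURATED = "(1) (2) (2) (3) (3) [1]"
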