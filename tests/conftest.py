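import random

import pytest

from mlrules.core import Solution, Species

# names/arity pool used by the random nested-state generators
_NAMES = [("A", 0), ("B", 0), ("C", 1), ("D", 2)]


def random_species(rng: random.Random, depth: int) -> Species:
    name, arity = rng.choice(_NAMES)
    attrs = tuple(rng.choice([0, 1, 2, "P", True, 1.5]) for _ in range(arity))
    if depth > 0 and rng.random() < 0.5:
        return Species(name, attrs, random_solution(rng, depth - 1))
    return Species(name, attrs)


def random_solution(rng: random.Random, depth: int,
                    max_pops: int = 4) -> Solution:
    pops = []
    for _ in range(rng.randint(0, max_pops)):
        pops.append((random_species(rng, depth), rng.randint(1, 3)))
    return Solution(pops)


@pytest.fixture
def rng():
    return random.Random(20260201)
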