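from __future__ import annotations

import numpy as np
import pytest

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.45) -> str:
    at = (1 - gc) / 2
    g = gc / 2
    return "".join(rng.choice(BASES, size=n, p=[at, g, g, at]))


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def make_seq(rng):
    def _make(n: int, gc: float = 0.45) -> str:
        return random_seq(rng, n, gc)

    return _make
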