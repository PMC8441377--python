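"""Shared fixtures: a synthetic amplicon design mimicking a pooled 3x3
dual-guide experiment (three upstream and three downstream cut sites flanking
a central target region)."""

import numpy as np
import pytest

from ampdel import AmpliconReference, Guide, GuidePair, make_pairs


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def amplicon() -> AmpliconReference:
    return AmpliconReference("amp1", random_dna(2500, seed=20260101))


@pytest.fixture(scope="session")
def guides() -> list[Guide]:
    us = [Guide(f"US-{i+1}", "upstream", c) for i, c in enumerate([600, 700, 800])]
    ds = [Guide(f"DS-{i+1}", "downstream", c) for i, c in enumerate([1600, 1700, 1800])]
    return us + ds


@pytest.fixture(scope="session")
def pairs(guides) -> list[GuidePair]:
    return make_pairs(guides)


@pytest.fixture(scope="session")
def pair_33(pairs) -> GuidePair:
    return next(p for p in pairs if p.pair_id == "US-3/DS-3")
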