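import numpy as np
import pytest

from loopquant import simulate as sim


@pytest.fixture(scope="session")
def small_locus() -> sim.DiploidLocus:
    """A 40 kb diploid locus shared across tests (cheap to build, seeded)."""
    return sim.make_diploid_locus(sim.LocusConfig(seed=11, length=40_000, target_offset=10_000, target_width=2_000))


@pytest.fixture(scope="session")
def default_locus() -> sim.DiploidLocus:
    """The default 120 kb locus used by end-to-end 4C tests."""
    return sim.make_diploid_locus(sim.LocusConfig(seed=11))


@pytest.fixture(scope="session")
def default_viewpoint(default_locus):
    return sim.design_viewpoint(default_locus)


def brute_force_digest(seq: str, primary: str, secondary: str):
    """Independent oracle: character-by-character digest of a sequence.

    Returns a list of (start, end, valid) tuples; used to validate
    build_fragment_map without sharing any scanning code with it.
    """
    n = len(seq)
    cut_positions = []
    for i in range(n - len(primary) + 1):
        if seq[i : i + len(primary)] == primary:
            cut_positions.append(i)
    bounds = [0]
    for c in cut_positions:
        if c != 0:
            bounds.append(c)
    bounds.append(n)
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        valid = False
        for i in range(s, e - len(secondary) + 1):
            if seq[i : i + len(secondary)] == secondary:
                valid = True
                break
        out.append((s, e, valid))
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
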