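import numpy as np
import pytest

from fpdenovo.motif_model import Motif

# seeds of mutually distant random 10-bp motifs (pairwise distance >= 0.65)
DISTANT_MOTIF_SEEDS = [0, 2, 22, 120, 1452]


def onehot_motif(consensus: str, nsites: float = 10.0, name: str | None = None) -> Motif:
    counts = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = nsites
    return Motif(counts, nsites=nsites, name=name or consensus)


def strong_motif(name: str, w: int, seed: int, dominant: float = 17.0) -> Motif:
    """Random informative motif: one dominant base per column."""
    rng = np.random.default_rng(seed)
    counts = np.full((4, w), 1.0)
    for j in range(w):
        counts[rng.integers(0, 4), j] = dominant
    return Motif(counts, nsites=dominant + 3.0, name=name)


def random_motif(width: int, rng: np.random.Generator, nsites: float = 20.0) -> Motif:
    counts = rng.random((4, width)) * nsites + 0.1
    return Motif(counts, nsites=nsites, name=f"rand{rng.integers(1 << 30)}")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
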