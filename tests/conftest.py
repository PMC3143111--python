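import numpy as np
import pytest

from coopmod.network import WpiNetwork, assemble_wpi
from coopmod.scoring import Seed


@pytest.fixture
def t1_network() -> WpiNetwork:
    """Six-gene toy network with a bridging hub.

    Protein edges s-a, t-a, s-b, a-b, c-d; weights chosen so gene a is a
    heavy bridge between s and t and gene b a lighter exclusive partner
    of s.  Used for all hand-traced score values.
    """
    ppi = [("s", "a"), ("t", "a"), ("s", "b"), ("a", "b"), ("c", "d")]
    weights = {"s": 1, "t": 1, "a": 5, "b": 2, "c": 0, "d": 3}
    return assemble_wpi(ppi, [], weights)


@pytest.fixture
def t1_seed(t1_network) -> Seed:
    from coopmod.scoring import consistency_score

    return Seed("s", "t", consistency_score(t1_network, ["s"], ["t"]))


def random_wpi(rng: np.random.Generator, n_genes: int,
               ppi_prob: float = 0.25, reg_prob: float = 0.08,
               max_weight: int = 6) -> WpiNetwork:
    """Small random network with both edge kinds and random integer weights."""
    genes = [f"g{i:02d}" for i in range(n_genes)]
    ppi = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if rng.random() < ppi_prob
    ]
    reg = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(n_genes)
        if i != j and rng.random() < reg_prob
    ]
    if not ppi and not reg:
        ppi = [(genes[0], genes[1])]
    weights = {g: int(rng.integers(0, max_weight + 1)) for g in genes}
    return assemble_wpi(ppi, reg, weights, extra_genes=genes)
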