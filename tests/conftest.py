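import numpy as np
import pandas as pd
import pytest

from magicwas.simulate import (FounderPanel, GeneticMap, RILPopulation,
                               funnel_cross, simulate_founders)


@pytest.fixture(scope="session")
def small_panel() -> FounderPanel:
    return simulate_founders(400, None, 0.55, seed=42)


@pytest.fixture(scope="session")
def small_pop(small_panel) -> RILPopulation:
    return funnel_cross(small_panel, 200, selfing_gens=4, seed=43)


def make_map(n: int, chrom: str = "1A", cm_len: float = 100.0,
             bp_len: int = 1_000_000) -> GeneticMap:
    """Evenly spaced single-chromosome map for hand fixtures."""
    bp = np.linspace(1, bp_len, n).astype(int)
    cm = np.linspace(0, cm_len, n)
    df = pd.DataFrame({"chrom": chrom, "bp": bp, "cM": cm},
                      index=[f"S{i:05d}" for i in range(n)])
    return GeneticMap(df)


def panel_from_strings(haplos: list[str], gmap: GeneticMap | None = None,
                       names=None) -> FounderPanel:
    """Founder panel from one allele string per founder (hand fixtures)."""
    g = np.array([list(h) for h in haplos], dtype="<U1")
    gmap = gmap or make_map(g.shape[1])
    names = tuple(names or [f"F{i + 1}" for i in range(len(haplos))])
    return FounderPanel(names, g, gmap)


def pop_from_strings(genos: list[list[str]], gmap: GeneticMap | None = None
                     ) -> RILPopulation:
    """Population from per-line lists of two-character genotype strings."""
    g = np.array(genos, dtype="<U2")
    gmap = gmap or make_map(g.shape[1])
    return RILPopulation([f"L{i + 1}" for i in range(len(genos))], g, gmap)
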