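import numpy as np
import pytest

from mscrate.simulate import (
    GeneGenealogy,
    LocusAlignment,
    SpeciesTreeParams,
)
from mscrate.substitution import SubstitutionModel


@pytest.fixture(scope="session")
def jc69_model() -> SubstitutionModel:
    return SubstitutionModel()


@pytest.fixture(scope="session")
def clock_true_params() -> SpeciesTreeParams:
    """Zero-theta species tree: genealogies are exactly ultrametric with
    Homo-Pan, Homo-Gorilla and Homo-Pongo heights 0.00625/0.008/0.013."""
    return SpeciesTreeParams(
        tau_hc=0.00625, tau_hcg=0.008, tau_root=0.013,
        theta_hc=0.0, theta_hcg=0.0, theta_root=0.0,
    )


def clock_newick(h1: float, h2: float, h3: float) -> str:
    """Ultrametric 4-taxon newick with the species-tree topology."""
    return (
        f"(((Homo:{h1},Pan:{h1}):{h2 - h1},Gorilla:{h2}):{h3 - h2},"
        f"Pongo:{h3});"
    )


def genealogy_from_heights(h1: float, h2: float, h3: float) -> GeneGenealogy:
    return GeneGenealogy(
        locus_id="manual",
        newick=clock_newick(h1, h2, h3),
        t_hc=h1,
        t_hcg=h2,
        t_root=h3,
        hc_sister=True,
    )


def alignment_with_mismatches(x: int, n: int) -> LocusAlignment:
    """4-taxon alignment where Homo and Pan differ at exactly x of n sites
    and Gorilla/Pongo copy Pan."""
    codes = np.zeros((4, n), dtype=np.int8)
    codes[0, :x] = 1  # Homo differs at the first x sites
    return LocusAlignment(
        locus_id="synthetic", taxa=("Homo", "Pan", "Gorilla", "Pongo"), codes=codes
    )
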