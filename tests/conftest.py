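import numpy as np
import pandas as pd
import pytest

from pairomics.io import SampleDesign
from pairomics.taxonomy import TaxonomyTree


def make_design(n_pairs: int) -> SampleDesign:
    mouse, site = {}, {}
    for i in range(1, n_pairs + 1):
        mouse[f"M{i}_CC"] = f"M{i}"
        site[f"M{i}_CC"] = "CC"
        mouse[f"M{i}_F"] = f"M{i}"
        site[f"M{i}_F"] = "F"
    return SampleDesign(mouse=mouse, site=site)


@pytest.fixture
def design3() -> SampleDesign:
    return make_design(3)


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    """Two phyla under one domain; genus g1 holds species s1, s2; the
    second phylum holds species s3."""
    parent = {
        "root": "root",
        "p1": "root", "p2": "root",
        "c1": "p1",
        "o1": "c1",
        "f1": "o1",
        "g1": "f1",
        "s1": "g1", "s2": "g1",
        "c2": "p2", "o2": "c2", "f2": "o2", "g2": "f2", "s3": "g2",
    }
    rank = {
        "root": "domain",
        "p1": "phylum", "p2": "phylum",
        "c1": "class", "c2": "class",
        "o1": "order", "o2": "order",
        "f1": "family", "f2": "family",
        "g1": "genus", "g2": "genus",
        "s1": "species", "s2": "species", "s3": "species",
    }
    return TaxonomyTree(parent, rank)


@pytest.fixture
def toy_matrix(design3):
    """3-pair matrix with deterministic small counts."""
    from pairomics.io import PairedCountMatrix

    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(8, 6)),
        index=[f"f{i}" for i in range(8)],
        columns=design3.samples,
    )
    return PairedCountMatrix(counts, design3)
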