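import numpy as np
import pandas as pd
import pytest

from satay.fitness import NormalizedMatrix
from satay.models import GeneModel, InsertionSite, LibraryMeta
from satay.synthetic import SimulationConfig, default_design, simulate_experiment


@pytest.fixture(scope="session")
def small_screen():
    """A small all-neutral 24-library screen shared across tests."""
    cfg = SimulationConfig(n_genes=80, insertions_per_library=8000, seed=42)
    return simulate_experiment(cfg, design=default_design())


@pytest.fixture
def toy_genes():
    return [
        GeneModel(gene_id="geneA", chrom="chrI", start=100, end=200),
        GeneModel(gene_id="geneB", chrom="chrI", start=150, end=400),  # overlaps geneA
        GeneModel(gene_id="geneC", chrom="chrII", start=0, end=300),
    ]


def make_sites(rows, library="L1"):
    return [
        InsertionSite(chrom=c, pos=p, strand=s, reads=r, library=library)
        for c, p, s, r in rows
    ]


@pytest.fixture
def norm_from_values():
    """Wrap a plain gene x library value matrix as a NormalizedMatrix."""

    def _build(values: pd.DataFrame, pseudocount: float = 1.0) -> NormalizedMatrix:
        libs = [LibraryMeta(library=c) for c in values.columns]
        return NormalizedMatrix(values=values.astype(float), source="tn",
                                pseudocount=pseudocount, libraries=libs)

    return _build
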