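from __future__ import annotations

import numpy as np
import pytest

import allelemine as am
from allelemine.gene_model import GeneModel


@pytest.fixture(scope="session")
def small_series():
    """Reference + paralogs + 6-allele series with truth, aligned."""
    cfg = am.SimulationConfig(seed=11, n_alleles=6, n_paralogs=2)
    ref, paras, alleles, truth = am.simulate_series(cfg)
    aln = am.align_near_identical([ref] + alleles + paras)
    return ref, paras, alleles, truth, aln


@pytest.fixture(scope="session")
def default_model():
    return am.default_gene_model()


@pytest.fixture(scope="session")
def default_domains():
    return am.default_domain_map()


def single_exon_model(length: int) -> GeneModel:
    """Trivial gene model: one exon covering the whole sequence."""
    assert length % 3 == 0
    return GeneModel(exons=[(1, length)])


def trivial_alignment(rows: dict[str, str], ref_id: str) -> am.AlleleAlignment:
    return am.AlleleAlignment(rows=list(rows.items()), ref_id=ref_id)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
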