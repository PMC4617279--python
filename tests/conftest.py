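"""Shared fixtures: tiny simulated samples and hand-built toy references."""

import numpy as np
import pytest

from circdetect import synthetic_data as sim
from circdetect import workflow
from circdetect.io_formats import GeneModel, Genome, Transcript


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small error-free study: 6 genes, 3 circles, 3k reads."""
    return sim.SimConfig(n_genes=6, depth=3000, seed=7, rrna_fraction=0.1)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    genome, models = sim.build_genome(tiny_cfg)
    rrna = sim.build_rrna(tiny_cfg)
    reads, truth = sim.simulate_reads(genome, models, tiny_cfg, rrna)
    return {"cfg": tiny_cfg, "genome": genome, "models": models, "rrna": rrna,
            "reads": reads, "truth": truth}


@pytest.fixture(scope="session")
def tiny_run(tiny_sim):
    """Full pipeline result over the tiny sample."""
    res = workflow.run_pipeline(
        tiny_sim["reads"], tiny_sim["genome"], tiny_sim["models"], tiny_sim["rrna"],
        sample="tiny",
    )
    res.truth = tiny_sim["truth"]
    return res


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_gene(gene_id, contig, strand, exons, biotype="protein_coding", cds=None):
    tx = Transcript(f"t_{gene_id}", list(exons), list(cds or []))
    return GeneModel(gene_id, gene_id.upper(), biotype, strand, contig, [tx])
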