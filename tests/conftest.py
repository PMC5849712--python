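import pytest

from ecas_splice.annotation_model import Annotation, ExonInterval, GeneModel
from ecas_splice.synthetic_data import SimulationConfig, simulate_dataset


def make_gene(
    gene_id="g1",
    contig="c1",
    strand="+",
    exons=((1, 100), (201, 300), (401, 500)),
    cds=(10, 490),
):
    return GeneModel(
        gene_id=gene_id,
        contig_id=contig,
        strand=strand,
        exons=[ExonInterval(contig, s, e) for s, e in exons],
        cds_start=cds[0],
        cds_end=cds[1],
        model_id=f"{gene_id}.1",
    )


@pytest.fixture
def three_exon_gene():
    """'+' gene: exons [1..100],[201..300],[401..500], CDS [10..490]."""
    return make_gene()


@pytest.fixture
def toy_annotation(three_exon_gene):
    return Annotation(genes={"g1": three_exon_gene}, contigs={"c1": "A" * 600})


@pytest.fixture(scope="session")
def small_dataset():
    """Shared 60-gene, 4-species simulation (noise off, in-memory evidence)."""
    return simulate_dataset(SimulationConfig(seed=11, n_genes=60))


@pytest.fixture(scope="session")
def noisy_dataset_dir(tmp_path_factory):
    """40-gene simulation with noise junctions, written to disk (SAM + TSV)."""
    outdir = tmp_path_factory.mktemp("noisy_sim")
    dataset = simulate_dataset(
        SimulationConfig(seed=21, n_genes=40, noise_junction_rate=0.25), outdir
    )
    return outdir, dataset
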