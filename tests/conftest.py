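import pytest

from eploops.pipeline import PipelineConfig, run_all
from eploops.simulate import GroundTruth, SimConfig, simulate


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """The default synthetic dataset (seed 0), generated once per session."""
    outdir = tmp_path_factory.mktemp("sim_default")
    simulate(SimConfig(seed=0), outdir)
    return outdir


@pytest.fixture(scope="session")
def ground_truth(sim_dir) -> GroundTruth:
    return GroundTruth.load(sim_dir / "ground_truth.json")


@pytest.fixture(scope="session")
def pipeline_out(tmp_path_factory, sim_dir):
    """Full pipeline run on the default synthetic dataset."""
    outdir = tmp_path_factory.mktemp("pipeline_default")
    config = PipelineConfig(
        outdir=str(outdir),
        seed=0,
        genome_fa=str(sim_dir / "genome.fa"),
        gtf=str(sim_dir / "genes.gtf"),
        loops_bedpe=str(sim_dir / "loops.bedpe"),
        tf_peaks=str(sim_dir / "tf_peaks.narrowPeak"),
        k27ac_peaks=str(sim_dir / "k27ac_peaks.broadPeak"),
        tracks_dir=str(sim_dir / "tracks"),
        external_enhancers=str(sim_dir / "external_enhancers.bed"),
        de_table=str(sim_dir / "de_table.tsv"),
        tf_list=str(sim_dir / "tf_list.txt"),
        subtype_expr=str(sim_dir / "subtype_expr.tsv"),
        subtype_labels=str(sim_dir / "subtype_labels.tsv"),
        cell_expr=str(sim_dir / "cell_expr.tsv"),
        gene_sets=str(sim_dir / "gene_sets.gmt"),
        matrix_rep1=str(sim_dir / "matrix_rep1.txt"),
        matrix_rep2=str(sim_dir / "matrix_rep2.txt"),
    )
    run_all(config)
    return outdir


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """A reduced layout for tests that re-run the generator."""
    return SimConfig(
        seed=7,
        n_chroms=2,
        chrom_len=2_000_000,
        n_genes=40,
        n_loops=200,
        n_planted_ep_genes=10,
        n_subtypes=6,
        n_samples_per_subtype=4,
        n_specific_genes=5,
        n_cells=60,
        n_expr_genes=120,
        n_decoy_tf_peaks=10,
        n_typical_enhancer_domains=8,
        n_super_enhancer_domains=2,
    )
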