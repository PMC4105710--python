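import pytest

from pacall.pipeline import PipelineConfig, run_all
from pacall.synthetic import generate_dataset


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default synthetic dataset (20 genes, 50 PA sites, depth 50, ±2 nt
    wobble, 10% decoy reads, seed 42) written to disk once per session."""
    d = tmp_path_factory.mktemp("fixture")
    ds = generate_dataset(outdir=d, seed=42)
    return d, ds


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    """Full pipeline run over the default fixture."""
    d, ds = fixture_dir
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = PipelineConfig(
        reads=str(d / "reads.fastq"),
        alignment=str(d / "truth.sam"),
        genome=str(d / "genome.fa"),
        gene_models=str(d / "genes.gff3"),
        mirna_sites=str(d / "mirna_sites.bed"),
        outdir=str(out),
    )
    return run_all(cfg), ds


def match_clusters_to_truth(clusters, truth, tol=2):
    """Map each non-decoy truth site to clusters whose mode is within tol."""
    matches = {}
    for t in truth:
        if t.decoy:
            continue
        matches[t.site_id] = [
            c
            for c in clusters
            if c.chrom == t.chrom
            and c.strand == t.strand
            and abs(c.mode_coord - t.coord) <= tol
        ]
    return matches
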