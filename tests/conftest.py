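import pytest

from spotrna import PipelineConfig, SimulationSpec, run_pipeline, simulate_dataset
from spotrna.read_structure import ReadLayout, Segment

FIXTURE_SEED = 20240901


def make_config(ds, outdir, **overrides) -> PipelineConfig:
    cfg = PipelineConfig(
        outdir=str(outdir),
        fastq_r1=ds.paths["fastq_r1"],
        fastq_r2=ds.paths["fastq_r2"],
        sam=ds.paths["sam"],
        annotation_sources=[
            [ds.paths["genes_gtf"], "gencode"],
            [ds.paths["smallrna_gtf"], "gtf"],
            [ds.paths["spurious_bed"], "bed6"],
        ],
        whitelist_a=ds.paths["whitelist_a"],
        whitelist_b=ds.paths["whitelist_b"],
        layout=ds.layout,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """Standard zero-error synthetic dataset (2 chroms x 100 kb, 20 genes,
    10 miRNAs with arms, 16x16 grid, 5 UMIs per planted pair)."""
    root = tmp_path_factory.mktemp("sim")
    return simulate_dataset(SimulationSpec(seed=FIXTURE_SEED), root)


@pytest.fixture(scope="session")
def pipeline_run(fixture_dataset, tmp_path_factory):
    """Full pipeline run (with validation) over the standard dataset."""
    out = tmp_path_factory.mktemp("run")
    cfg = make_config(fixture_dataset, out)
    summaries = run_pipeline(cfg)
    return fixture_dataset, cfg, summaries


@pytest.fixture
def simple_layout() -> ReadLayout:
    """[barcode A: 8][linker ACGT: 4][barcode B: 8][umi: 6], flank 2."""
    return ReadLayout(
        segments=(
            Segment("barcode", 8, slot_id="A"),
            Segment("linker", 4, sequence="ACGT"),
            Segment("barcode", 8, slot_id="B"),
            Segment("umi", 6, slot_id="U"),
        ),
        flank=2,
        max_linker_mismatch=1,
    )
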