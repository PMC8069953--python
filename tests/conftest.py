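import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ba_graph():
    """A 1000-node scale-free interactome on the synthetic gene namespace."""
    from dmdnet.synthetic import generate_interactome

    return generate_interactome(1000, 3, seed=42)


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """One full synthetic input set plus a completed pipeline run."""
    from dmdnet.pipeline import PipelineConfig, run_pipeline
    from dmdnet.synthetic import write_synthetic_inputs

    root = tmp_path_factory.mktemp("fixture")
    indir, outdir = root / "inputs", root / "out"
    truth = write_synthetic_inputs(indir, seed=0)
    config = PipelineConfig(
        expression_studies=[
            [f"study{i}", str(indir / f"study{i}_expression.tsv"),
             str(indir / f"study{i}_design.tsv")]
            for i in (1, 2, 3)
        ],
        string_links=str(indir / "string_links.tsv"),
        gda_table=str(indir / "gda.tsv"),
        dgidb_table=str(indir / "dgidb.tsv"),
        drug_target_table=str(indir / "drug_targets.tsv"),
        signature_library=str(indir / "library.gmt"),
        outdir=str(outdir),
        lcc_permutations=1000,
        hub_degree=5,  # scaled to the 1000-node fixture network
        seed=0,
    )
    manifest = run_pipeline(config)
    return {"truth": truth, "config": config, "manifest": manifest,
            "indir": indir, "outdir": outdir}
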