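"""End-to-end orchestration: configuration, staging, logging, and manifest.

A :class:`PipelineConfig` names the input files and holds every threshold
with the analysis defaults (DEG calling at FDR < 0.05 and |ES| > 2,
interactome edges at combined score >= 700, GDA score > 0.01, hub degree
>= 20, 10,000 LCC permutations, 1,000 random lists for the degree null,
top 50 network-ranked drugs).  :func:`run_pipeline` executes
meta-analysis -> DEGs -> disease module (+ LCC significance) -> DIAMOnD ->
candidate selection -> the three drug engines, writing per-stage outputs
and a deterministic JSON manifest.  One global seed fans out to per-stage
seeds by fixed offsets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .anti_signature import read_signature_library, score_library
from .candidates import build_signature, select_predicted_candidates, select_seed_candidates
from .diamond import run_diamond
from .drug_enrichment import enrich_drugs, read_dgidb_table
from .drug_network import build_drug_gene_network, rank_drugs_by_degree_z
from .io import read_drug_target_table
from .meta import RandomEffectsMeta
from .network import extract_module, lcc_significance, read_gda_seeds, read_string_edges

__all__ = ["PipelineConfig", "PipelineInputError", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger("dmdnet.pipeline")

_SEED_OFFSETS = {"lcc": 1, "drug_network": 2}


class PipelineInputError(ValueError):
    """A referenced input file is missing or unreadable (CLI exit code 2)."""


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds, seed, and output directory of one run."""

    expression_studies: list[list[str]] = field(default_factory=list)  # [id, expr, design]
    string_links: str = ""
    gda_table: str = ""
    dgidb_table: str = ""
    drug_target_table: str = ""
    signature_library: str = ""
    outdir: str = "dmdnet_out"

    fdr_max: float = 0.05
    es_min: float = 2.0
    string_min_score: int = 700
    gda_min: float = 0.01
    hub_degree: int = 20
    lcc_permutations: int = 10000
    diamond_iters: int | None = None  # None = automatic: the DEG count
    n_random: int = 1000
    top_drugs: int = 50
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def input_paths(self) -> list[str]:
        paths = [p for (_sid, expr, design) in self.expression_studies for p in (expr, design)]
        paths += [
            p
            for p in (self.string_links, self.gda_table, self.dgidb_table,
                      self.drug_target_table, self.signature_library)
            if p
        ]
        return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise PipelineInputError(f"missing input files: {missing}")
    if not config.expression_studies:
        raise PipelineInputError("no expression studies configured")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "dmdnet",
        "version": __version__,
        "config": asdict(config),
        "seed_offsets": dict(_SEED_OFFSETS),
        "stages": {},
        "status": "running",
    }

    def finish(status: str, notice: str | None = None) -> dict:
        manifest["status"] = status
        if notice:
            manifest["notice"] = notice
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest

    def stage(name: str):
        def deco(fn):
            def wrapped(*args, **kwargs):
                logger.info("%s\tstart\t", name)
                try:
                    out = fn(*args, **kwargs)
                except Exception as exc:
                    logger.error("%s\tfailed\t%s", name, exc)
                    finish("failed", notice=f"stage {name} failed: {exc}")
                    raise PipelineStageError(name, exc) from exc
                logger.info("%s\tdone\t", name)
                return out
            return wrapped
        return deco

    # ---- meta-analysis -------------------------------------------------
    @stage("meta")
    def _meta():
        model = RandomEffectsMeta.from_files(
            [tuple(s) for s in config.expression_studies]
        )
        results = model.fit()
        results.to_tsv(outdir / "meta.tsv")
        degs = results.call_degs(fdr_max=config.fdr_max, es_min=config.es_min)
        manifest["stages"]["meta"] = {
            "n_genes": int(len(results.table)),
            "n_degs": len(degs),
            "n_up": len(degs.up),
            "n_down": len(degs.down),
        }
        return results, degs

    results, degs = _meta()

    # ---- disease module ------------------------------------------------
    @stage("module")
    def _module():
        net = read_string_edges(config.string_links, min_score=config.string_min_score)
        seeds = read_gda_seeds(config.gda_table, min_gda=config.gda_min)
        module = extract_module(net, seeds)
        sig = lcc_significance(
            net, module.mapped_genes, n_permutations=config.lcc_permutations,
            seed=config.seed + _SEED_OFFSETS["lcc"],
        )
        payload = sig.to_dict()
        payload.update(
            n_seeds=len(seeds), n_mapped=len(module.mapped_genes),
            n_induced_edges=module.n_induced_edges,
        )
        (outdir / "module.json").write_text(json.dumps(payload, indent=2) + "\n")
        manifest["stages"]["module"] = payload
        return net, seeds, module

    net, seeds, module = _module()

    # ---- DIAMOnD -------------------------------------------------------
    n_iter = config.diamond_iters if config.diamond_iters is not None else len(degs)
    if n_iter < 1:
        return finish(
            "halted",
            notice="empty signature: zero DEGs leave no DIAMOnD prefix or candidates",
        )

    @stage("diamond")
    def _diamond():
        ranking = run_diamond(net, module.mapped_genes, n_iterations=n_iter)
        ranking.to_tsv(outdir / "diamond.tsv")
        manifest["stages"]["diamond"] = {"n_iterations": n_iter, "n_ranked": len(ranking)}
        return ranking

    ranking = _diamond()

    # ---- candidate selection -------------------------------------------
    @stage("candidates")
    def _candidates():
        seed_cands = select_seed_candidates(degs, module, min_degree=config.hub_degree)
        predicted = select_predicted_candidates(
            degs, ranking, net, top_n=n_iter, min_degree=config.hub_degree
        )
        signature = build_signature(seed_cands, predicted.genes, results.table)
        signature.to_json(outdir / "signature.json")
        signature.to_gmt(outdir / "signature.gmt", name="disease_signature")
        manifest["stages"]["candidates"] = {
            "n_seed_candidates": len(seed_cands),
            "n_predicted_overlap": predicted.n_overlap,
            "n_predicted_candidates": len(predicted.genes),
            "n_signature": len(signature),
        }
        return seed_cands, predicted, signature

    seed_cands, predicted, signature = _candidates()
    if not signature.genes:
        return finish("halted", notice="empty signature: no candidate genes selected")

    background = set(results.table.index) & set(net.nodes)
    manifest["background_size"] = len(background)

    # ---- drug engines --------------------------------------------------
    if config.dgidb_table:
        @stage("drugs_enrich")
        def _enrich():
            records = read_dgidb_table(config.dgidb_table)
            table = enrich_drugs(
                records,
                candidate_genes=predicted.genes & background,
                background=background,
                signature=signature,
            )
            table.to_csv(outdir / "drugs_enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["drugs_enrich"] = {"n_drugs_tested": int(len(table))}
            return table

        _enrich()

    if config.drug_target_table:
        @stage("drugs_network")
        def _network():
            targets = read_drug_target_table(config.drug_target_table)
            bipartite = build_drug_gene_network(targets, signature.genes)
            bipartite.to_tsv(outdir / "drug_gene_edges.tsv")
            table = rank_drugs_by_degree_z(
                targets, signature.genes & background, background,
                n_random=config.n_random, seed=config.seed + _SEED_OFFSETS["drug_network"],
                top_k=config.top_drugs,
            )
            table.to_csv(outdir / "drugs_network.tsv", sep="\t", index=False)
            manifest["stages"]["drugs_network"] = {
                "n_edges": int(len(bipartite.edges)),
                "n_ranked": int(len(table)),
            }
            return table

        _network()

    if config.signature_library:
        @stage("drugs_antisig")
        def _antisig():
            library = read_signature_library(config.signature_library)
            universe = set(results.table.index)
            for sig in library:
                universe |= sig.genes
            table = score_library(signature, library, universe_size=len(universe))
            table.to_csv(outdir / "drugs_antisignature.tsv", sep="\t", index=False)
            manifest["stages"]["drugs_antisig"] = {"n_signatures": int(len(table))}
            return table

        _antisig()

    return finish("complete")
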