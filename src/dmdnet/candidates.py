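"""Candidate-gene selection and signature assembly.

Seed candidates are DEGs that fall inside the disease module and are hubs
there (degree >= 20 within the module's induced subgraph).  Predicted
candidates are DEGs among the top DIAMOnD-ranked genes that are hubs in the
full interactome.  Their union, with up/down directions taken from the
meta-analysis, forms the disease signature consumed by the drug engines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .diamond import DiamondRanking
from .network import DiseaseModule, find_hubs
from .signature import GeneSignature
from .stats import hypergeom_tail

__all__ = [
    "select_seed_candidates",
    "PredictedCandidates",
    "select_predicted_candidates",
    "build_signature",
    "overlap_significance",
]

logger = logging.getLogger("dmdnet.candidates")


def select_seed_candidates(degs: GeneSignature, module: DiseaseModule,
                           min_degree: int = 20) -> set[str]:
    """DEGs inside the disease module that are hubs of the module subgraph."""
    overlap = degs.genes & module.mapped_genes
    logger.info("candidates\tdeg_module_overlap\t%d", len(overlap))
    if not overlap:
        return set()
    return find_hubs(overlap, module, min_degree=min_degree)


@dataclass
class PredictedCandidates:
    """Predicted candidate genes plus the pre-hub-filter overlap size."""

    genes: set[str]
    n_overlap: int


def select_predicted_candidates(degs: GeneSignature, ranking: DiamondRanking,
                                net: nx.Graph, top_n: int | None = None,
                                min_degree: int = 20) -> PredictedCandidates:
    """DEGs among the top ``top_n`` DIAMOnD genes that are interactome hubs.

    ``top_n`` defaults to the DEG count (the ranking prefix mirrors the
    signature size).  A ranking shorter than ``top_n`` is used in full with
    a logged notice.
    """
    if top_n is None:
        top_n = len(degs)
    if top_n < 0:
        raise ValueError("top_n must be >= 0")
    if len(ranking) < top_n:
        logger.info("candidates\tranking_exhausted\t%d < %d", len(ranking), top_n)
    prefix = set(ranking.top(top_n))
    overlap = degs.genes & prefix
    hubs = find_hubs(overlap, net, min_degree=min_degree) if overlap else set()
    logger.info("candidates\tdeg_prefix_overlap\t%d hubs %d", len(overlap), len(hubs))
    return PredictedCandidates(genes=hubs, n_overlap=len(overlap))


def build_signature(seed_cands: set[str], predicted_cands: set[str],
                    meta_table: pd.DataFrame) -> GeneSignature:
    """Assemble the disease signature with provenance tags and directions.

    Directions come from the meta-analysis ``combined_es`` sign; a candidate
    absent from the table raises an error naming the gene.  Genes in both
    candidate sets keep the ``seed_candidate`` tag (logged).
    """
    both = set(seed_cands) & set(predicted_cands)
    if both:
        logger.info("candidates\tin_both_sets_tagged_seed\t%d", len(both))
    provenance = {g: "predicted_candidate" for g in predicted_cands}
    provenance.update({g: "seed_candidate" for g in seed_cands})

    up: set[str] = set()
    down: set[str] = set()
    for gene in provenance:
        if gene not in meta_table.index:
            raise ValueError(f"candidate gene {gene!r} absent from the meta-analysis table")
        if float(meta_table.loc[gene, "combined_es"]) >= 0:
            up.add(gene)
        else:
            down.add(gene)
    return GeneSignature(up=up, down=down, provenance=provenance)


def overlap_significance(set_a: set[str], set_b: set[str],
                         background: set[str]) -> tuple[float, float]:
    """Fraction of ``set_a`` falling in ``set_b`` and its hypergeometric tail p.

    Both sets must lie within ``background``; the p-value is
    ``P(X >= |a & b|)`` for |a| draws from |background| containing |b|
    marked genes.
    """
    set_a, set_b, background = set(set_a), set(set_b), set(background)
    if not set_a:
        raise ValueError("set_a is empty; overlap fraction undefined")
    if not (set_a <= background and set_b <= background):
        raise ValueError("set_a and set_b must be subsets of the background")
    inter = len(set_a & set_b)
    fraction = inter / len(set_a)
    p = hypergeom_tail(len(background), len(set_b), len(set_a), inter)
    return fraction, p
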