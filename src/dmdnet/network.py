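"""Interactome construction, disease-module extraction, and LCC significance.

The protein--protein interaction network is read from a STRING-style
protein-links file (combined scores on a 0--1000 scale; edges kept at
score >= 700, the high-confidence threshold).  Disease seed genes come from
a DisGeNET-style gene--disease association table (GDA score strictly > 0.01).
The disease module is the subgraph induced by the mapped seeds; its largest
connected component (LCC) is compared against LCC sizes of uniformly
resampled node sets of the same size to obtain a z-score and an empirical
p-value with add-one correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "read_string_edges",
    "read_gda_seeds",
    "DiseaseModule",
    "extract_module",
    "find_hubs",
    "ModuleSignificance",
    "lcc_significance",
]

logger = logging.getLogger("dmdnet.network")


def read_string_edges(path: str | Path, min_score: int = 700,
                      aliases: str | Path | None = None) -> nx.Graph:
    """Read a STRING-style protein-links file into an undirected simple graph.

    The file is whitespace-separated with columns ``protein1 protein2
    combined_score`` (integer 0--1000) and an optional header.  Rows with
    ``combined_score >= min_score`` are kept (0.7 corresponds to 700);
    reciprocal duplicates collapse to one undirected edge and self-loops are
    dropped with a logged count.  ``aliases`` optionally maps protein
    identifiers to gene symbols via a two-column file.
    """
    alias_map: dict[str, str] = {}
    if aliases is not None:
        for lineno, line in enumerate(Path(aliases).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{aliases}:{lineno}: expected two columns")
            alias_map[fields[0]] = fields[1]

    graph = nx.Graph()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if lineno == 1 and fields[-1].lower() in {"combined_score", "score"}:
                continue
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, found {len(fields)}")
            a, b, raw_score = fields[0], fields[1], fields[2]
            try:
                score = int(raw_score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer score {raw_score!r}") from exc
            if score < min_score:
                continue
            a = alias_map.get(a, a)
            b = alias_map.get(b, b)
            if a == b:
                n_self_loops += 1
                continue
            graph.add_edge(a, b)
    if n_self_loops:
        logger.info("network\tself_loops_dropped\t%d", n_self_loops)
    if graph.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges at combined_score >= {min_score}")
    return graph


def read_gda_seeds(path: str | Path, min_gda: float = 0.01) -> set[str]:
    """Seed genes from a gene--disease association TSV (score strictly > ``min_gda``)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"gene_symbol", "gda_score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    keep = df.loc[df["gda_score"].astype(float) > min_gda, "gene_symbol"]
    return set(keep.astype(str))


@dataclass
class DiseaseModule:
    """Subgraph of the interactome induced by disease seed genes."""

    seed_genes: set[str]
    mapped_genes: set[str]
    subgraph: nx.Graph
    lcc_nodes: set[str]

    @property
    def n_induced_edges(self) -> int:
        return self.subgraph.number_of_edges()


def extract_module(net: nx.Graph, genes: set[str]) -> DiseaseModule:
    """Map seed genes onto the interactome and compute the induced LCC."""
    genes = set(genes)
    mapped = genes & set(net.nodes)
    absent = len(genes) - len(mapped)
    if absent:
        logger.info("network\tseeds_absent_from_interactome\t%d", absent)
    sub = net.subgraph(mapped).copy()
    if sub.number_of_nodes():
        lcc = max(nx.connected_components(sub), key=len)
    else:
        lcc = set()
    return DiseaseModule(seed_genes=genes, mapped_genes=mapped,
                         subgraph=sub, lcc_nodes=set(lcc))


def find_hubs(nodes: set[str], graph: nx.Graph | DiseaseModule,
              min_degree: int = 20) -> set[str]:
    """Nodes with degree >= ``min_degree`` within the given graph ("at least 20")."""
    g = graph.subgraph if isinstance(graph, DiseaseModule) else graph
    nodes = set(nodes)
    missing = nodes - set(g.nodes)
    if missing:
        raise ValueError(f"nodes absent from graph: {sorted(missing)[:5]}")
    return {n for n in nodes if g.degree(n) >= min_degree}


@dataclass
class ModuleSignificance:
    """LCC size of a gene set against a size-matched random-node null."""

    observed_lcc: int
    null_mean: float
    null_sd: float
    z: float  # NaN flags an undefined z (null_sd == 0)
    empirical_p: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_lcc": self.observed_lcc,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": None if np.isnan(self.z) else self.z,
            "empirical_p": self.empirical_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _lcc_size(adjacency: dict[str, set[str]], nodes: set[str]) -> int:
    """Largest connected component of the subgraph induced by ``nodes``."""
    best = 0
    unvisited = set(nodes)
    while unvisited:
        start = unvisited.pop()
        size = 1
        stack = [start]
        while stack:
            current = stack.pop()
            hits = adjacency[current] & unvisited
            if hits:
                size += len(hits)
                unvisited -= hits
                stack.extend(hits)
        best = max(best, size)
    return best


def lcc_significance(net: nx.Graph, genes: set[str], n_permutations: int = 10000,
                     seed: int = 0, degree_preserving: bool = False) -> ModuleSignificance:
    """Significance of a gene set's LCC against random node sets of equal size.

    The null draws ``n_permutations`` node sets of size |mapped genes|
    uniformly from all interactome nodes (or, with ``degree_preserving``,
    matching the observed log2-degree-bin profile) and records their LCC
    sizes.  z is the standardized observed LCC; the empirical p-value uses
    the add-one correction ``(1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    mapped = set(genes) & set(net.nodes)
    if len(mapped) < 2:
        raise ValueError("need at least 2 mapped genes for LCC significance")

    adjacency = {n: set(net[n]) for n in net.nodes}
    observed = _lcc_size(adjacency, mapped)
    all_nodes = np.array(sorted(net.nodes), dtype=object)
    rng = np.random.default_rng(seed)
    size = len(mapped)

    if degree_preserving:
        degrees = np.array([net.degree(n) for n in all_nodes])
        bins = np.floor(np.log2(np.maximum(degrees, 1))).astype(int)
        module_bins = np.floor(
            np.log2(np.maximum([net.degree(n) for n in mapped], 1))
        ).astype(int)
        by_bin = {b: all_nodes[bins == b] for b in np.unique(bins)}
        wanted = {b: int((module_bins == b).sum()) for b in np.unique(module_bins)}

        def draw() -> set[str]:
            out: list[str] = []
            for b, count in wanted.items():
                pool = by_bin.get(b, all_nodes)
                out.extend(rng.choice(pool, size=min(count, len(pool)), replace=False))
            return set(out)
    else:

        def draw() -> set[str]:
            return set(rng.choice(all_nodes, size=size, replace=False))

    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _lcc_size(adjacency, draw())

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
    if null_sd == 0:
        logger.info("network\tlcc_null_sd_zero\tz undefined")
    empirical_p = (1.0 + float((null >= observed).sum())) / (n_permutations + 1.0)
    return ModuleSignificance(
        observed_lcc=observed, null_mean=null_mean, null_sd=null_sd, z=z,
        empirical_p=empirical_p, n_permutations=n_permutations, seed=seed,
    )
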