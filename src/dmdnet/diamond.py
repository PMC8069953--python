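"""DIAMOnD: disease-module propagation by iterative connectivity significance.

Starting from the mapped seed genes, each iteration scores every non-member
node with at least one link into the current module by its connectivity
p-value — the hypergeometric tail probability of drawing at least its
observed number of module neighbours (ks) among its degree-k neighbours,
from a network of N nodes containing the s0 current module members:

    p = sum_{i=ks}^{min(k, s0)} C(s0, i) * C(N - s0, k - i) / C(N, k)

The minimal-p candidate joins the module and is recorded with its step.
N stays the full network node count throughout; seed weights are 1.
Ties at equal p break deterministically: higher ks first, then higher k,
then lexicographic gene symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import pandas as pd

from .stats import hypergeom_tail

__all__ = ["DiamondStep", "DiamondRanking", "connectivity_pvalue", "run_diamond"]

logger = logging.getLogger("dmdnet.diamond")


class DiamondStep(NamedTuple):
    gene: str
    step: int  # 1-based iteration at which the gene joined
    p_conn: float
    degree_k: int
    seed_links_ks: int


def connectivity_pvalue(network_size: int, module_size: int, degree_k: int,
                        links_to_module_ks: int) -> float:
    """Connectivity significance of one candidate node.

    Parameters map onto the hypergeometric tail as population ``network_size``,
    marked ``module_size``, draws ``degree_k``, observed ``links_to_module_ks``.
    """
    return hypergeom_tail(network_size, module_size, degree_k, links_to_module_ks)


@dataclass
class DiamondRanking:
    """Ordered DIAMOnD predictions with per-step connectivity p-values."""

    entries: list[DiamondStep]

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def top(self, n: int) -> list[str]:
        return self.genes[:n]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.step, e.gene, e.p_conn, e.degree_k, e.seed_links_ks) for e in self.entries],
            columns=["rank", "gene", "p_conn", "degree", "seed_links"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


_TIE_RTOL = 1e-9  # p-values this close count as tied (different summation orders)


def _beats(p: float, ks: int, k: int, gene: str,
           best: tuple[float, int, int, str]) -> bool:
    """Candidate ordering: smaller p, then higher ks, higher k, lexicographic."""
    best_p, best_ks, best_k, best_gene = best
    if p < best_p * (1.0 - _TIE_RTOL):
        return True
    if p > best_p * (1.0 + _TIE_RTOL) and p > best_p + 1e-300:
        return False
    return (-ks, -k, gene) < (-best_ks, -best_k, best_gene)


def run_diamond(net: nx.Graph, seeds: set[str], n_iterations: int) -> DiamondRanking:
    """Rank non-seed genes by iterative connectivity significance.

    Stops early (with a logged notice) when no candidate remains.  Seeds
    equal to the whole node set yield an empty ranking with a warning.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    mapped_seeds = set(seeds) & set(net.nodes)
    if not mapped_seeds:
        raise ValueError("no seed gene maps into the network")
    if len(mapped_seeds) < len(set(seeds)):
        logger.info("diamond\tseeds_absent\t%d", len(set(seeds)) - len(mapped_seeds))

    N = net.number_of_nodes()
    module = set(mapped_seeds)
    if module == set(net.nodes):
        logger.warning("diamond\tno_candidates\tseeds cover the whole network")
        return DiamondRanking(entries=[])

    # ks bookkeeping: links into the current module for every border node
    ks: dict[str, int] = {}
    for member in module:
        for nb in net[member]:
            if nb not in module:
                ks[nb] = ks.get(nb, 0) + 1

    entries: list[DiamondStep] = []
    for step in range(1, n_iterations + 1):
        if not ks:
            logger.info("diamond\tearly_stop\tno candidates at step %d", step)
            break
        s0 = len(module)
        cache: dict[tuple[int, int], float] = {}
        best: tuple[float, int, int, str] | None = None
        for gene, links in ks.items():
            k = net.degree(gene)
            key = (k, links)
            p = cache.get(key)
            if p is None:
                p = connectivity_pvalue(N, s0, k, links)
                cache[key] = p
            if best is None or _beats(p, links, k, gene, best):
                best = (p, links, k, gene)
        p, links, k, gene = best
        entries.append(
            DiamondStep(gene=gene, step=step, p_conn=p, degree_k=k, seed_links_ks=links)
        )
        module.add(gene)
        del ks[gene]
        for nb in net[gene]:
            if nb not in module:
                ks[nb] = ks.get(nb, 0) + 1
    return DiamondRanking(entries=entries)
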