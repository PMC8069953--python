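"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the hypergeometric
tail is summed from ``math.comb`` ratios, and the module-propagation oracle
recomputes every candidate's connectivity p-value from scratch at every
iteration with no incremental bookkeeping.
"""

from math import comb

import networkx as nx


def hypergeom_tail_comb(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability by direct combinatorial sums."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def diamond_bruteforce(net: nx.Graph, seeds: set[str], n_iterations: int):
    """From-scratch module propagation: returns (gene, step, p, k, ks) tuples.

    Every iteration rescans all non-member nodes, recounts their links into
    the module, and recomputes the full tail sum; ties break by higher ks,
    higher degree, then lexicographic gene symbol.
    """
    N = net.number_of_nodes()
    module = set(seeds) & set(net.nodes)
    out = []
    for step in range(1, n_iterations + 1):
        s0 = len(module)
        best = None
        for gene in sorted(net.nodes):
            if gene in module:
                continue
            ks = sum(1 for nb in net[gene] if nb in module)
            if ks == 0:
                continue
            k = net.degree(gene)
            p = hypergeom_tail_comb(N, s0, k, ks)
            if best is None:
                best = (p, ks, k, gene)
                continue
            bp, bks, bk, bg = best
            # near-equal p counts as a tie (floating summation order differs)
            if p < bp * (1 - 1e-9):
                best = (p, ks, k, gene)
            elif p <= bp * (1 + 1e-9) and (-ks, -k, gene) < (-bks, -bk, bg):
                best = (p, ks, k, gene)
        if best is None:
            break
        p, ks, k, gene = best
        out.append((gene, step, p, k, ks))
        module.add(gene)
    return out
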