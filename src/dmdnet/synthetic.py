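"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate, in one shared gene-symbol namespace: multi-study
expression matrices with planted standardized effects (case/control, unit
Gaussian noise, per-study gene panels emulating platform differences), a
preferential-attachment interactome containing a topologically clustered
disease gene set, drug--gene interaction tables with planted
phenotype-reversing drugs, drug--target tables for the network engine, and
paired up/down signature libraries with planted reversers.  All generators
are pure functions of their parameters and seed, and a
:class:`SyntheticTruth` records every planted set so recovery tests are
self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .anti_signature import LibrarySignature, write_signature_library
from .io import write_expression
from .meta import ExpressionStudy
from .signature import GeneSignature

__all__ = [
    "SyntheticTruth",
    "gene_names",
    "generate_expression_studies",
    "generate_interactome",
    "generate_disease_genes",
    "generate_drug_gene_table",
    "generate_drug_target_table",
    "generate_signature_library",
    "write_synthetic_inputs",
]

# a few type strings outside both published action lists
_NEUTRAL_TYPES = ("binder", "ligand", "substrate", "modulator", "cofactor")
_INHIBITING_SAMPLE = ("inhibitor", "antagonist", "blocker", "inverse agonist",
                      "negative modulator", "antagonist, inhibitor")
_ACTIVATING_SAMPLE = ("agonist", "activator", "inducer", "positive modulator",
                      "potentiator", "agonist, activator")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    deg_genes_up: set[str] = field(default_factory=set)
    deg_genes_down: set[str] = field(default_factory=set)
    module_genes: set[str] = field(default_factory=set)
    reversing_drugs: set[str] = field(default_factory=set)
    rng_seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "deg_genes_up": sorted(self.deg_genes_up),
                    "deg_genes_down": sorted(self.deg_genes_down),
                    "module_genes": sorted(self.module_genes),
                    "reversing_drugs": sorted(self.reversing_drugs),
                    "rng_seed": self.rng_seed,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            deg_genes_up=set(d["deg_genes_up"]),
            deg_genes_down=set(d["deg_genes_down"]),
            module_genes=set(d["module_genes"]),
            reversing_drugs=set(d["reversing_drugs"]),
            rng_seed=int(d["rng_seed"]),
        )


def gene_names(n: int) -> list[str]:
    """The shared synthetic gene-symbol namespace ``G00001..``."""
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_expression_studies(n_studies: int = 3, n_genes: int = 2000,
                                n_cases: int = 10, n_controls: int = 10,
                                deg_fraction: float = 0.05,
                                effect_magnitude: float = 3.0,
                                panel_fraction: tuple[float, float] = (0.8, 1.0),
                                seed: int = 0,
                                planted_up: list[str] | None = None,
                                planted_down: list[str] | None = None,
                                ) -> tuple[list[ExpressionStudy], SyntheticTruth]:
    """Case/control studies with planted standardized effects.

    Expression is unit-variance Gaussian noise; a ``deg_fraction`` of genes
    is shifted by ``effect_magnitude`` standard deviations in cases (half
    up, half down), consistently across studies.  Each study measures a
    random gene panel covering a ``panel_fraction`` share of the universe
    (platform-coverage emulation).  ``planted_up``/``planted_down``
    override the random choice of planted genes with explicit symbol lists
    (``deg_fraction`` is then ignored).
    """
    if n_studies < 1:
        raise ValueError("need at least one study")
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least 2 samples per group")
    if not 0 <= deg_fraction <= 1:
        raise ValueError("deg_fraction must lie in [0, 1]")
    lo, hi = panel_fraction
    if not 0 < lo <= hi <= 1:
        raise ValueError("panel_fraction must satisfy 0 < lo <= hi <= 1")

    rng = np.random.default_rng(seed)
    genes = np.array(gene_names(n_genes))
    if planted_up is not None or planted_down is not None:
        index = {g: i for i, g in enumerate(genes)}
        missing = (set(planted_up or ()) | set(planted_down or ())) - set(index)
        if missing:
            raise ValueError(f"planted genes outside the universe: {sorted(missing)[:5]}")
        up_idx = np.array([index[g] for g in sorted(planted_up or ())], dtype=int)
        down_idx = np.array([index[g] for g in sorted(planted_down or ())], dtype=int)
    else:
        n_deg = int(round(deg_fraction * n_genes))
        planted = rng.choice(n_genes, size=n_deg, replace=False)
        up_idx = planted[: n_deg // 2 + n_deg % 2]
        down_idx = planted[n_deg // 2 + n_deg % 2:]
    shift = np.zeros(n_genes)
    shift[up_idx] = effect_magnitude
    shift[down_idx] = -effect_magnitude

    studies = []
    for s in range(n_studies):
        frac = rng.uniform(lo, hi)
        panel = np.sort(rng.choice(n_genes, size=max(2, int(round(frac * n_genes))),
                                   replace=False))
        n = n_controls + n_cases
        data = rng.normal(size=(len(panel), n))
        data[:, n_controls:] += shift[panel][:, None]
        samples = [f"S{s + 1}_{'ctl' if i < n_controls else 'case'}{i + 1:02d}"
                   for i in range(n)]
        groups = pd.Series(
            ["control"] * n_controls + ["case"] * n_cases, index=samples, name="group"
        )
        matrix = pd.DataFrame(data, index=genes[panel], columns=samples)
        studies.append(ExpressionStudy(study_id=f"study{s + 1}", matrix=matrix, groups=groups))

    truth = SyntheticTruth(
        deg_genes_up=set(genes[up_idx]), deg_genes_down=set(genes[down_idx]), rng_seed=seed
    )
    return studies, truth


def generate_interactome(n_nodes: int = 1000, edges_per_new_node: int = 3,
                         seed: int = 0, genes: list[str] | None = None) -> nx.Graph:
    """Preferential-attachment (Barabasi--Albert) interactome.

    Node names come from ``genes`` (first ``n_nodes`` entries) or default to
    the shared synthetic namespace, keeping the network aligned with the
    expression universe.
    """
    if not 1 <= edges_per_new_node < n_nodes:
        raise ValueError("need n_nodes > edges_per_new_node >= 1")
    graph = nx.barabasi_albert_graph(n_nodes, edges_per_new_node, seed=seed)
    names = genes[:n_nodes] if genes is not None else gene_names(n_nodes)
    if len(names) < n_nodes:
        raise ValueError("gene name list shorter than n_nodes")
    return nx.relabel_nodes(graph, dict(enumerate(names)))


def generate_disease_genes(net: nx.Graph, module_size: int = 50,
                           locality: float = 1.0, seed: int = 0) -> set[str]:
    """A disease gene set of tunable topological clustering.

    With ``locality`` 1 the set grows by breadth-first expansion from a
    random anchor (a connected, clustered module); with 0 it is a uniform
    random sample; in between, each added gene is a frontier neighbour with
    probability ``locality`` and a uniform random node otherwise.
    """
    nodes = sorted(net.nodes)
    if module_size > len(nodes):
        raise ValueError("module_size exceeds the node count")
    if not 0 <= locality <= 1:
        raise ValueError("locality must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if module_size == 0:
        return set()

    chosen: set[str] = {nodes[rng.integers(len(nodes))]}
    while len(chosen) < module_size:
        frontier = sorted(
            {nb for g in chosen for nb in net[g]} - chosen
        )
        if frontier and rng.random() < locality:
            chosen.add(frontier[rng.integers(len(frontier))])
        else:
            pool = [n for n in nodes if n not in chosen]
            chosen.add(pool[rng.integers(len(pool))])
    return chosen


def generate_drug_gene_table(gene_universe: list[str] | set[str], n_drugs: int = 500,
                             targets_per_drug: tuple[int, int] = (3, 30),
                             signature: GeneSignature | None = None,
                             planted_reversers: int = 0, planted_hits: int = 10,
                             seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """DGIdb-style interaction table with optional planted reversing drugs.

    Background drugs target uniform random genes with interaction types
    drawn from the published vocabulary plus neutral strings.  Planted
    reversers additionally hit ``planted_hits`` signature genes in the
    phenotype-reversing direction (inhibiting types on up-genes, activating
    on down-genes).
    """
    universe = sorted(set(gene_universe))
    if not universe:
        raise ValueError("gene universe is empty")
    if planted_reversers > n_drugs:
        raise ValueError("planted_reversers cannot exceed n_drugs")
    if planted_reversers and (signature is None or not signature.genes):
        raise ValueError("planted reversers require a non-empty signature")
    lo, hi = targets_per_drug
    if not 1 <= lo <= hi:
        raise ValueError("targets_per_drug must satisfy 1 <= lo <= hi")

    rng = np.random.default_rng(seed)
    all_types = _INHIBITING_SAMPLE + _ACTIVATING_SAMPLE + _NEUTRAL_TYPES
    rows: list[tuple[str, str, str]] = []
    planted_names = {f"DRUG{i + 1:04d}" for i in range(planted_reversers)}
    sig_genes = signature.genes if signature is not None else set()
    nonsig = [g for g in universe if g not in sig_genes]
    for i in range(n_drugs):
        drug = f"DRUG{i + 1:04d}"
        n_targets = int(rng.integers(lo, hi + 1))
        # planted drugs draw their background targets outside the signature,
        # so every in-signature pair they carry is direction-opposing
        pool = nonsig if drug in planted_names else universe
        background = rng.choice(len(pool), size=min(n_targets, len(pool)), replace=False)
        for gi in background:
            rows.append((pool[gi], drug, all_types[rng.integers(len(all_types))]))
        if drug in planted_names:
            sig_up = sorted(signature.up)
            sig_down = sorted(signature.down)
            pool = [(g, "up") for g in sig_up] + [(g, "down") for g in sig_down]
            pick = rng.choice(len(pool), size=min(planted_hits, len(pool)), replace=False)
            for j in pick:
                gene, direction = pool[j]
                bank = _INHIBITING_SAMPLE if direction == "up" else _ACTIVATING_SAMPLE
                rows.append((gene, drug, bank[rng.integers(len(bank))]))

    table = pd.DataFrame(rows, columns=["gene_name", "drug_name", "interaction_types"])
    table = table.drop_duplicates(subset=["gene_name", "drug_name"], keep="last")
    table = table.sort_values(["drug_name", "gene_name"], kind="mergesort").reset_index(drop=True)
    truth = SyntheticTruth(reversing_drugs=planted_names, rng_seed=seed)
    return table, truth


def generate_drug_target_table(gene_universe: list[str] | set[str], n_drugs: int = 500,
                               targets_per_drug: tuple[int, int] = (3, 30),
                               signature: GeneSignature | None = None,
                               planted_reversers: int = 0, planted_hits: int = 10,
                               seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Drug--target table (``drug, gene, source``) for the network engine.

    Reuses the interaction-table generator and assigns each drug a
    drugbank/ctd source tag.
    """
    table, truth = generate_drug_gene_table(
        gene_universe, n_drugs=n_drugs, targets_per_drug=targets_per_drug,
        signature=signature, planted_reversers=planted_reversers,
        planted_hits=planted_hits, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    drugs = sorted(table["drug_name"].unique())
    source = {d: ("drugbank" if rng.random() < 0.5 else "ctd") for d in drugs}
    out = pd.DataFrame(
        {
            "drug": table["drug_name"],
            "gene": table["gene_name"],
            "source": table["drug_name"].map(source),
        }
    )
    return out.reset_index(drop=True), truth


def generate_signature_library(gene_universe: list[str] | set[str],
                               n_signatures: int = 100, up_size: int = 30,
                               down_size: int = 30,
                               query: GeneSignature | None = None,
                               planted_reversers: int = 0,
                               reversal_fraction: float = 0.8,
                               seed: int = 0
                               ) -> tuple[list[LibrarySignature], SyntheticTruth]:
    """Paired up/down signature library with optional planted reversers.

    A planted reverser draws a ``reversal_fraction`` share of its up-set
    from the query's down-set and of its down-set from the query's up-set,
    padding with random genes.
    """
    universe = sorted(set(gene_universe))
    if planted_reversers > n_signatures:
        raise ValueError("planted_reversers cannot exceed n_signatures")
    if planted_reversers and (query is None or not query.genes):
        raise ValueError("planted reversers require a non-empty query signature")
    rng = np.random.default_rng(seed)

    def random_disjoint(n_up: int, n_down: int, exclude: set[str]) -> tuple[set[str], set[str]]:
        pool = [g for g in universe if g not in exclude]
        pick = rng.choice(len(pool), size=min(n_up + n_down, len(pool)), replace=False)
        picked = [pool[i] for i in pick]
        return set(picked[:n_up]), set(picked[n_up:])

    library: list[LibrarySignature] = []
    planted = {f"SIG{i + 1:04d}" for i in range(planted_reversers)}
    for i in range(n_signatures):
        sig_id = f"SIG{i + 1:04d}"
        if sig_id in planted:
            n_rev_up = min(int(round(reversal_fraction * up_size)), len(query.down))
            n_rev_down = min(int(round(reversal_fraction * down_size)), len(query.up))
            rev_up = set(
                np.array(sorted(query.down))[
                    rng.choice(len(query.down), size=n_rev_up, replace=False)
                ]
            ) if n_rev_up else set()
            rev_down = set(
                np.array(sorted(query.up))[
                    rng.choice(len(query.up), size=n_rev_down, replace=False)
                ]
            ) if n_rev_down else set()
            pad_up, pad_down = random_disjoint(
                up_size - len(rev_up), down_size - len(rev_down),
                exclude=rev_up | rev_down | set(query.genes),
            )
            up, down = rev_up | pad_up, rev_down | pad_down
        else:
            up, down = random_disjoint(up_size, down_size, exclude=set())
        library.append(
            LibrarySignature(sig_id=sig_id, perturbagen=f"drug_{sig_id.lower()}",
                             up=frozenset(up), down=frozenset(down))
        )
    truth = SyntheticTruth(reversing_drugs=planted, rng_seed=seed)
    return library, truth


def write_synthetic_inputs(outdir: str | Path, n_genes: int = 2000, n_studies: int = 3,
                           n_network_nodes: int | None = None, module_size: int = 50,
                           n_drugs: int = 500, planted_reversers: int = 5,
                           planted_hits: int = 25, n_library: int = 100,
                           seed: int = 0) -> SyntheticTruth:
    """Write a complete synthetic input set in the pipeline's file dialects.

    Produces expression/design TSVs per study, a STRING-style edge list, a
    GDA table, a DGIdb-style interaction table, a drug--target table, a
    signature-library GMT, and the serialized truth.  The planted structure
    mirrors the disease setting: the GDA seeds form a clustered module,
    the planted DEGs sit partly inside the module and partly among its
    highest-degree network neighbours (so DIAMOnD can predict them), and
    the planted reversers oppose the planted expression effects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = gene_names(n_genes)
    rng = np.random.default_rng(seed)

    if n_network_nodes is None:
        n_network_nodes = min(1000, n_genes // 2)  # network covers half the universe
    module_size = min(module_size, n_network_nodes // 4)
    net = generate_interactome(n_network_nodes, seed=seed + 1, genes=genes)
    pd.DataFrame(
        [(a, b, 900) for a, b in sorted(map(sorted, net.edges))],
        columns=["protein1", "protein2", "combined_score"],
    ).to_csv(outdir / "string_links.tsv", sep="\t", index=False)

    module = generate_disease_genes(net, module_size=module_size, seed=seed + 2)
    pd.DataFrame(
        {"gene_symbol": sorted(module), "gda_score": 0.3}
    ).to_csv(outdir / "gda.tsv", sep="\t", index=False)
    truth = SyntheticTruth(module_genes=module, rng_seed=seed)

    # planted DEGs: some module members, the module's best-connected
    # neighbours (discoverable by propagation), and a random remainder
    n_deg = max(4, int(round(0.05 * n_genes)))
    in_module = sorted(module)[: n_deg // 5]
    ring = sorted(
        {nb for g in module for nb in net[g]} - module,
        key=lambda g: (-net.degree(g), g),
    )[: (3 * n_deg) // 5]
    rest_pool = [g for g in genes if g not in module and g not in set(ring)]
    rest = [
        rest_pool[i]
        for i in rng.choice(len(rest_pool), size=n_deg - len(in_module) - len(ring),
                            replace=False)
    ]
    planted = sorted(in_module + ring + rest)
    half = len(planted) // 2
    order = rng.permutation(len(planted))
    planted_up = [planted[i] for i in sorted(order[:len(planted) - half])]
    planted_down = [planted[i] for i in sorted(order[len(planted) - half:])]

    studies, expr_truth = generate_expression_studies(
        n_studies=n_studies, n_genes=n_genes, seed=seed,
        planted_up=planted_up, planted_down=planted_down,
    )
    truth.deg_genes_up = expr_truth.deg_genes_up
    truth.deg_genes_down = expr_truth.deg_genes_down
    for study in studies:
        write_expression(
            outdir / f"{study.study_id}_expression.tsv",
            outdir / f"{study.study_id}_design.tsv",
            study.matrix, study.groups,
        )

    deg_signature = GeneSignature(
        up=truth.deg_genes_up & set(net.nodes), down=truth.deg_genes_down & set(net.nodes)
    )
    dgidb, drug_truth = generate_drug_gene_table(
        set(net.nodes), n_drugs=n_drugs, signature=deg_signature,
        planted_reversers=planted_reversers, planted_hits=planted_hits, seed=seed + 3,
    )
    dgidb.to_csv(outdir / "dgidb.tsv", sep="\t", index=False)
    targets, _ = generate_drug_target_table(
        set(net.nodes), n_drugs=n_drugs, signature=deg_signature,
        planted_reversers=planted_reversers, planted_hits=planted_hits, seed=seed + 3,
    )
    targets.to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)
    truth.reversing_drugs = drug_truth.reversing_drugs

    library, _ = generate_signature_library(
        genes, n_signatures=n_library, query=deg_signature,
        planted_reversers=min(planted_reversers, n_library), seed=seed + 4,
    )
    write_signature_library(outdir / "library.gmt", library)

    truth.to_json(outdir / "truth.json")
    return truth
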