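"""Network-based drug ranking against a bipartite drug--gene network.

Drug--target tables (DrugBank-style drugs and CTD-style chemicals in one
namespace, distinguished by source tags) are restricted to the disease
signature genes, giving each drug a degree — the number of signature genes
it targets.  The null model redraws the signature as uniform random gene
lists of the same size from the analysis universe; each drug's degree
against the random lists yields an expected mean and SD, a z-score, a
one-sided normal p-value, and a BH FDR.  Drugs are ranked by FDR then z
(raw degree is available as an alternative key) and truncated to the top k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import adjust_bh

__all__ = ["DrugGeneNetwork", "build_drug_gene_network", "rank_drugs_by_degree_z"]

logger = logging.getLogger("dmdnet.drug_network")


@dataclass
class DrugGeneNetwork:
    """Bipartite drug--gene network restricted to signature genes."""

    edges: pd.DataFrame  # columns: drug, gene
    drug_sources: dict[str, str]  # drug -> comma-joined source tags

    @property
    def drug_nodes(self) -> set[str]:
        return set(self.edges["drug"])

    @property
    def gene_nodes(self) -> set[str]:
        return set(self.edges["gene"])

    def degree(self) -> pd.Series:
        return self.edges.groupby("drug")["gene"].nunique().sort_values(ascending=False)

    def to_tsv(self, path) -> None:
        out = self.edges.copy()
        out["source"] = out["drug"].map(self.drug_sources)
        out.to_csv(path, sep="\t", index=False)


def _concat_tables(target_tables: pd.DataFrame | list[pd.DataFrame]) -> pd.DataFrame:
    if isinstance(target_tables, pd.DataFrame):
        target_tables = [target_tables]
    frames = []
    for tbl in target_tables:
        required = {"drug", "gene"}
        if not required <= set(tbl.columns):
            raise ValueError(f"drug-target table needs columns {sorted(required)}")
        frame = tbl.copy()
        if "source" not in frame.columns:
            frame["source"] = "other"
        frames.append(frame[["drug", "gene", "source"]].astype(str))
    return pd.concat(frames, ignore_index=True)


def build_drug_gene_network(target_tables: pd.DataFrame | list[pd.DataFrame],
                            signature_genes: set[str]) -> DrugGeneNetwork:
    """Map signature genes onto drug--target tables; drop edge-less drugs.

    Duplicate (drug, gene) rows across sources collapse to one edge with
    merged source tags.
    """
    table = _concat_tables(target_tables)
    n_drugs_total = table["drug"].nunique()
    table = table[table["gene"].isin(set(signature_genes))]
    if table.empty:
        raise ValueError("no drug targets any signature gene")
    dropped = n_drugs_total - table["drug"].nunique()
    if dropped:
        logger.info("drug_network\tdrugs_without_signature_edges\t%d", dropped)
    sources = (
        table.groupby("drug")["source"]
        .apply(lambda s: ",".join(sorted(set(s))))
        .to_dict()
    )
    edges = table[["drug", "gene"]].drop_duplicates().reset_index(drop=True)
    return DrugGeneNetwork(edges=edges, drug_sources=sources)


def rank_drugs_by_degree_z(target_tables: pd.DataFrame | list[pd.DataFrame],
                           signature_genes: set[str], gene_universe: set[str],
                           n_random: int = 1000, seed: int = 0, top_k: int = 50,
                           sort_by: str = "fdr_z") -> pd.DataFrame:
    """Rank drugs by signature-target degree standardized against random lists.

    For each of ``n_random`` replicates, a uniform random gene list of size
    |signature| is drawn from ``gene_universe``; per-drug degrees against the
    replicates give the null mean and SD.  ``sort_by`` is ``"fdr_z"``
    (FDR ascending, z descending) or ``"degree"``.  Drugs with zero null SD
    get a flagged undefined z (NaN) and rank by degree among themselves
    (logged).  Returns the top ``top_k`` rows with a 1-based ``rank`` column.
    """
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    if sort_by not in {"fdr_z", "degree"}:
        raise ValueError("sort_by must be 'fdr_z' or 'degree'")
    signature_genes = set(signature_genes)
    universe = sorted(set(gene_universe))
    if not signature_genes <= set(universe):
        raise ValueError("signature_genes must lie within gene_universe")

    table = _concat_tables(target_tables)
    table = table[table["gene"].isin(universe)]
    if table.empty:
        raise ValueError("no drug targets any universe gene")

    gene_index = {g: i for i, g in enumerate(universe)}
    drugs = sorted(table["drug"].unique())
    drug_index = {d: i for i, d in enumerate(drugs)}
    targets = np.zeros((len(drugs), len(universe)), dtype=np.float32)
    for drug, gene in table[["drug", "gene"]].drop_duplicates().itertuples(index=False):
        targets[drug_index[drug], gene_index[gene]] = 1.0

    sig_mask = np.zeros(len(universe), dtype=np.float32)
    for g in signature_genes:
        sig_mask[gene_index[g]] = 1.0
    observed = targets @ sig_mask

    rng = np.random.default_rng(seed)
    rand = np.zeros((len(universe), n_random), dtype=np.float32)
    size = len(signature_genes)
    for j in range(n_random):
        rand[rng.choice(len(universe), size=size, replace=False), j] = 1.0
    null = targets @ rand  # drugs x replicates
    null_mean = null.mean(axis=1).astype(float)
    null_sd = null.std(axis=1, ddof=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    n_flagged = int(np.isnan(z).sum())
    if n_flagged:
        logger.info("drug_network\tz_undefined_null_sd_zero\t%d", n_flagged)
    p = np.where(np.isnan(z), 1.0, _sps.norm.sf(np.where(np.isnan(z), 0.0, z)))

    result = pd.DataFrame(
        {
            "drug": drugs,
            "degree": observed.astype(int),
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "fdr": adjust_bh(p),
        }
    )
    if sort_by == "degree":
        result = result.sort_values(["degree", "drug"], ascending=[False, True],
                                    kind="mergesort")
    else:
        # NaN z (undefined) sinks below defined scores, ordered by degree
        result = result.assign(_zkey=np.where(np.isnan(z), -np.inf, z)).sort_values(
            ["fdr", "_zkey", "degree", "drug"], ascending=[True, False, False, True],
            kind="mergesort",
        ).drop(columns="_zkey")
    result = result.head(top_k).reset_index(drop=True)
    result.insert(0, "rank", np.arange(1, len(result) + 1))
    return result
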