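"""Direction-aware drug--target enrichment over DGIdb-style interaction tables.

Each drug--gene interaction carries a type string (e.g. ``inhibitor`` or
``antagonist, blocker``); the packaged vocabulary classifies it as
inhibiting, activating, or other.  A drug--gene pair is *phenotype-reversing*
when an inhibiting interaction hits an up-regulated signature gene or an
activating interaction hits a down-regulated one.  Per drug, the overlap of
reversing targets with the candidate gene set is tested with the one-sided
hypergeometric tail against the analysis background (genes shared by the
meta-analysis and the interactome), followed by Benjamini--Hochberg
adjustment across the tested drugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .signature import GeneSignature
from .stats import adjust_bh, hypergeom_tail

__all__ = [
    "DrugInteractionRecord",
    "load_vocabulary",
    "normalize_types",
    "classify_interaction",
    "read_dgidb_table",
    "reversal_targets",
    "enrich_drugs",
]

logger = logging.getLogger("dmdnet.drug_enrichment")

_seen_unknown: set[str] = set()


def load_vocabulary() -> tuple[frozenset[str], frozenset[str]]:
    """The packaged (inhibiting, activating) interaction-type string sets."""
    pkg = resources.files("dmdnet.data")
    inhibiting = frozenset(
        line.strip()
        for line in (pkg / "interaction_types_inhibiting.txt").read_text().splitlines()
        if line.strip()
    )
    activating = frozenset(
        line.strip()
        for line in (pkg / "interaction_types_activating.txt").read_text().splitlines()
        if line.strip()
    )
    return inhibiting, activating


_INHIBITING, _ACTIVATING = load_vocabulary()


def normalize_types(types: str | Iterable[str]) -> str:
    """Normalize an interaction-type annotation to the vocabulary convention.

    Accepts a raw string (comma- or pipe-separated tokens) or an iterable of
    tokens; lower-cases, strips, and rejoins with ``", "`` preserving order.
    """
    if isinstance(types, str):
        tokens = types.replace("|", ",").split(",")
    else:
        tokens = list(types)
    return ", ".join(t.strip().lower() for t in tokens if t.strip())


def classify_interaction(types: str | Iterable[str]) -> str:
    """Classify a type annotation as ``inhibiting``, ``activating``, or ``other``.

    Matching is an exact string comparison of the normalized annotation
    against the packaged vocabulary; unknown strings classify as ``other``
    and are logged once per distinct string.
    """
    normalized = normalize_types(types)
    if normalized in _INHIBITING:
        return "inhibiting"
    if normalized in _ACTIVATING:
        return "activating"
    if normalized and normalized not in _seen_unknown:
        _seen_unknown.add(normalized)
        logger.info("drug_enrichment\tunknown_interaction_type\t%s", normalized)
    return "other"


@dataclass(frozen=True)
class DrugInteractionRecord:
    drug: str
    gene: str
    interaction_types: tuple[str, ...]

    @property
    def action_class(self) -> str:
        return classify_interaction(self.interaction_types)


def read_dgidb_table(path: str | Path) -> pd.DataFrame:
    """Read a DGIdb-style TSV (``gene_name, drug_name, interaction_types``).

    Returns a frame with columns ``gene, drug, interaction_types,
    action_class``; type tokens may be pipe- or comma-separated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_name", "drug_name", "interaction_types"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}, found {list(df.columns)}")
    out = pd.DataFrame(
        {
            "gene": df["gene_name"].astype(str),
            "drug": df["drug_name"].astype(str),
            "interaction_types": df["interaction_types"].map(normalize_types),
        }
    )
    out["action_class"] = out["interaction_types"].map(classify_interaction)
    return out


def reversal_targets(records: pd.DataFrame, signature: GeneSignature) -> dict[str, set[str]]:
    """Per-drug sets of signature genes hit in the phenotype-reversing direction.

    A pair counts when the gene is up-regulated and the interaction is
    inhibiting, or down-regulated and activating; gene sets are
    deduplicated per drug.
    """
    if "action_class" not in records.columns:
        records = records.assign(
            action_class=records["interaction_types"].map(classify_interaction)
        )
    reversing = (
        records["action_class"].eq("inhibiting") & records["gene"].isin(signature.up)
    ) | (records["action_class"].eq("activating") & records["gene"].isin(signature.down))
    hits: dict[str, set[str]] = {}
    for drug, gene in records.loc[reversing, ["drug", "gene"]].itertuples(index=False):
        hits.setdefault(drug, set()).add(gene)
    return hits


def enrich_drugs(records: pd.DataFrame, candidate_genes: set[str],
                 background: set[str] | int, signature: GeneSignature | None = None,
                 min_hits: int = 1,
                 allowed_drugs: set[str] | None = None) -> pd.DataFrame:
    """Hypergeometric drug--target enrichment against the analysis background.

    ``candidate_genes`` is the marked set K (the predicted candidate genes).
    ``background`` is the background gene *set* (targets are restricted to
    it before counting) or, when only a size is known, an integer N with
    targets assumed pre-restricted.  When ``signature`` is given, only
    phenotype-reversing pairs count as hits; otherwise any target inside
    ``candidate_genes`` counts.  Drugs with zero background targets are
    excluded (logged); ``allowed_drugs`` optionally restricts the tested
    family (e.g. to clinical-stage compounds).  Rows are sorted by FDR then
    p-value.
    """
    candidate_genes = set(candidate_genes)
    if isinstance(background, int):
        n_background = background
        background_set: set[str] | None = None
    else:
        background_set = set(background)
        n_background = len(background_set)
        if not candidate_genes <= background_set:
            raise ValueError("candidate_genes must lie within the background")
    if n_background < len(candidate_genes):
        raise ValueError("background smaller than the candidate set")

    if allowed_drugs is not None:
        records = records[records["drug"].isin(allowed_drugs)]

    if signature is not None:
        hit_map = reversal_targets(records, signature)
    else:
        hit_map = {}
        inside = records[records["gene"].isin(candidate_genes)]
        for drug, gene in inside[["drug", "gene"]].itertuples(index=False):
            hit_map.setdefault(drug, set()).add(gene)

    rows = []
    n_excluded = 0
    for drug, grp in records.groupby("drug", sort=True):
        targets = set(grp["gene"])
        if background_set is not None:
            targets &= background_set
        if not targets:
            n_excluded += 1
            continue
        hit_genes = hit_map.get(drug, set()) & candidate_genes & targets
        if len(hit_genes) < min_hits:
            continue
        p = hypergeom_tail(n_background, len(candidate_genes), len(targets), len(hit_genes))
        rows.append(
            {
                "drug": drug,
                "hit_genes": ",".join(sorted(hit_genes)),
                "n_hits": len(hit_genes),
                "n_total_targets": len(targets),
                "p": p,
            }
        )
    if n_excluded:
        logger.info("drug_enrichment\tdrugs_without_background_targets\t%d", n_excluded)

    result = pd.DataFrame(rows, columns=["drug", "hit_genes", "n_hits", "n_total_targets", "p"])
    if len(result):
        result["fdr"] = adjust_bh(result["p"].to_numpy())
        result = result.sort_values(["fdr", "p", "drug"], kind="mergesort").reset_index(drop=True)
    else:
        result["fdr"] = pd.Series(dtype=float)
    return result
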