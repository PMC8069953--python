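"""Random-effects effect-size meta-analysis across expression studies.

Per study, each gene receives a standardized mean difference (Cohen's d)
with Hedges' small-sample correction g = J*d, J = 1 - 3/(4*df - 1), and the
usual large-sample variance v = (n1+n0)/(n1*n0) + g^2 / (2*(n1+n0)).
Per gene, study effects are combined with the DerSimonian--Laird
random-effects model: fixed weights w_i = 1/v_i give Cochran's Q, the
between-study variance is tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),
random-effects weights w*_i = 1/(v_i + tau^2) give the combined effect and a
Wald statistic z = mu * sqrt(sum w*), with a two-sided normal p-value and
Benjamini--Hochberg adjustment across genes.

The module follows the statsmodels model/results idiom:
``RandomEffectsMeta(studies).fit()`` returns a :class:`MetaResults` carrying
the per-gene table, a ``summary()``, and the DEG-calling rule
(FDR < 0.05 and |combined effect| > 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import read_expression
from .signature import GeneSignature
from .stats import adjust_bh

__all__ = [
    "ExpressionStudy",
    "compute_study_effects",
    "RandomEffectsMeta",
    "MetaResults",
    "combine_random_effects",
]

logger = logging.getLogger("dmdnet.meta")


@dataclass
class ExpressionStudy:
    """One expression study: a genes-by-samples matrix and case/control labels."""

    study_id: str
    matrix: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.groups = self.groups.astype(str)
        counts = self.groups.value_counts()
        for grp in ("control", "case"):
            if counts.get(grp, 0) < 2:
                raise ValueError(
                    f"study {self.study_id}: group '{grp}' needs >= 2 samples, "
                    f"has {counts.get(grp, 0)}"
                )
        extra = set(self.groups.unique()) - {"control", "case"}
        if extra:
            raise ValueError(f"study {self.study_id}: unknown groups {sorted(extra)}")
        if not set(self.groups.index) <= set(self.matrix.columns):
            raise ValueError(f"study {self.study_id}: design samples absent from matrix")
        self.matrix.index = self.matrix.index.astype(str).rename("gene")

    @classmethod
    def from_files(cls, study_id: str, expr_path: str | Path,
                   design_path: str | Path) -> "ExpressionStudy":
        matrix, groups = read_expression(expr_path, design_path)
        return cls(study_id=study_id, matrix=matrix, groups=groups)

    @property
    def n_case(self) -> int:
        return int((self.groups == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.groups == "control").sum())


def compute_study_effects(study: ExpressionStudy) -> pd.DataFrame:
    """Per-gene standardized effects for one study.

    Returns a frame indexed by gene with columns ``d`` (Cohen's d,
    case minus control over pooled SD), ``g`` (Hedges-corrected), and ``v``
    (variance of g).  Duplicate gene rows (multiple probes) are collapsed to
    the row with the largest |d|; genes with zero pooled SD are excluded and
    counted in the log.
    """
    case = study.matrix.loc[:, study.groups.index[study.groups == "case"]]
    ctrl = study.matrix.loc[:, study.groups.index[study.groups == "control"]]
    n1, n0 = case.shape[1], ctrl.shape[1]

    m1 = case.mean(axis=1).to_numpy()
    m0 = ctrl.mean(axis=1).to_numpy()
    s1 = case.var(axis=1, ddof=1).to_numpy()
    s0 = ctrl.var(axis=1, ddof=1).to_numpy()
    pooled_sd = np.sqrt(((n1 - 1) * s1 + (n0 - 1) * s0) / (n1 + n0 - 2))

    with np.errstate(divide="ignore", invalid="ignore"):
        d = (m1 - m0) / pooled_sd
    df = n1 + n0 - 2
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    v = (n1 + n0) / (n1 * n0) + g**2 / (2.0 * (n1 + n0))

    out = pd.DataFrame({"d": d, "g": g, "v": v}, index=study.matrix.index)
    n_zero_sd = int((pooled_sd == 0).sum())
    if n_zero_sd:
        logger.info("meta\tzero_sd_excluded\t%s:%d", study.study_id, n_zero_sd)
    out = out[np.isfinite(out["d"])]
    if out.index.has_duplicates:
        out = (
            out.assign(_abs_d=out["d"].abs())
            .sort_values("_abs_d", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_abs_d")
        )
        logger.info("meta\tduplicate_probes_collapsed\t%s", study.study_id)
    return out


def combine_random_effects(effects: Sequence[pd.DataFrame],
                           study_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """DerSimonian--Laird combination of per-study effect frames.

    Each frame is indexed by gene with columns ``g`` and ``v``; genes may be
    missing from some studies (platform differences) and are combined over
    the studies that measure them.  Returns the per-gene table with columns
    ``combined_es, tau2, z, p, fdr, n_studies, direction``.
    """
    if len(effects) == 0:
        raise ValueError("need at least one study")
    genes = effects[0].index
    for eff in effects[1:]:
        genes = genes.union(eff.index)
    genes = genes.sort_values()

    k = len(effects)
    G = len(genes)
    g_mat = np.full((k, G), np.nan)
    v_mat = np.full((k, G), np.nan)
    for i, eff in enumerate(effects):
        aligned = eff.reindex(genes)
        g_mat[i] = aligned["g"].to_numpy()
        v_mat[i] = aligned["v"].to_numpy()

    present = np.isfinite(g_mat) & np.isfinite(v_mat) & (v_mat > 0)
    n_studies = present.sum(axis=0)
    if (n_studies == 0).any():
        dropped = genes[n_studies == 0]
        logger.info("meta\tgenes_in_zero_studies\t%d", len(dropped))

    w = np.where(present, 1.0 / np.where(present, v_mat, 1.0), 0.0)
    sw = w.sum(axis=0)
    sw2 = (w**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g_fixed = np.nansum(np.where(present, w * g_mat, 0.0), axis=0) / sw
        Q = np.nansum(np.where(present, w * (g_mat - g_fixed) ** 2, 0.0), axis=0)
        c = sw - sw2 / sw
        tau2 = np.where(
            (n_studies > 1) & (c > 0),
            np.maximum(0.0, (Q - (n_studies - 1)) / np.where(c > 0, c, 1.0)),
            0.0,
        )
        w_star = np.where(present, 1.0 / (v_mat + tau2[None, :]), 0.0)
        sws = w_star.sum(axis=0)
        mu = np.nansum(np.where(present, w_star * g_mat, 0.0), axis=0) / sws
        z = mu * np.sqrt(sws)

    keep = n_studies > 0
    p = 2.0 * _sps.norm.sf(np.abs(z[keep]))
    table = pd.DataFrame(
        {
            "combined_es": mu[keep],
            "tau2": tau2[keep],
            "z": z[keep],
            "p": p,
            "fdr": adjust_bh(p),
            "n_studies": n_studies[keep].astype(int),
        },
        index=genes[keep],
    )
    table["direction"] = np.where(table["combined_es"] >= 0, "up", "down")
    table.index.name = "gene"
    return table


class RandomEffectsMeta:
    """Random-effects meta-analysis model over a collection of expression studies.

    Parameters
    ----------
    studies
        The :class:`ExpressionStudy` objects to combine.  Genes present in
        only a subset of studies are combined over the studies measuring
        them (``n_studies`` records how many).
    """

    def __init__(self, studies: Iterable[ExpressionStudy]):
        self.studies = list(studies)
        if not self.studies:
            raise ValueError("need at least one study")
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError("study_ids must be unique")

    @classmethod
    def from_files(cls, studies: Sequence[tuple[str, str | Path, str | Path]]
                   ) -> "RandomEffectsMeta":
        """Build the model from ``(study_id, expression_tsv, design_tsv)`` triples."""
        return cls(ExpressionStudy.from_files(*spec) for spec in studies)

    def fit(self) -> "MetaResults":
        effects = [compute_study_effects(s) for s in self.studies]
        table = combine_random_effects(effects, [s.study_id for s in self.studies])
        return MetaResults(model=self, table=table)


@dataclass
class MetaResults:
    """Fitted meta-analysis: per-gene combined effects, p-values, and FDR."""

    model: RandomEffectsMeta
    table: pd.DataFrame

    def call_degs(self, fdr_max: float = 0.05, es_min: float = 2.0) -> GeneSignature:
        """Differentially expressed genes: FDR < ``fdr_max`` and |effect| > ``es_min``.

        Both inequalities are strict.  Returns a directed signature with the
        up-set (combined effect > ``es_min``) and down-set (< ``-es_min``).
        """
        t = self.table
        sig = t["fdr"] < fdr_max
        up = set(t.index[sig & (t["combined_es"] > es_min)])
        down = set(t.index[sig & (t["combined_es"] < -es_min)])
        return GeneSignature(up=up, down=down)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["combined_es", "tau2", "z", "p", "fdr", "n_studies", "direction"]
        self.table[cols].to_csv(path, sep="\t", index_label="gene")

    def summary(self, fdr_max: float = 0.05, es_min: float = 2.0, top: int = 10) -> str:
        degs = self.call_degs(fdr_max, es_min)
        lines = [
            "Random-effects meta-analysis (DerSimonian-Laird)",
            f"  studies:  {len(self.model.studies)} "
            f"({', '.join(s.study_id for s in self.model.studies)})",
            f"  genes:    {len(self.table)}",
            f"  DEGs:     {len(degs)} at FDR<{fdr_max}, |ES|>{es_min} "
            f"({len(degs.up)} up, {len(degs.down)} down)",
            "",
            f"  top {top} genes by p-value:",
        ]
        head = self.table.nsmallest(top, "p")
        lines.append(
            head[["combined_es", "tau2", "z", "p", "fdr", "n_studies"]].to_string(
                float_format=lambda x: f"{x:.3g}"
            )
        )
        return "\n".join(lines)
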