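"""Anti-signature scoring of a query signature against a perturbagen library.

For every library signature the scorer computes the signed Jaccard
similarity

    J(q_up, s_up) + J(q_down, s_down) - J(q_up, s_down) - J(q_down, s_up)

(range [-2, 2]; -2 is a perfect reverser), an overlap p-value (one-sided
hypergeometric tail on the total up+down overlap against the gene
universe, direction-blind), a BH q-value across the library, a robust
z-score of the similarity against the library's similarity distribution
(median/MAD by default, mean/SD optionally), and the combined score
z * log10(p).  Hits are sorted ascending by similarity, most reversing
first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_gmt, write_gmt
from .signature import GeneSignature
from .stats import adjust_bh, hypergeom_tail

__all__ = [
    "LibrarySignature",
    "read_signature_library",
    "write_signature_library",
    "signed_jaccard",
    "score_library",
]

logger = logging.getLogger("dmdnet.anti_signature")

_MAD_TO_SD = 1.4826  # MAD of a normal distribution scaled to its SD


@dataclass(frozen=True)
class LibrarySignature:
    """One perturbagen signature: disjoint up/down gene sets."""

    sig_id: str
    perturbagen: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"{self.sig_id}: up and down sets overlap")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


def read_signature_library(path: str | Path) -> list[LibrarySignature]:
    """Read a paired-GMT library: ``<sig_id>_up`` / ``<sig_id>_down`` lines.

    The GMT description field carries the perturbagen name (falling back to
    the sig_id); a missing half of a pair is treated as empty.
    """
    ups: dict[str, tuple[str, list[str]]] = {}
    downs: dict[str, tuple[str, list[str]]] = {}
    for name, desc, genes in read_gmt(path):
        if name.endswith("_up"):
            ups[name[:-3]] = (desc, genes)
        elif name.endswith("_down"):
            downs[name[:-5]] = (desc, genes)
        else:
            raise ValueError(f"{path}: GMT set {name!r} lacks an _up/_down suffix")
    library = []
    for sig_id in sorted(set(ups) | set(downs)):
        desc_up, up = ups.get(sig_id, ("", []))
        desc_down, down = downs.get(sig_id, ("", []))
        perturbagen = desc_up or desc_down or sig_id
        if perturbagen == "na":
            perturbagen = sig_id
        library.append(
            LibrarySignature(sig_id=sig_id, perturbagen=perturbagen,
                             up=frozenset(up), down=frozenset(down))
        )
    return library


def write_signature_library(path: str | Path, library: list[LibrarySignature]) -> None:
    sets = []
    for sig in library:
        sets.append((f"{sig.sig_id}_up", sig.perturbagen, sorted(sig.up)))
        sets.append((f"{sig.sig_id}_down", sig.perturbagen, sorted(sig.down)))
    write_gmt(path, sets)


def _jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    if not a and not b:
        return 0.0
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def signed_jaccard(query: GeneSignature, sig: LibrarySignature) -> float:
    """Signed Jaccard similarity between a query and a library signature."""
    if not query.genes:
        raise ValueError("query signature is empty")
    return (
        _jaccard(query.up, sig.up)
        + _jaccard(query.down, sig.down)
        - _jaccard(query.up, sig.down)
        - _jaccard(query.down, sig.up)
    )


def score_library(query: GeneSignature, library: list[LibrarySignature],
                  universe_size: int, robust: bool = True) -> pd.DataFrame:
    """Score a query signature against a library; most reversing hits first.

    Columns: ``sig_id, perturbagen, similarity, p, q, z, combined`` with
    ``combined = z * log10(p)``.  ``universe_size`` must cover every gene-set
    union involved; ``robust`` selects median/MAD (default) or mean/SD
    standardization of the similarity scores.
    """
    if not library:
        raise ValueError("library is empty")
    q_genes = query.genes
    if not q_genes:
        raise ValueError("query signature is empty")

    sims = np.empty(len(library))
    pvals = np.empty(len(library))
    for i, sig in enumerate(library):
        union = len(q_genes | sig.genes)
        if universe_size < union:
            raise ValueError(
                f"universe_size {universe_size} smaller than the gene-set union "
                f"({union}) for {sig.sig_id}"
            )
        sims[i] = signed_jaccard(query, sig)
        overlap = len(q_genes & sig.genes)
        pvals[i] = hypergeom_tail(universe_size, len(q_genes), len(sig.genes), overlap)

    if robust:
        center = float(np.median(sims))
        scale = _MAD_TO_SD * float(np.median(np.abs(sims - center)))
        if scale == 0:
            logger.info("anti_signature\tmad_zero\tfalling back to SD scaling")
            scale = float(np.std(sims, ddof=1)) if len(sims) > 1 else 0.0
    else:
        center = float(np.mean(sims))
        scale = float(np.std(sims, ddof=1)) if len(sims) > 1 else 0.0
    z = (sims - center) / scale if scale > 0 else np.zeros_like(sims)

    with np.errstate(divide="ignore"):
        combined = z * np.log10(pvals)

    out = pd.DataFrame(
        {
            "sig_id": [s.sig_id for s in library],
            "perturbagen": [s.perturbagen for s in library],
            "similarity": sims,
            "p": pvals,
            "q": adjust_bh(pvals),
            "z": z,
            "combined": combined,
        }
    )
    return out.sort_values(["similarity", "sig_id"], kind="mergesort").reset_index(drop=True)
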