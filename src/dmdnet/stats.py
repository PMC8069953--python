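"""Exact enrichment statistics shared across the pipeline.

Every significance call in the package funnels through two primitives:
the upper tail of the hypergeometric distribution (``P(X >= k)`` for an
overlap of ``k`` between a marked set and a drawn set) and
Benjamini--Hochberg step-up adjustment of a family of p-values.  Keeping
them in one place guarantees that the drug-enrichment engine, the DIAMOnD
connectivity score, the set-overlap test, and the anti-signature scorer
all use the identical tail convention (one-sided, enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HypergeomParams",
    "PValueVector",
    "hypergeom_tail",
    "adjust_bh",
]


@dataclass(frozen=True)
class HypergeomParams:
    """Parameters of the one-sided overlap test.

    ``population_size`` is the background universe N, ``marked_count`` the
    marked subset K (e.g. the candidate-gene set), ``draw_count`` the number
    of draws n (e.g. a drug's targets), and ``observed_overlap`` the observed
    intersection k.
    """

    population_size: int
    marked_count: int
    draw_count: int
    observed_overlap: int

    def __post_init__(self) -> None:
        N, K, n, k = (
            self.population_size,
            self.marked_count,
            self.draw_count,
            self.observed_overlap,
        )
        if N < 0:
            raise ValueError(f"population_size must be >= 0, got {N}")
        if not 0 <= K <= N:
            raise ValueError(f"marked_count must satisfy 0 <= K <= N; got K={K}, N={N}")
        if not 0 <= n <= N:
            raise ValueError(f"draw_count must satisfy 0 <= n <= N; got n={n}, N={N}")
        if not 0 <= k <= min(K, n):
            raise ValueError(
                f"observed_overlap must satisfy 0 <= k <= min(K, n); "
                f"got k={k}, K={K}, n={n}"
            )

    def tail(self) -> float:
        return hypergeom_tail(
            self.population_size, self.marked_count, self.draw_count, self.observed_overlap
        )


def hypergeom_tail(population_size: int, marked_count: int, draw_count: int,
                   observed_overlap: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    X counts marked items among ``draw_count`` draws without replacement
    from a population of ``population_size`` containing ``marked_count``
    marked items.  The survival function is evaluated in scipy's
    log-space-capable implementation, so values far below double underflow
    of the naive sum (e.g. 1e-300) remain exact to machine precision.

    Parameters are validated through :class:`HypergeomParams`; a violated
    bound raises ``ValueError`` naming the bound.
    """
    params = HypergeomParams(population_size, marked_count, draw_count, observed_overlap)
    if params.observed_overlap == 0:
        return 1.0
    p = float(
        _sps.hypergeom.sf(
            params.observed_overlap - 1,
            params.population_size,
            params.marked_count,
            params.draw_count,
        )
    )
    # sf can return tiny negative numbers from cancellation on edge cases
    return min(1.0, max(0.0, p))


def adjust_bh(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values, in input order.

    Adjusted values are capped at 1 and monotone after the step-up
    smoothing; an empty input returns an empty array.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("adjust_bh expects a 1-d array of p-values")
    if arr.size == 0:
        return np.empty(0, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, fdr, _, _ = multipletests(arr, method="fdr_bh")
    return fdr


@dataclass
class PValueVector:
    """A family of tests: identifiers, raw p-values, and BH-adjusted values."""

    ids: list
    p: np.ndarray
    fdr: np.ndarray

    @classmethod
    def from_pvalues(cls, ids: Sequence, p: Sequence[float]) -> "PValueVector":
        if len(ids) != len(p):
            raise ValueError("ids and p must have equal length")
        arr = np.asarray(p, dtype=float)
        return cls(ids=list(ids), p=arr, fdr=adjust_bh(arr))
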