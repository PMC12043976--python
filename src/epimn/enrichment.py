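"""Gene-set overlap statistics and multiple-testing adjusters.

The central statistic is the one-tailed (upper) hypergeometric test: with N
universe genes of which K are m6A-modified, a target set of n genes showing k
modified members has P(X >= k) under random draws without replacement. The
upper tail is accumulated in log-space from gammaln-based log-PMF terms, so
it stays exact for the small counts where brute-force enumeration can verify
it and stable for genome-scale counts.

Benjamini-Hochberg and Bonferroni adjusters are thin, validated wrappers
around statsmodels' multipletests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .genome import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "hypergeom_lower_tail",
    "gene_set_enrichment",
    "adjust_bh",
    "adjust_bonferroni",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap counts, fractions, and upper-tail p for one target set.

    k = modified members of the target set, n = target-set size,
    K = modified genes in the universe, N = universe size.
    """

    k: int
    n: int
    K: int
    N: int
    p_upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N
                and self.K <= self.N):
            raise ValueError(
                f"inconsistent counts k={self.k}, n={self.n}, K={self.K}, N={self.N}"
            )

    @property
    def fraction_set(self) -> float:
        """k/n — fraction of the target set that is modified."""
        return self.k / self.n

    @property
    def fraction_universe(self) -> float:
        """K/N — fraction of the universe that is modified."""
        return self.K / self.N

    def report(self) -> dict:
        """Presentation-rounded summary (percentages at 2 dp)."""
        return {
            "k": self.k,
            "n": self.n,
            "K": self.K,
            "N": self.N,
            "percent_set": round(100 * self.fraction_set, 2),
            "percent_universe": round(100 * self.fraction_universe, 2),
            "p_upper": float(f"{self.p_upper:.4g}"),
        }


def _log_pmf(i: np.ndarray, K: int, n: int, N: int) -> np.ndarray:
    """log P(X = i) for X ~ Hypergeometric(N, K, n) via log-binomials."""
    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(K, i) + logc(N - K, n - i) - logc(N, n)


def _validate(k: int, K: int, n: int, N: int) -> None:
    if N <= 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("counts must be nonnegative with N > 0")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log-space.

    Exactly 1.0 for k = 0 (or any k at or below the distribution's support
    minimum).
    """
    _validate(k, K, n, N)
    lo = max(0, n - (N - K))  # support minimum
    if k <= lo:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    if i.size == 0:
        return 0.0
    return float(np.exp(logsumexp(_log_pmf(i, K, n, N))))


def hypergeom_lower_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X <= k); complements :func:`hypergeom_upper_tail` at k+1."""
    _validate(max(k, 0), K, n, N)
    hi = min(n, K)
    if k >= hi:
        return 1.0
    i = np.arange(max(0, n - (N - K)), k + 1)
    if i.size == 0:
        return 0.0
    return float(np.exp(logsumexp(_log_pmf(i, K, n, N))))


def gene_set_enrichment(
    modified: GeneSet, target: GeneSet, universe: GeneSet
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``modified`` within ``target``.

    Both ``target`` and ``modified`` are intersected with the universe first
    (logged when members fall outside it), so the counts are always
    consistent.
    """
    uni = universe.members
    if not uni:
        raise ValueError("empty universe")
    tgt = target.members & uni
    mod = modified.members & uni
    if len(tgt) < len(target.members):
        logger.info(
            "%d target gene(s) outside the universe dropped",
            len(target.members) - len(tgt),
        )
    if len(mod) < len(modified.members):
        logger.info(
            "%d modified gene(s) outside the universe dropped",
            len(modified.members) - len(mod),
        )
    if not tgt:
        raise ValueError("target set has no members inside the universe")
    k = len(mod & tgt)
    result = EnrichmentResult(
        k=k,
        n=len(tgt),
        K=len(mod),
        N=len(uni),
        p_upper=hypergeom_upper_tail(len(mod & tgt), len(mod), len(tgt), len(uni)),
    )
    return result


def _check_unit_interval(raw) -> np.ndarray:
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr))):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def adjust_bh(raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = _check_unit_interval(raw)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def adjust_bonferroni(raw) -> np.ndarray:
    """Bonferroni adjustment min(p * m, 1), input order preserved."""
    arr = _check_unit_interval(raw)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="bonferroni")[1]
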