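"""Hypergeometric over-representation of one gene set in another.

Used to test whether tissue-preferentially expressed genes are enriched among
DMV genes: with a universe of N genes of which K are in set A, drawing the n
genes of set B without replacement, the p-value is the upper tail
P(X >= k) for the observed overlap k (k itself included, the standard
over-representation convention).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .io import ValidationError


@dataclass(frozen=True)
class EnrichmentResult:
    universe_size: int  # N
    set_a_size: int  # K
    set_b_size: int  # n
    overlap: int  # k
    p_value: float
    fold_enrichment: float


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    scipy evaluates the tail in log space internally, so the result is stable
    far into the tail (p << 1e-16 does not underflow to a rounded 0 until the
    true value does).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"need 0 <= K <= N and 0 <= n <= N, got N={N} K={K} n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"need 0 <= k <= min(K, n), got k={k} K={K} n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def set_enrichment(set_a, set_b, universe) -> EnrichmentResult:
    """Enrichment of ``set_a`` in ``set_b`` against ``universe``.

    Both sets must be subsets of the universe; offenders are listed in the
    error.  The p-value is symmetric in (set_a, set_b).
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    for label, s in (("set_a", set_a), ("set_b", set_b)):
        extra = s - universe
        if extra:
            raise ValidationError(
                f"{label} has {len(extra)} element(s) outside the universe: "
                f"{sorted(extra)[:10]}"
            )
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    p = hypergeometric_upper_tail(N, K, n, k)
    fold = (k / n) / (K / N) if (n > 0 and K > 0) else float("nan")
    return EnrichmentResult(N, K, n, k, p, fold)
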