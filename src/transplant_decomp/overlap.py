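"""Exact hypergeometric set-overlap statistics.

All overlap claims in the pipeline (DE sets shared between environments,
constitutive genes shared between ecotype pairs, DE genes carrying divergence
outliers) reduce to the same question: drawing two subsets of sizes ``K`` and
``n`` independently from a universe of ``N`` genes, how surprising is an
intersection of at least ``k``?  The answer is the upper tail of the
hypergeometric distribution, computed here exactly in log space so that
p-values far below float-underflow of naive products (1e-147 and smaller)
remain meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["OverlapTest", "hypergeom_tail", "expected_overlap", "overlap_test"]


def _log_pmf(N: int, K: int, n: int, k: np.ndarray) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n), via log-gamma."""
    k = np.asarray(k, dtype=float)

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(K, k) + lchoose(N - K, n - k) - lchoose(N, n)


def _check_bounds(N: int, K: int, n: int, k: int) -> tuple[int, int]:
    if N <= 0:
        raise ValueError(f"universe size must be positive, got N={N}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"set sizes out of range: K={K}, n={n}, N={N}")
    lo = max(0, K + n - N)
    hi = min(K, n)
    if not (lo <= k <= hi):
        raise ValueError(
            f"observed overlap k={k} outside feasible range [{lo}, {hi}] "
            f"for N={N}, K={K}, n={n}"
        )
    return lo, hi


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    The sum is taken over whichever tail has fewer terms: the upper tail is
    accumulated directly with :func:`scipy.special.logsumexp` when it is the
    short side, otherwise the complement of the lower tail is used.  Either
    way every term is an exact log-pmf evaluation, so tiny tails keep full
    relative precision.

    Parameters
    ----------
    N, K, n, k
        Universe size, first set size, second set size, observed overlap.

    Returns
    -------
    float
        P(X >= k), in (0, 1]; exactly 1.0 when ``k`` is at its lower bound.
    """
    lo, hi = _check_bounds(N, K, n, k)
    if k <= lo:
        return 1.0
    upper = np.arange(k, hi + 1)
    lower = np.arange(lo, k)
    if len(upper) <= len(lower):
        return float(np.exp(logsumexp(_log_pmf(N, K, n, upper))))
    p = 1.0 - float(np.exp(logsumexp(_log_pmf(N, K, n, lower))))
    # complement can round to 0 only when the true tail is ~1e-16 yet has
    # more terms than the lower side; recompute directly in that case
    if p <= 0.0:
        return float(np.exp(logsumexp(_log_pmf(N, K, n, upper))))
    return min(p, 1.0)


def expected_overlap(N: int, K: int, n: int) -> float:
    """Chance expectation n*K/N of the overlap of two independent subsets."""
    if N <= 0:
        raise ValueError(f"universe size must be positive, got N={N}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"set sizes out of range: K={K}, n={n}, N={N}")
    return n * K / N


def round_half_away(x: float) -> int:
    """Round half away from zero, the convention used for printed expectations."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass
class OverlapTest:
    """Result of an exact two-set overlap test.

    Attributes
    ----------
    universe_size, set1_size, set2_size, observed
        The (N, K, n, k) of the hypergeometric model.
    expected
        Chance expectation ``n*K/N``.
    expected_rounded
        ``expected`` rounded half-away-from-zero, matching how chance
        expectations are typically printed.
    p_upper
        Exact P(X >= k).
    intersection
        Sorted members of the observed intersection (empty when the test was
        built from sizes alone).
    """

    universe_size: int
    set1_size: int
    set2_size: int
    observed: int
    expected: float
    expected_rounded: int
    p_upper: float
    intersection: list[str] = field(default_factory=list)

    @classmethod
    def from_sizes(cls, N: int, K: int, n: int, k: int) -> "OverlapTest":
        exp = expected_overlap(N, K, n)
        return cls(N, K, n, k, exp, round_half_away(exp), hypergeom_tail(N, K, n, k))

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "set1_size": self.set1_size,
            "set2_size": self.set2_size,
            "observed": self.observed,
            "expected": self.expected,
            "expected_rounded": self.expected_rounded,
            "p_upper": self.p_upper,
            "intersection": list(self.intersection),
        }


def overlap_test(set1, set2, universe) -> OverlapTest:
    """Exact overlap test of two gene sets against a finite universe.

    Raises
    ------
    ValueError
        If any element of either set lies outside the universe (named in the
        message) — a silent subset would change N and bias the test.
    """
    set1, set2, universe = set(set1), set(set2), set(universe)
    for name, s in (("set1", set1), ("set2", set2)):
        stray = s - universe
        if stray:
            raise ValueError(
                f"{name} contains elements outside the universe: "
                f"{sorted(stray)[:5]}{'...' if len(stray) > 5 else ''}"
            )
    inter = sorted(set1 & set2)
    res = OverlapTest.from_sizes(len(universe), len(set1), len(set2), len(inter))
    res.intersection = inter
    return res
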