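"""Order-statistic null distribution of the log-ratio statistic and testing.

Under the null hypothesis that a gene is uninformative, its distance rank in
each of d clusters is an independent discrete-uniform draw on 1..p.  The
joint law of the minimum and maximum of those d ranks has a closed
inclusion-exclusion form, from which the exact pmf of

    V = ln( max / min )

follows by aggregating (min, max) pairs with equal reduced ratio.  With
several clustering runs the observed statistic is a sum of independent V's
(one per run, each with its own cluster count), whose distribution is
estimated by seeded Monte-Carlo simulation; upper-tail p-values use the
standard +1-corrected empirical estimator.  Genes with p > 0.9 (an
over-represented upper atom under the discrete null) are set aside before
Benjamini-Hochberg adjustment of the remainder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "NullSpec",
    "SelectionResult",
    "joint_minmax_pmf",
    "v_pmf",
    "count_rank_pairs",
    "count_distinct_ratios",
    "mc_null_sample",
    "pvalues",
    "bh_select",
]


@dataclass
class NullSpec:
    """Parameters of the multi-run null: gene count, cluster counts, replicates."""

    p: int
    ds: list[int]
    T: int = 20_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("p must be at least 2")
        if len(self.ds) == 0 or any(d < 2 for d in self.ds):
            raise ValueError("every run must have at least 2 clusters")
        if self.T < 1:
            raise ValueError("T must be positive")


@dataclass
class SelectionResult:
    """Per-gene statistic, Monte-Carlo p-value, BH q-value and selection flag.

    ``q_values`` is NaN for genes filtered out before adjustment
    (p > filter_threshold).
    """

    gene_ids: list[str]
    v_agg: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray      # NaN where filtered
    selected: np.ndarray      # bool
    alpha: float
    filter_threshold: float


def joint_minmax_pmf(p: int, d: int, k1: int, k2: int) -> float:
    """P(min = k1, max = k2) for d i.i.d. discrete-uniform ranks on 1..p.

    For ``k1 < k2`` this is the inclusion-exclusion expression
    ``((k2-k1+1)/p)^d + ((k2-k1-1)/p)^d - 2 ((k2-k1)/p)^d``; the diagonal
    ``k1 == k2`` (all d draws equal) has probability ``(1/p)^d`` — the
    k1 < k2 expression does not specialize correctly to the diagonal, so it
    is handled as its own case.
    """
    if not (1 <= k1 <= k2 <= p):
        raise ValueError(f"need 1 <= k1 <= k2 <= p, got k1={k1}, k2={k2}, p={p}")
    if d < 1:
        raise ValueError("d must be at least 1")
    if k1 == k2:
        return (1.0 / p) ** d
    w = k2 - k1
    return ((w + 1) / p) ** d + ((w - 1) / p) ** d - 2.0 * (w / p) ** d


def count_rank_pairs(p: int) -> int:
    """Number of (min, max) pairs with 1 <= min <= max <= p: p(p+1)/2."""
    if p < 1:
        raise ValueError("p must be positive")
    return p * (p + 1) // 2


def count_distinct_ratios(p: int) -> int:
    """Number of distinct values of max/min over 1 <= min <= max <= p.

    Each distinct ratio corresponds to a reduced fraction b/a with
    ``gcd(a, b) = 1`` and ``a <= b <= p``, giving ``1 + sum_{b=2..p} phi(b)``
    by an Euler-totient sieve.
    """
    if p < 1:
        raise ValueError("p must be positive")
    if p == 1:
        return 1
    phi = np.arange(p + 1, dtype=np.int64)
    for i in range(2, p + 1):
        if phi[i] == i:  # i is prime
            phi[i::i] -= phi[i::i] // i
    return 1 + int(phi[2:].sum())


def v_pmf(p: int, d: int, max_pairs: int = 5_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of V = ln(max/min) under the single-run null.

    Aggregates the joint (min, max) law over all pairs whose reduced ratio
    ``max/min`` coincides (ratios compared as integer fractions, never as
    floats).  Returns ``(values, probs)`` with values sorted ascending.

    Raises if the ``p(p+1)/2`` pair enumeration exceeds ``max_pairs``; at
    that scale use :func:`mc_null_sample` instead.
    """
    if p < 2 or d < 2:
        raise ValueError("need p >= 2 and d >= 2")
    n_pairs = count_rank_pairs(p)
    if n_pairs > max_pairs:
        raise ValueError(
            f"exact enumeration of {n_pairs} (min, max) pairs exceeds the cap "
            f"of {max_pairs}; use Monte-Carlo sampling instead"
        )
    mass: dict[tuple[int, int], float] = {}
    for k1 in range(1, p + 1):
        for k2 in range(k1, p + 1):
            g = math.gcd(k1, k2)
            key = (k2 // g, k1 // g)  # reduced (numerator, denominator)
            mass[key] = mass.get(key, 0.0) + joint_minmax_pmf(p, d, k1, k2)
    keys = sorted(mass.keys(), key=lambda nd: nd[0] / nd[1])
    values = np.array([math.log(num / den) for num, den in keys])
    probs = np.array([mass[k] for k in keys])
    return values, probs


def mc_null_sample(spec: NullSpec) -> np.ndarray:
    """T Monte-Carlo replicates of the summed multi-run null statistic.

    Each replicate draws, for every run t, ``d_t`` i.i.d. uniform ranks on
    1..p, forms ``ln(max/min)``, and sums over runs.
    """
    rng = np.random.default_rng(spec.seed)
    total = np.zeros(spec.T)
    for d in spec.ds:
        draws = rng.integers(1, spec.p + 1, size=(spec.T, d))
        total += np.log(draws.max(axis=1) / draws.min(axis=1))
    return total


def pvalues(v_agg: np.ndarray, null_samples: np.ndarray) -> np.ndarray:
    """Upper-tailed +1-corrected Monte-Carlo p-values in (0, 1].

    ``p_j = (1 + #{samples >= v_j}) / (T + 1)``.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("null sample set is empty")
    v_agg = np.asarray(v_agg, dtype=float)
    srt = np.sort(null_samples)
    T = srt.size
    n_ge = T - np.searchsorted(srt, v_agg, side="left")
    return (1.0 + n_ge) / (T + 1.0)


def bh_select(
    p_values: np.ndarray,
    alpha: float = 0.05,
    filter_threshold: float = 0.9,
    v_agg: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
) -> SelectionResult:
    """Filter clearly-null genes, then Benjamini-Hochberg select the rest.

    Genes with ``p > filter_threshold`` are excluded from the adjustment
    (their q-value is NaN and they are never selected); BH step-up at level
    ``alpha`` is applied to the remaining p-values.
    """
    p_values = np.asarray(p_values, dtype=float)
    m = p_values.size
    if np.any(p_values <= 0) or np.any(p_values > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if v_agg is None:
        v_agg = np.full(m, np.nan)
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(m)]
    keep = p_values <= filter_threshold
    q_values = np.full(m, np.nan)
    selected = np.zeros(m, dtype=bool)
    if np.any(keep):
        rej, q, _, _ = multipletests(p_values[keep], alpha=alpha, method="fdr_bh")
        q_values[keep] = q
        selected[keep] = rej
    else:
        logger.warning("all %d p-values exceed the %.2f filter; nothing to adjust", m, filter_threshold)
    return SelectionResult(
        gene_ids=list(gene_ids),
        v_agg=np.asarray(v_agg, dtype=float),
        p_values=p_values,
        q_values=q_values,
        selected=selected,
        alpha=alpha,
        filter_threshold=filter_threshold,
    )
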