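"""Statistical toolkit for SCRaMbLE cohorts.

Covers the deletion-enrichment screen (one-sided Fisher tests under a
Bonferroni family-wise threshold), exact Poisson rate-equality tests for
event-type counts, the Poisson null model for novel-junction functional
types, the essential-vs-nonessential amplification comparison, the
synthetic-lethal sample-size bound, and trajectory combinatorics for the
size of the explorable genome space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "fisher_one_sided",
    "deletion_enrichment",
    "rate_equality_test",
    "junction_type_null",
    "JunctionTypeStats",
    "amplification_group_test",
    "synthetic_lethal_sample_size",
    "trajectory_count",
]

JUNCTION_TYPES = ("CC", "CU", "CN", "UU", "UN", "NN")
_LABEL = {"CDS": "C", "UTR": "U", "NC": "N"}


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for enrichment of the top-left cell.

    Exact hypergeometric upper tail P(X >= a) with margins fixed, for the
    2x2 table [[a, b], [c, d]].
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    M, n, N = a + b + c + d, a + c, a + b
    if M == 0:
        return 1.0
    return float(sps.hypergeom.sf(a - 1, M, n, N))


def deletion_enrichment(
    deletion_matrix: np.ndarray, slow_mask: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Per-segment one-sided Fisher test for deletion enrichment in slow strains.

    ``deletion_matrix`` is strains x segments (1 = segment deleted);
    ``slow_mask`` flags the slower-growing strains.  Returns the per-segment
    p-values and the Bonferroni family-wise threshold alpha / L.
    """
    X = np.asarray(deletion_matrix, dtype=bool)
    slow = np.asarray(slow_mask, dtype=bool)
    if X.shape[0] != slow.shape[0]:
        raise ValueError("mask length must equal the number of strains")
    if slow.all() or not slow.any():
        raise ValueError("slow-strain mask must be non-degenerate")
    n_slow, n_fast = int(slow.sum()), int((~slow).sum())
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        a = int(X[slow, j].sum())  # deleted in slow
        c = int(X[~slow, j].sum())  # deleted in fast
        pvals[j] = fisher_one_sided(a, n_slow - a, c, n_fast - c)
    return pvals, alpha / X.shape[1]


def rate_equality_test(x: int, y: int, method: str = "double") -> float:
    """Exact two-sided test of equal Poisson rates from two counts.

    Conditional on x + y events, x is Binomial(x + y, 1/2) under equal
    rates.  ``method="double"`` doubles the smaller tail (capped at 1);
    ``method="minlike"`` sums all outcomes no more likely than x.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    n = x + y
    if n == 0:
        import warnings

        warnings.warn("rate test on two zero counts is uninformative; p = 1")
        return 1.0
    if method == "minlike":
        return float(sps.binomtest(x, n, 0.5).pvalue)
    if method != "double":
        raise ValueError("method must be 'double' or 'minlike'")
    lower = sps.binom.cdf(x, n, 0.5)
    upper = sps.binom.sf(x - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class JunctionTypeStats:
    T: int
    observed: dict[str, int]
    half_site_counts: dict[str, int]
    probabilities: dict[str, float]
    expected: dict[str, float]
    pvalues: dict[str, float]


def junction_type_null(annotated_novel_junctions: list[tuple[str, str]]) -> JunctionTypeStats:
    """Poisson null model for novel-junction functional types.

    Input: one (annotation, annotation) pair per distinct novel junction per
    strain (already deduplicated within each strain), with annotations in
    {CDS, UTR, NC}.  Half-site counts are n_C = 2*CC + CU + CN (cyclically
    for U and N); half-site probabilities p_X = n_X / 2T.  The expected count
    of an X-Y junction type is Poisson with mean T*p_X*p_Y (X != Y) or
    T*p_X^2 (X = Y), exactly as the counting scheme defines it; two-sided p
    doubles the smaller of the Poisson tails, capped at 1.
    """
    if not annotated_novel_junctions:
        raise ValueError("no novel junctions supplied")
    observed = {t: 0 for t in JUNCTION_TYPES}
    for a, b in annotated_novel_junctions:
        key = "".join(sorted((_LABEL[a], _LABEL[b])))
        key = {"CU": "CU", "CC": "CC", "CN": "CN", "NU": "UN", "UU": "UU", "NN": "NN"}[key]
        observed[key] += 1
    T = len(annotated_novel_junctions)
    n = {
        "C": 2 * observed["CC"] + observed["CU"] + observed["CN"],
        "U": 2 * observed["UU"] + observed["CU"] + observed["UN"],
        "N": 2 * observed["NN"] + observed["CN"] + observed["UN"],
    }
    total = sum(n.values())  # = 2T
    p = {k: v / total for k, v in n.items()}
    expected, pvalues = {}, {}
    for t in JUNCTION_TYPES:
        x, y = t[0], t[1]
        mean = T * p[x] * p[y] if x != y else T * p[x] ** 2
        expected[t] = mean
        obs = observed[t]
        lower = sps.poisson.cdf(obs, mean) if mean > 0 else float(obs == 0)
        upper = sps.poisson.sf(obs - 1, mean) if mean > 0 else float(obs == 0)
        pvalues[t] = float(min(1.0, 2.0 * min(lower, upper)))
    return JunctionTypeStats(
        T=T, observed=observed, half_site_counts=n, probabilities=p,
        expected=expected, pvalues=pvalues,
    )


def amplification_group_test(
    amplified_strain_counts, essential_mask, welch: bool = False
) -> float:
    """Two-sided t-test: strains-amplified counts, essential vs nonessential.

    Pooled-variance Student t by default; Welch optional.
    """
    counts = np.asarray(amplified_strain_counts, dtype=float)
    mask = np.asarray(essential_mask, dtype=bool)
    g1, g2 = counts[mask], counts[~mask]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two segments")
    res = sps.ttest_ind(g1, g2, equal_var=not welch)
    return float(res.pvalue)


def synthetic_lethal_sample_size(
    T: int, d: float, alpha: float = 0.05, exact: bool = False
) -> float:
    """Strains needed to detect synthetic-lethal pairs among T nonessential genes.

    With per-gene deletion fraction d, a pair is co-deleted with probability
    d^2 per strain; significance at level alpha over P = T(T-1)/2 tested
    pairs requires exp(-N d^2) < alpha/P.  The default returns the
    large-T shorthand (2 ln T + ln 10)/d^2 (for alpha = 0.05); ``exact=True``
    returns ln(P/alpha)/d^2.
    """
    if T < 2:
        raise ValueError("T must be at least 2")
    if not 0 < d < 1:
        raise ValueError("d must be in (0, 1)")
    if exact:
        P = T * (T - 1) / 2
        return math.log(P / alpha) / d**2
    return (2 * math.log(T) + math.log(10)) / d**2


def trajectory_count(
    n_sites: int, k_events: int, mode: str = "deletions_and_inversions"
) -> int:
    """Exact number of k-event recombination trajectories over n loxPsym sites.

    Each event picks an unordered pair of sites, C(n, 2) ways, doubled when
    both deletion and inversion outcomes are counted; trajectories multiply.
    """
    if n_sites < 2 or k_events < 0:
        raise ValueError("need n_sites >= 2 and k_events >= 0")
    per_event = math.comb(n_sites, 2)
    if mode == "deletions_and_inversions":
        per_event *= 2
    elif mode != "inversions_only":
        raise ValueError("mode must be 'inversions_only' or 'deletions_and_inversions'")
    return per_event**k_events
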