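"""Statistical layer: chi-square enrichment, BH-FDR, t-tests, MSEA.

Thin, explicit wrappers over scipy.stats and statsmodels so every test
used in the analysis has a single definition with its
conventions baked in: Pearson chi-square without continuity correction,
step-up Benjamini-Hochberg, one-sample two-tailed t, one-sided
hypergeometric over-representation for metabolite set enrichment, and a
rank-based two-sample comparison for numeric lipid properties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ContingencyTable:
    """2x2 counts: rows = in/out of the metabolite set, columns = attribute."""

    counts: np.ndarray  # shape (2, 2)
    row_labels: tuple[str, str] = ("in_set", "out_of_set")
    col_labels: tuple[str, str] = ("with_attribute", "without_attribute")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("grand total must be positive")


@dataclass
class EnrichmentResult:
    table: ContingencyTable
    chi2_statistic: float
    p_value: float
    direction: str  # enriched | depleted | none
    significant: bool
    label: str = ""
    q_value: Optional[float] = None


def contingency_from_sets(
    query: set, attribute: set, background: set,
    label: str = "",
) -> ContingencyTable:
    """Build the 2x2 table for set-vs-attribute association over a background."""
    if not background:
        raise ValueError("empty background")
    q = query & background
    a = attribute & background
    n11 = len(q & a)
    n10 = len(q - a)
    n01 = len(a - q)
    n00 = len(background) - n11 - n10 - n01
    return ContingencyTable(np.array([[n11, n10], [n01, n00]], dtype=float))


def chi_square_enrichment(
    table: ContingencyTable, alpha: float = 0.05, label: str = ""
) -> EnrichmentResult:
    """Pearson chi-square (df=1, no continuity correction), upper-tail p.

    Direction compares the observed (set, attribute) cell with its
    expectation under independence.  A zero marginal makes the test
    undefined; p = 1 is returned with a warning.
    """
    c = table.counts
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    n = c.sum()
    if (row == 0).any() or (col == 0).any():
        warnings.warn("zero marginal in contingency table; chi-square undefined")
        return EnrichmentResult(table, 0.0, 1.0, "none", False, label)
    chi2, p, _, expected = stats.chi2_contingency(c, correction=False)
    direction = "enriched" if c[0, 0] > expected[0, 0] else (
        "depleted" if c[0, 0] < expected[0, 0] else "none"
    )
    return EnrichmentResult(
        table, float(chi2), float(p), direction, bool(p < alpha), label
    )


def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH: returns (q_values, reject flags) at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def one_sample_t(values: Sequence[float], mu0: float) -> tuple[float, float]:
    """One-sample two-tailed t-test of `values` against mean mu0.

    Zero-variance samples are degenerate for t: if the common value
    equals mu0 the null is exactly true (t=0, p=1); otherwise the
    deviation is noiseless and p=0 is returned with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a t-test")
    if np.ptp(x) == 0.0:
        if x[0] == mu0:
            return 0.0, 1.0
        warnings.warn("zero-variance sample differing from mu0; p set to 0")
        return float("inf") if x[0] > mu0 else float("-inf"), 0.0
    t, p = stats.ttest_1samp(x, popmean=mu0)
    return float(t), float(p)


def pathway_enrichment(
    query_set: set,
    pathway_annotation: Mapping[str, set],
    background_set: set,
    q: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation (MSEA) of a metabolite set in each pathway.

    One-sided hypergeometric test per pathway: drawing |query| metabolites
    from the background, how surprising is the observed overlap with the
    pathway?  BH is applied across pathways; ``significant`` reflects the
    BH decision at level ``q``.  "No pathway significant" is a valid
    verdict.
    """
    if not background_set:
        raise ValueError("empty background")
    if not set(query_set) <= set(background_set):
        raise ValueError("query set must be contained in the background")
    M = len(background_set)
    N = len(query_set)
    results: list[EnrichmentResult] = []
    pvals = []
    for pid in sorted(pathway_annotation):
        members = set(pathway_annotation[pid]) & background_set
        n = len(members)
        k = len(set(query_set) & members)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        p = min(p, 1.0)
        table = contingency_from_sets(set(query_set), members, set(background_set))
        expected = N * n / M if M else 0.0
        direction = "enriched" if k > expected else ("depleted" if k < expected else "none")
        results.append(EnrichmentResult(table, float("nan"), p, direction, False, pid))
        pvals.append(p)
    if pvals:
        qvals, reject = benjamini_hochberg(pvals, q)
        for res, qv, rej in zip(results, qvals, reject):
            res.significant = bool(rej)
            res.q_value = float(qv)
    return results


def compare_numeric_property(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two numeric samples.

    Used for lipid chain-length / saturation comparisons.  The null is
    exact for small samples (both n <= 8) and normal-approximated with
    tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size <= 8 and b.size <= 8 and
                         np.unique(np.concatenate([a, b])).size == a.size + b.size) \
        else "auto"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(u), float(p)
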