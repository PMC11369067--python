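"""Exact, asymptotic and permutation statistics for cohort comparisons.

Covers the tests used to compare engraftment scores and clinical outcomes
across pretreatment arms and donors: Fisher's exact test (point-probability
two-sided convention), the chi-square test, the exact Wilcoxon rank-sum test,
two-way ANOVA with Type II sums of squares, alpha-diversity indices,
PERMANOVA on a distance matrix, and complete-linkage clustering of donor
family-level profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova

from .profiles_io import DEFAULT_TAU


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_permutations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    observed_species: int
    shannon: float  # natural-log units


@dataclass(frozen=True)
class LinkageTree:
    """Complete-linkage merge structure over donor profiles."""

    linkage: np.ndarray  # scipy condensed linkage matrix
    labels: tuple[str, ...]
    method: str = "complete"
    metric: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def fisher_exact_2x2(a: int, b: int, c: int, d: int, convention: str = "point-probability") -> TestResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The default point-probability convention sums the hypergeometric
    probabilities of every table with the observed margins whose point
    probability does not exceed the observed one; the computation is exact
    integer arithmetic.  ``convention="doubling"`` doubles the smaller
    one-sided tail instead (capped at 1).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate margin in 2x2 table; p-value is 1", stacklevel=2)
        return TestResult(statistic=odds, p_value=1.0, method="fisher-exact-degenerate")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # integer table weights: P(k) = weight(k) / comb(n, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    observed = weights[a]
    total = comb(n, c1)
    if convention == "point-probability":
        num = sum(w for w in weights.values() if w <= observed)
    elif convention == "doubling":
        lower = sum(w for k, w in weights.items() if k <= a)
        upper = sum(w for k, w in weights.items() if k >= a)
        num = min(2 * min(lower, upper), total)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return TestResult(statistic=odds, p_value=num / total, method=f"fisher-exact-{convention}")


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table (1 df)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for a table with a zero margin")
    res = ss.chi2_contingency(table, correction=yates)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="chi-square" + ("-yates" if yates else ""))


def wilcoxon_rank_sum_exact(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when both group sizes are <= 12 and the pooled
    data are tie-free; otherwise mid-ranks with the tie-corrected normal
    approximation.  The method actually used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size <= 12 and y.size <= 12:
        res = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="wilcoxon-exact")
    res = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), method="wilcoxon-normal-approx")


def two_way_anova(score, factor_a, factor_b) -> dict[str, TestResult]:
    """Two-way ANOVA (additive model, Type II sums of squares) per factor.

    Suits the unbalanced two-arm, two-donor design: each factor's F tests its
    effect while controlling for the other, with no interaction term.  A
    response with zero variance yields F = 0, p = 1 for both factors.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"score": np.asarray(score, dtype=float), "a": list(factor_a), "b": list(factor_b)})
    for name in ("a", "b"):
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has a single observed level")
    if np.ptp(df["score"].to_numpy()) == 0:
        null = TestResult(statistic=0.0, p_value=1.0, method="two-way-anova-typeII-degenerate")
        return {"factor_a": null, "factor_b": null}
    fit = smf.ols("score ~ C(a) + C(b)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return {
        "factor_a": TestResult(float(table.loc["C(a)", "F"]), float(table.loc["C(a)", "PR(>F)"]), "two-way-anova-typeII"),
        "factor_b": TestResult(float(table.loc["C(b)", "F"]), float(table.loc["C(b)", "PR(>F)"]), "two-way-anova-typeII"),
    }


def diversity(sample: pd.Series, tau: float = DEFAULT_TAU, sample_id: str | None = None) -> DiversityResult:
    """Richness (observed species >= tau) and Shannon diversity (natural log).

    The detected sub-composition is re-closed to sum 1 before computing
    H = -sum p_i ln p_i.
    """
    detected = sample[sample >= tau]
    if detected.empty:
        raise ValueError("no species detected in sample")
    p = detected.to_numpy(dtype=float)
    p = p / p.sum()
    shannon = float(-(p * np.log(p)).sum())
    return DiversityResult(
        sample_id=sample_id if sample_id is not None else str(sample.name),
        observed_species=int(detected.size),
        shannon=shannon,
    )


def permanova(
    distance_matrix: pd.DataFrame | np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int = 0,
) -> TestResult:
    """PERMANOVA pseudo-F with a label-permutation p-value.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations); the seed
    makes the permutation stream reproducible.
    """
    labels = list(labels)
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    if isinstance(distance_matrix, pd.DataFrame):
        dm = DistanceMatrix(distance_matrix.to_numpy(), ids=[str(i) for i in distance_matrix.index])
    else:
        dm = DistanceMatrix(np.asarray(distance_matrix, dtype=float))
    res = _skbio_permanova(dm, labels, permutations=n_permutations, seed=seed)
    return TestResult(
        statistic=float(res["test statistic"]),
        p_value=float(res["p-value"]),
        method="permanova",
        n_permutations=n_permutations,
        seed=seed,
    )


def donor_family_clustering(mean_family_abundances: pd.DataFrame) -> LinkageTree:
    """Complete-linkage hierarchical clustering of donors on Euclidean distance.

    Rows are donors, columns mean family-level relative abundances across each
    donor's samples.  Duplicate donor profiles merge at height 0.
    """
    if len(mean_family_abundances) < 2:
        raise ValueError("need >= 2 donors to cluster")
    Z = sch.linkage(mean_family_abundances.to_numpy(dtype=float), method="complete", metric="euclidean")
    return LinkageTree(linkage=Z, labels=tuple(str(i) for i in mean_family_abundances.index))


def mean_family_abundances(profiles: pd.DataFrame, family_of_species: pd.Series, by: pd.Series) -> pd.DataFrame:
    """Aggregate species columns to families, then average samples per donor.

    ``family_of_species`` maps species id -> family name; ``by`` maps sample
    id -> donor id.
    """
    families = profiles.T.groupby(family_of_species.reindex(profiles.columns)).sum().T
    return families.groupby(by.reindex(profiles.index)).mean()
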