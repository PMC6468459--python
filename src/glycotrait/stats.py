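"""Group statistics: trait comparison, PCA, differential genes, regressions.

Trait group contrasts use the exact two-sided Mann-Whitney U test (exact for
group sizes up to 10, normal approximation with tie correction otherwise),
with Bonferroni correction over the emitted traits.  Gene differential
expression uses a two-sided Welch t-test on the log2 matrix, with fold
changes on the linear scale; trait-gene association is ordinary least
squares per pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA

__all__ = [
    "AssociationResult",
    "mann_whitney_traits",
    "pca_profiles",
    "gene_differential",
    "trait_gene_regression",
    "cdx1_fold_ratio",
    "bonferroni",
]


@dataclass
class AssociationResult:
    """One feature's test result in a group contrast or regression."""

    feature: str
    statistic: float
    p_raw: float
    p_adjusted: float
    fold_change: float | None = None
    mean_high: float | None = None
    mean_low: float | None = None

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_adjusted,
            "fold_change": self.fold_change,
            "mean_high": self.mean_high,
            "mean_low": self.mean_low,
        }


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(m * p, 1)."""
    return float(min(p * m, 1.0))


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results]).set_index("feature")


def _split_groups(values: pd.DataFrame, groups: pd.Series) -> tuple[pd.Index, pd.Index]:
    groups = groups.reindex(values.index)
    if groups.isna().any():
        missing = values.index[groups.isna()].tolist()
        raise ValueError(f"samples without group label: {missing}")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    # 'high' / 'low' naming preferred; otherwise first level plays 'high'
    if set(levels) == {"high", "low"}:
        hi, lo = "high", "low"
    else:
        hi, lo = levels[0], levels[1]
    return values.index[groups == hi], values.index[groups == lo]


def mann_whitney_traits(
    traits: pd.DataFrame,
    groups: pd.Series,
    exact_max_n: int = 10,
) -> list[AssociationResult]:
    """Two-sided Mann-Whitney U per trait with Bonferroni over the table.

    The Bonferroni family is the number of traits actually tested (columns
    with data in both groups).  Constant traits give p = 1 with a warning.
    """
    hi_idx, lo_idx = _split_groups(traits, groups)
    tested = [
        c for c in traits.columns
        if traits.loc[hi_idx, c].notna().any() and traits.loc[lo_idx, c].notna().any()
    ]
    m = len(tested)
    results = []
    for col in tested:
        a = traits.loc[hi_idx, col].dropna().to_numpy()
        b = traits.loc[lo_idx, col].dropna().to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"trait {col!r} is constant across both groups; p = 1")
            u, p = len(a) * len(b) / 2.0, 1.0
        else:
            has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
            method = (
                "exact"
                if max(a.size, b.size) <= exact_max_n and not has_ties
                else "asymptotic"
            )
            u, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        results.append(
            AssociationResult(
                feature=col, statistic=float(u), p_raw=float(p),
                p_adjusted=bonferroni(p, m),
                mean_high=float(a.mean()), mean_low=float(b.mean()),
                fold_change=float(a.mean() / b.mean()) if b.mean() > 0 else None,
            )
        )
    return results


def pca_profiles(
    profiles: pd.DataFrame,
    n_components: int = 4,
    scale: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of per-sample glycan abundances (samples x compositions).

    Columns are mean-centred and, by default, scaled to unit variance.
    Returns (scores, loadings, explained variance fractions).  The sign of
    each component is fixed so its largest-|loading| element is positive.
    """
    if profiles.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    x = profiles.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    rank = int(np.linalg.matrix_rank(x))
    k = min(n_components, rank, *x.shape)
    if k < n_components:
        warnings.warn(f"n_components truncated from {n_components} to rank {k}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_
    for j in range(k):  # deterministic sign convention
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(k)]
    return (
        pd.DataFrame(scores, index=profiles.index, columns=names),
        pd.DataFrame(loadings, index=names, columns=profiles.columns),
        pca.explained_variance_ratio_,
    )


def gene_differential(
    expression: pd.DataFrame,
    groups: pd.Series,
    gene_subset: "list[str] | None" = None,
    equal_var: bool = False,
) -> list[AssociationResult]:
    """Per-gene two-sided t-test (Welch by default) on a log2 matrix.

    ``expression`` is genes x samples.  Fold change = 2^(mean_high -
    mean_low).  Bonferroni over the tested subset; genes absent from the
    matrix are reported with NaN statistics rather than dropped silently.
    """
    if gene_subset is None:
        from .reference import GLYCO_GENE_PANEL

        gene_subset = [g for g in GLYCO_GENE_PANEL] + ["CDX1"]
        gene_subset = list(dict.fromkeys(gene_subset))
    hi_idx, lo_idx = _split_groups(expression.T, groups)
    present = [g for g in gene_subset if g in expression.index]
    m = len(present)
    results = []
    for gene in gene_subset:
        if gene not in expression.index:
            results.append(AssociationResult(gene, np.nan, np.nan, np.nan))
            continue
        a = expression.loc[gene, hi_idx].to_numpy(dtype=float)
        b = expression.loc[gene, lo_idx].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
        diff = float(a.mean() - b.mean())
        results.append(
            AssociationResult(
                feature=gene, statistic=float(t), p_raw=float(p),
                p_adjusted=bonferroni(float(p), m),
                fold_change=float(2.0 ** diff),
                mean_high=float(a.mean()), mean_low=float(b.mean()),
            )
        )
    return results


def trait_gene_regression(
    traits: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """OLS of trait (%) on gene log2 expression for each (trait, gene) pair.

    Samples are paired by name across the two tables; fewer than three
    paired samples is an error.  Returns slope, intercept, R^2 and the
    two-sided p-value for the slope, Bonferroni-adjusted over the pairs.
    """
    shared = traits.index.intersection(expression.columns)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired samples, found {len(shared)}")
    m = len(pairs)
    rows = []
    for trait, gene in pairs:
        x = expression.loc[gene, shared].to_numpy(dtype=float)
        y = traits.loc[shared, trait].to_numpy(dtype=float)
        fit = scipy.stats.linregress(x, y)
        rows.append(
            {
                "trait": trait, "gene": gene,
                "slope": fit.slope, "intercept": fit.intercept,
                "r2": fit.rvalue**2, "p_raw": fit.pvalue,
                "p_bonferroni": bonferroni(fit.pvalue, m),
            }
        )
    return pd.DataFrame(rows).set_index(["trait", "gene"])


def cdx1_fold_ratio(high_values, low_values) -> float:
    """Ratio of arithmetic group means (high / low) on the linear scale."""
    high = np.asarray(list(high_values), dtype=float)
    low = np.asarray(list(low_values), dtype=float)
    if low.mean() == 0:
        raise ZeroDivisionError("low-group mean expression is zero")
    return float(high.mean() / low.mean())
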