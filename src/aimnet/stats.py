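"""Nonparametric group statistics: K-S screening, rank-sum contrasts,
Spearman performance correlations, and Benjamini-Hochberg FDR.

The workflow replicated here screens every feature family with a
one-sample Kolmogorov-Smirnov test against a fitted normal, then — as
the screening is only reported, never trusted — always proceeds
nonparametrically: two-sided Wilcoxon rank-sum tests for condition
contrasts (edgewise over the 435 channel pairs, nodewise over the 30
channels, and on global metrics) and Spearman rank correlations between
network features and mean ring scores, each family corrected by the
Benjamini-Hochberg step-up FDR procedure. Significance tiers 0.05 /
0.01 are carried through as flags.

The rank-sum test uses exact two-sided p-values by enumeration when the
pooled sample is small (n_a + n_b <= 12) and tie-free, otherwise the
normal approximation with midranks, tie correction, and a continuity
correction. The contrasts are unpaired, matching the replicated
workflow, even though the underlying design is within-subject; a paired
signed-rank alternative is available via ``paired=True``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "CorrelationResult",
    "ks_normality",
    "wilcoxon_ranksum",
    "spearman",
    "fdr_bh",
    "edgewise_compare",
    "nodewise_compare",
    "correlate_with_performance",
]

ALPHA_SIGNIFICANT = 0.05
ALPHA_HIGHLY_SIGNIFICANT = 0.01


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    n_a: int
    n_b: int
    feature_id: str = ""
    contrast: str = ""
    p_adjusted: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot undercut the raw p")


@dataclass
class CorrelationResult:
    rho: float
    p_raw: float
    n: int
    feature_id: str = ""
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("|rho| cannot exceed 1")


def ks_normality(sample) -> TestResult:
    """One-sample K-S test against a normal fitted to the sample.

    Used purely as a screening gate: the result is reported but the
    pipeline proceeds nonparametrically regardless. The p-value comes
    from the asymptotic K-S distribution with the sample mean and
    (ddof=1) standard deviation plugged in.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("K-S screening needs at least 4 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample; K-S test undefined")
    stat, p = sst.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(
        statistic=float(stat), p_raw=float(p), n_a=x.size, n_b=0,
        method="ks_fitted_normal",
    )


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all assignments of ranks to group a."""
    pooled = np.concatenate([a, b])
    ranks = sst.rankdata(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - mu) >= obs_dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_ranksum(a, b, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode``: ``"exact"`` enumerates every rank assignment (feasible for
    small samples), ``"approx"`` uses the normal approximation with
    midranks, tie correction and continuity correction, ``"auto"``
    (default) picks exact when n_a + n_b <= 12 and there are no ties.
    The reported statistic is the rank sum of sample ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= 12 and not has_ties) else "approx"
    ranks = sst.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    n_a, n_b, n = a.size, b.size, pooled.size
    mu = n_a * (n + 1) / 2.0
    if mode == "exact":
        p = _exact_ranksum_p(a, b)
    elif mode == "approx":
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0 or w == mu:
            p = 1.0
        else:
            z = (abs(w - mu) - 0.5) / np.sqrt(var)  # continuity correction
            p = float(min(1.0, 2.0 * sst.norm.sf(max(z, 0.0))))
    else:
        raise ValueError(f"mode must be 'auto', 'exact' or 'approx', got {mode!r}")
    return TestResult(statistic=w, p_raw=p, n_a=n_a, n_b=n_b, method=f"ranksum_{mode}")


def wilcoxon_signedrank(a, b) -> TestResult:
    """Paired signed-rank alternative for the within-subject design."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = sst.wilcoxon(a, b, zero_method="wilcox", correction=True)
    return TestResult(
        statistic=float(res.statistic), p_raw=float(res.pvalue),
        n_a=a.size, n_b=b.size, method="signedrank_paired",
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the t-approximation p (n - 2 d.f.)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("Spearman needs at least 4 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input; rank correlation undefined")
    rho, p = sst.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_raw=float(p), n=x.size)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def _compare_features(
    feat_a: np.ndarray,
    feat_b: np.ndarray,
    feature_ids: list[str],
    contrast: str,
    alpha: float,
    paired: bool,
) -> pd.DataFrame:
    rows = []
    for j, fid in enumerate(feature_ids):
        if paired:
            r = wilcoxon_signedrank(feat_a[:, j], feat_b[:, j])
        else:
            r = wilcoxon_ranksum(feat_a[:, j], feat_b[:, j])
        diff = float(np.median(feat_a[:, j]) - np.median(feat_b[:, j]))
        rows.append(
            {
                "feature_id": fid,
                "contrast": contrast,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "direction": "a>b" if diff > 0 else ("a<b" if diff < 0 else "a=b"),
                "n_a": r.n_a,
                "n_b": r.n_b,
                "method": r.method,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = fdr_bh(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    df["highly_significant"] = df["p_adjusted"] < ALPHA_HIGHLY_SIGNIFICANT
    return df


def edgewise_compare(
    matrices_a,
    matrices_b,
    channel_labels,
    alpha: float = ALPHA_SIGNIFICANT,
    contrast: str = "A_vs_B",
    paired: bool = False,
) -> pd.DataFrame:
    """Rank-sum test per upper-triangle edge, FDR across all edges.

    ``matrices_a``/``matrices_b`` are stacks (subjects x channels x
    channels) of per-subject connectivity matrices from the two cohorts.
    Returns a tidy frame with one row per edge (chan_a, chan_b) carrying
    raw and adjusted p-values and the signed direction of the median
    difference.
    """
    a = np.asarray([getattr(m, "values", m) for m in matrices_a], dtype=float)
    b = np.asarray([getattr(m, "values", m) for m in matrices_b], dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per cohort")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("cohorts carry different channel sets")
    n_ch = a.shape[1]
    iu, ju = np.triu_indices(n_ch, k=1)
    feat_a = a[:, iu, ju]
    feat_b = b[:, iu, ju]
    ids = [f"{channel_labels[i]}-{channel_labels[j]}" for i, j in zip(iu, ju)]
    df = _compare_features(feat_a, feat_b, ids, contrast, alpha, paired)
    df.insert(0, "chan_a", [channel_labels[i] for i in iu])
    df.insert(1, "chan_b", [channel_labels[j] for j in ju])
    return df


def nodewise_compare(
    vectors_a,
    vectors_b,
    node_labels,
    alpha: float = ALPHA_SIGNIFICANT,
    contrast: str = "A_vs_B",
    paired: bool = False,
) -> pd.DataFrame:
    """Rank-sum test per node (subjects x nodes stacks), FDR across nodes."""
    a = np.atleast_2d(np.asarray(vectors_a, dtype=float))
    b = np.atleast_2d(np.asarray(vectors_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per cohort")
    if a.shape[1] != b.shape[1]:
        raise ValueError("cohorts carry different node sets")
    return _compare_features(a, b, list(node_labels), contrast, alpha, paired)


def correlate_with_performance(
    features: pd.DataFrame,
    scores: pd.Series,
    alpha: float = ALPHA_SIGNIFICANT,
) -> pd.DataFrame:
    """Spearman correlation of each feature column with mean scores.

    ``features`` is subjects x features (index = subject ids); ``scores``
    is the per-subject mean ring score with the same index. FDR is
    applied across the feature columns (one family per call).
    """
    if not features.index.equals(scores.index):
        raise ValueError("subject ids of features and scores are misaligned")
    if len(scores) < 5:
        raise ValueError("need at least 5 subjects for performance correlation")
    rows = []
    for col in features.columns:
        r = spearman(features[col].to_numpy(), scores.to_numpy())
        rows.append({"feature_id": col, "rho": r.rho, "p_raw": r.p_raw, "n": r.n})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = fdr_bh(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df
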