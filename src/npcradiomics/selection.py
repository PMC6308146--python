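"""Reproducibility / redundancy / significance feature-selection cascade.

Stage order is fixed — ICC -> PCC -> Kruskal-Wallis with Benjamini-Hochberg
-> per-feature ROC — and each stage consumes only the previous stage's
survivors.

* ICC: two-way random-effects, absolute-agreement, single-measure
  reliability (ICC(A,1)) of each feature across two observers; features
  with ICC < 0.8 are removed. This ICC form is the standard choice for
  rater reproducibility of delineation.
* PCC: iterative greedy redundancy pruning. While any retained pair has
  |Pearson r| >= threshold, take the most-correlated pair and remove the
  member with the larger mean absolute correlation against the currently
  retained set; exact ties break lexicographically (the later key is
  removed). Constant features are removed up front with a warning.
* Kruskal-Wallis: chi-square approximation with tie correction (standard
  at these sample sizes); Benjamini-Hochberg step-up adjustment;
  significant = adjusted p < alpha.
* ROC: empirical AUC = rescaled Mann-Whitney U with half credit for ties,
  oriented so AUC >= 0.5; Hanley-McNeil standard error; 95% CI truncated
  to [0, 1]; sensitivity/specificity at the Youden-optimal threshold
  (ties -> lower threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RocResult",
    "SelectionReport",
    "icc_two_way_random",
    "icc_filter",
    "pcc_prune",
    "kw_bh_test",
    "roc_analysis",
    "run_selection",
]


# ---------------------------------------------------------------------------
# ICC


def icc_two_way_random(data: np.ndarray) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    ``data`` is subjects x raters. Returns NaN when the mean-square
    decomposition is degenerate (no between-subject variance).
    """
    data = np.asarray(data, dtype=np.float64)
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("ICC needs >= 3 subjects and >= 2 raters")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr == 0 and mse == 0):
        return float("nan")
    return float((msr - mse) / denom)


def icc_filter(
    obs1: pd.DataFrame, obs2: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.Series, list[str]]:
    """Per-feature two-observer ICC; retain features with ICC >= threshold.

    Features whose ICC is undefined (zero between-subject variance) are
    removed with a warning.
    """
    if list(obs1.columns) != list(obs2.columns) or len(obs1) != len(obs2):
        raise ValueError("observer tables must share cases and feature keys")
    if len(obs1) < 3:
        raise ValueError("ICC needs at least 3 cases")

    icc_values = {}
    undefined = []
    for key in obs1.columns:
        data = np.column_stack([obs1[key].to_numpy(), obs2[key].to_numpy()])
        icc = icc_two_way_random(data)
        icc_values[key] = icc
        if np.isnan(icc):
            undefined.append(key)
    if undefined:
        warnings.warn(
            f"{len(undefined)} features with undefined ICC (no between-subject "
            "variance) were removed"
        )
    series = pd.Series(icc_values)
    retained = [k for k in obs1.columns if np.isfinite(series[k]) and series[k] >= threshold]
    return series, retained


# ---------------------------------------------------------------------------
# PCC pruning


def pcc_prune(table: pd.DataFrame, threshold: float = 0.80) -> list[str]:
    """Greedy redundancy pruning on the absolute Pearson correlation matrix."""
    if table.shape[1] < 2:
        return list(table.columns)
    if len(table) < 3:
        raise ValueError("PCC pruning needs at least 3 cases")

    constant = [k for k in table.columns if table[k].nunique() <= 1 or table[k].std() == 0]
    if constant:
        warnings.warn(f"{len(constant)} constant features removed before PCC pruning")
    keys = [k for k in table.columns if k not in constant]
    if len(keys) < 2:
        return keys

    corr = table[keys].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(keys), dtype=bool)

    while True:
        sub = np.where(alive)[0]
        if len(sub) < 2:
            break
        c = corr[np.ix_(sub, sub)]
        max_r = c.max()
        if max_r < threshold:
            break
        # most correlated pair; ties -> lexicographically smallest key pair
        pairs = np.argwhere(c == max_r)
        pairs = [(sub[a], sub[b]) for a, b in pairs if a < b]
        pairs.sort(key=lambda ab: (keys[ab[0]], keys[ab[1]]))
        a, b = pairs[0]
        mean_a = corr[a, sub].sum() / (len(sub) - 1)
        mean_b = corr[b, sub].sum() / (len(sub) - 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:  # exact tie: remove the lexicographically later key
            drop = a if keys[a] > keys[b] else b
        alive[drop] = False

    return [keys[i] for i in np.where(alive)[0]]


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Benjamini-Hochberg


def kw_bh_test(
    table: pd.DataFrame, labels: pd.Series | np.ndarray, alpha: float = 0.05
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Per-feature Kruskal-Wallis p-values with BH step-up adjustment."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {len(classes)}")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 cases")

    p_raw = {}
    for key in table.columns:
        groups = [table[key].to_numpy()[labels == c] for c in classes]
        if np.ptp(table[key].to_numpy()) == 0:
            p_raw[key] = 1.0  # identical values: H = 0 by convention
            continue
        stat, p = stats.kruskal(*groups)
        p_raw[key] = float(p)
    p_raw = pd.Series(p_raw)
    _, p_adj, _, _ = multipletests(p_raw.to_numpy(), alpha=alpha, method="fdr_bh")
    p_adj = pd.Series(p_adj, index=p_raw.index)
    significant = [k for k in table.columns if p_adj[k] < alpha]
    return p_raw, p_adj, significant


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    orientation: int  # +1: positive class has higher values; -1: flipped
    degenerate: bool = False


def roc_analysis(
    values: np.ndarray, labels: np.ndarray, positive_label=None
) -> RocResult:
    """Single-feature ROC: AUC (Mann-Whitney with tie credit), Hanley-McNeil SE,
    truncated 95% CI, and the Youden-optimal operating point."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("ROC needs exactly two classes")
    if positive_label is None:
        positive_label = classes[0]
    pos = values[labels == positive_label]
    neg = values[labels != positive_label]
    n1, n2 = len(pos), len(neg)

    degenerate = np.ptp(values) == 0
    if degenerate:
        warnings.warn("all feature values identical: AUC = 0.5, SE flagged")
        return RocResult(0.5, float("nan"), (0.0, 1.0), 1.0, 0.0, float(values[0]), 1, True)

    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (n1 * n2)
    orientation = 1
    if auc < 0.5:
        auc = 1.0 - auc
        orientation = -1

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se = float(
        np.sqrt(
            (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2))
            / (n1 * n2)
        )
    )
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    oriented = values * orientation
    pos_o = oriented[labels == positive_label]
    neg_o = oriented[labels != positive_label]
    best = (-1.0, None)
    for t in np.sort(np.unique(oriented)):  # ties -> lower threshold wins
        sens = float((pos_o >= t).mean())
        spec = float((neg_o < t).mean())
        youden = sens + spec - 1.0
        if youden > best[0]:
            best = (youden, (t, sens, spec))
    t, sens, spec = best[1]
    return RocResult(float(auc), se, ci, sens, spec, float(t * orientation), orientation)


# ---------------------------------------------------------------------------
# Full cascade


@dataclass
class SelectionReport:
    icc_per_feature: pd.Series
    retained_after_icc: list[str]
    retained_after_pcc: list[str]
    kw_p: pd.Series
    bh_adjusted_p: pd.Series
    significant_features: list[str]
    roc: dict[str, RocResult] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Significant features with p, SE, CI, AUC, sensitivity, specificity."""
        rows = []
        for key in self.significant_features:
            r = self.roc[key]
            rows.append(
                {
                    "feature": key,
                    "p_value": self.kw_p[key],
                    "p_adjusted": self.bh_adjusted_p[key],
                    "standard_error": r.se,
                    "ci95_low": r.ci95[0],
                    "ci95_high": r.ci95[1],
                    "auc": r.auc,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                }
            )
        return pd.DataFrame(rows)


def run_selection(
    obs1: pd.DataFrame,
    obs2: pd.DataFrame,
    labels,
    icc_threshold: float = 0.8,
    pcc_threshold: float = 0.80,
    alpha: float = 0.05,
    positive_label=None,
) -> SelectionReport:
    """ICC -> PCC -> KW/BH -> ROC on the observer-1 feature table."""
    icc_values, after_icc = icc_filter(obs1, obs2, threshold=icc_threshold)
    after_pcc = pcc_prune(obs1[after_icc], threshold=pcc_threshold) if after_icc else []
    if after_pcc:
        p_raw, p_adj, significant = kw_bh_test(obs1[after_pcc], labels, alpha=alpha)
    else:
        p_raw = pd.Series(dtype=float)
        p_adj = pd.Series(dtype=float)
        significant = []
    labels_arr = np.asarray(labels)
    roc = {
        key: roc_analysis(obs1[key].to_numpy(), labels_arr, positive_label=positive_label)
        for key in significant
    }
    return SelectionReport(
        icc_per_feature=icc_values,
        retained_after_icc=after_icc,
        retained_after_pcc=after_pcc,
        kw_p=p_raw,
        bh_adjusted_p=p_adj,
        significant_features=significant,
        roc=roc,
    )
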