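"""z-scored ROC biomarker analysis and greedy panel construction.

Each candidate miRNA's normalized expression is z-scored across the two
compared subject groups, scored by ROC AUC (the Mann-Whitney concordance
probability) with a two-sided normal-approximation p-value, and ranked.
Panels average the sign-oriented z-scores of the top-k markers; k grows while
the panel AUC strictly improves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import NormalizedMatrix, ValidationError


@dataclass
class ROCResult:
    auc: float
    p: float
    n_pos: int
    n_neg: int
    orientation: int = +1  # +1: higher score predicts positive class; -1: flipped

    def to_dict(self) -> dict:
        return {"auc": self.auc, "p": self.p, "n_pos": self.n_pos,
                "n_neg": self.n_neg, "orientation": self.orientation}


@dataclass
class PanelResult:
    ranked_markers: list[str]
    marker_rocs: dict[str, ROCResult]
    trajectory: list[tuple[int, float, float]]  # (panel size, auc, p)
    selected_panel: list[str]
    subject_scores: pd.Series  # mean oriented z-score per subject, selected panel

    def to_dict(self) -> dict:
        return {
            "ranked_markers": self.ranked_markers,
            "marker_rocs": {m: r.to_dict() for m, r in self.marker_rocs.items()},
            "trajectory": [list(t) for t in self.trajectory],
            "selected_panel": self.selected_panel,
            "subject_scores": {k: float(v) for k, v in self.subject_scores.items()},
        }


def zscore_markers(norm: NormalizedMatrix, mirna_ids, subjects) -> pd.DataFrame:
    """Per-miRNA z-scores across exactly the given subjects (sample sd, ddof=1)."""
    mirna_ids, subjects = list(mirna_ids), list(subjects)
    vals = norm.values.loc[mirna_ids, subjects]
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    zero = sd <= 0
    if zero.any():
        raise ValidationError(f"zero standard deviation for {list(vals.index[zero])[:5]}")
    return vals.sub(mean, axis=0).div(sd, axis=0)


def roc_auc(scores, labels) -> ROCResult:
    """AUC = U / (n_pos * n_neg), ties counted 1/2; two-sided Mann-Whitney p
    by normal approximation with tie and continuity correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be non-empty")
    ranks = stats.rankdata(scores)
    u = float(ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
    auc = u / (n_pos * n_neg)
    n = n_pos + n_neg
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n_pos * n_neg / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return ROCResult(auc=auc, p=1.0, n_pos=n_pos, n_neg=n_neg)
    mean_u = n_pos * n_neg / 2.0
    z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
    p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return ROCResult(auc=auc, p=p, n_pos=n_pos, n_neg=n_neg)


def rank_markers(z: pd.DataFrame, labels) -> tuple[list[str], dict[str, ROCResult]]:
    """Orient each marker so AUC >= 0.5 and sort by AUC desc, then p asc, then ID."""
    labels = np.asarray(labels).astype(bool)
    rocs: dict[str, ROCResult] = {}
    for m in z.index:
        r = roc_auc(z.loc[m].to_numpy(), labels)
        if r.auc < 0.5:
            r = ROCResult(auc=1.0 - r.auc, p=r.p, n_pos=r.n_pos, n_neg=r.n_neg,
                          orientation=-1)
        rocs[m] = r
    ordered = sorted(z.index, key=lambda m: (-rocs[m].auc, rocs[m].p, m))
    return list(ordered), rocs


def build_panel(z: pd.DataFrame, labels, ranked: list[str] | None = None,
                rocs: dict[str, ROCResult] | None = None) -> PanelResult:
    """Greedy prefix panel with strict-improvement stop rule.

    Panel score at size k = per-subject mean of the oriented z-scores of the
    top-k ranked markers; growth stops at the first k whose AUC does not
    strictly exceed the running maximum.  The selected panel is the prefix
    achieving the maximum AUC.
    """
    if ranked is None or rocs is None:
        ranked, rocs = rank_markers(z, labels)
    if not ranked:
        raise ValidationError("ranked marker list is empty")
    labels = np.asarray(labels).astype(bool)
    oriented = z.loc[ranked].mul(
        pd.Series({m: rocs[m].orientation for m in ranked}), axis=0)
    trajectory: list[tuple[int, float, float]] = []
    best_auc, best_k = -np.inf, 1
    for k in range(1, len(ranked) + 1):
        score = oriented.iloc[:k].mean(axis=0)
        r = roc_auc(score.to_numpy(), labels)
        trajectory.append((k, r.auc, r.p))
        if r.auc > best_auc:
            best_auc, best_k = r.auc, k
        elif k > 1:
            break
    selected = ranked[:best_k]
    subject_scores = oriented.iloc[:best_k].mean(axis=0)
    return PanelResult(ranked, rocs, trajectory, selected, subject_scores)


def panel_group_test(mean_z, labels) -> tuple[float, int, float]:
    """Classical unpaired two-tailed t-test (pooled variance) on panel scores."""
    mean_z = np.asarray(mean_z, dtype=float)
    labels = np.asarray(labels).astype(bool)
    a, b = mean_z[labels], mean_z[~labels]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both groups need >= 2 subjects")
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValidationError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), df, p


def normality_gated_correlation(x, y, alpha: float = 0.05):
    """Pearson if both marginals pass the D'Agostino-Pearson K^2 omnibus test
    at ``alpha``, else Spearman.  Returns (method, r, (ci_lo, ci_hi), p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 8:
        raise ValidationError("normality test requires n >= 8")
    normal = (stats.normaltest(x).pvalue > alpha) and (stats.normaltest(y).pvalue > alpha)
    if normal:
        method = "pearson"
        r, p = stats.pearsonr(x, y)
        se = 1.0 / np.sqrt(n - 3)
    else:
        method = "spearman"
        res = stats.spearmanr(x, y)
        r, p = res.statistic, res.pvalue
        se = np.sqrt(1.06 / (n - 3))  # Fieller approximation for rank correlation
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        zr = np.arctanh(r)
        ci = (float(np.tanh(zr - 1.959964 * se)), float(np.tanh(zr + 1.959964 * se)))
    return method, r, ci, float(p)


def correlate_panel_covariate(mean_z, covariate, alpha: float = 0.05):
    """Correlate per-subject panel scores with a clinical covariate (e.g. EDSS),
    choosing Pearson vs Spearman by the normality gate."""
    return normality_gated_correlation(np.asarray(mean_z, dtype=float),
                                       np.asarray(covariate, dtype=float), alpha=alpha)
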