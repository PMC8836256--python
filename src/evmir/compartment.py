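"""Matched serum-CSF miRNome comparison.

Per-miRNA mean normalized expression is computed over matched subjects in
each compartment; the log10 serum-CSF difference is split into two
populations ("similar" and "high-serum") with a deterministic 1-D 2-means,
and within-population and per-miRNA serum-CSF correlations are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import NormalizedMatrix, ValidationError
from .panel import normality_gated_correlation


@dataclass
class CompartmentPairs:
    table: pd.DataFrame  # index miRNA; serum_mean, csf_mean, log10_serum, log10_csf, population
    n_serum_only: int = 0
    n_csf_only: int = 0
    split_threshold: float | None = None

    @property
    def cluster_sizes(self) -> dict[str, int]:
        return self.table["population"].value_counts().to_dict()


def pair_compartments(serum: NormalizedMatrix, csf: NormalizedMatrix,
                      subject_map: dict[str, str]) -> CompartmentPairs:
    """Per-miRNA compartment means over matched subjects.

    ``subject_map`` must be a bijection serum sample ID -> CSF sample ID.
    Only miRNAs present (detected post-filter) in both matrices are paired;
    one-compartment miRNAs are counted, not silently dropped.
    """
    s_ids, c_ids = list(subject_map), list(subject_map.values())
    if len(set(s_ids)) != len(s_ids) or len(set(c_ids)) != len(c_ids):
        raise ValidationError("subject_map must be a bijection")
    if not set(s_ids) <= set(serum.values.columns) or not set(c_ids) <= set(csf.values.columns):
        raise ValidationError("subject_map references unknown samples")
    common = serum.values.index.intersection(csf.values.index)
    serum_mean = serum.values.loc[common, s_ids].mean(axis=1)
    csf_mean = csf.values.loc[common, c_ids].mean(axis=1)
    with np.errstate(divide="ignore"):
        tab = pd.DataFrame({
            "serum_mean": serum_mean,
            "csf_mean": csf_mean,
            "log10_serum": np.log10(serum_mean),
            "log10_csf": np.log10(csf_mean),
        })
        tab["population"] = "unassigned"
    return CompartmentPairs(
        table=tab,
        n_serum_only=len(serum.values.index.difference(csf.values.index)),
        n_csf_only=len(csf.values.index.difference(serum.values.index)),
    )


def _two_means_1d(d: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, float]:
    """Deterministic 1-D 2-means, centers initialized at the 10th/90th percentiles.
    Returns (labels: 1 for the upper cluster, threshold)."""
    c = np.percentile(d, [10.0, 90.0]).astype(float)
    for _ in range(max_iter):
        thr = c.mean()
        lab = (d > thr).astype(int)
        new = np.array([d[lab == 0].mean() if (lab == 0).any() else c[0],
                        d[lab == 1].mean() if (lab == 1).any() else c[1]])
        if np.allclose(new, c):
            c = new
            break
        c = new
    thr = float(c.mean())
    return (d > thr).astype(int), thr


def split_populations(pairs: CompartmentPairs, method: str = "kmeans2-on-difference") -> CompartmentPairs:
    """Label each paired miRNA "similar" or "high_serum".

    The per-miRNA difference d = log10(serum_mean) - log10(csf_mean) is
    clustered into two groups by deterministic 1-D 2-means; the higher-d
    cluster is "high_serum" and the separating threshold is recorded.
    """
    if method != "kmeans2-on-difference":
        raise ValidationError(f"unknown split method {method!r}")
    tab = pairs.table
    finite = np.isfinite(tab["log10_serum"]) & np.isfinite(tab["log10_csf"])
    d = (tab.loc[finite, "log10_serum"] - tab.loc[finite, "log10_csf"]).to_numpy()
    if len(d) < 10:
        raise ValidationError("need >= 10 paired miRNAs to split")
    if np.allclose(d, d[0]):
        warnings.warn("degenerate log-difference distribution; single population")
        tab["population"] = "similar"
        pairs.split_threshold = None
        return pairs
    lab, thr = _two_means_1d(d)
    tab.loc[finite, "population"] = np.where(lab == 1, "high_serum", "similar")
    tab.loc[~finite, "population"] = "similar"
    pairs.split_threshold = thr
    return pairs


def correlate_population(pairs: CompartmentPairs, population: str,
                         method: str = "spearman"):
    """Serum-CSF correlation of linear mean expression within one population.

    Spearman by default (the compartment means are heavily non-normal); a
    Pearson cross-check is available.  95% CI by Fisher transform.
    Returns (r, (lo, hi), p).
    """
    sub = pairs.table[pairs.table["population"] == population]
    if len(sub) < 5:
        raise ValidationError(f"population {population!r} has fewer than 5 miRNAs")
    x, y = sub["serum_mean"].to_numpy(), sub["csf_mean"].to_numpy()
    n = len(sub)
    if method == "spearman":
        res = stats.spearmanr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        se = np.sqrt(1.06 / (n - 3))
    elif method == "pearson":
        r, p = (float(v) for v in stats.pearsonr(x, y))
        se = 1.0 / np.sqrt(n - 3)
    else:
        raise ValidationError(f"unknown method {method!r}")
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        zr = np.arctanh(r)
        ci = (float(np.tanh(zr - 1.959964 * se)), float(np.tanh(zr + 1.959964 * se)))
    return r, ci, p


def per_mirna_correlation(serum: NormalizedMatrix, csf: NormalizedMatrix,
                          mirna_ids, subject_map: dict[str, str]) -> pd.DataFrame:
    """Between-subject serum-vs-CSF correlation for each listed miRNA.

    Method per the normality-gated rule (Pearson when both marginals pass the
    D'Agostino-Pearson test, else Spearman).  Missing miRNAs are reported in
    the output with NaN statistics, not raised.
    """
    s_ids, c_ids = list(subject_map), list(subject_map.values())
    if len(s_ids) < 5:
        raise ValidationError("need >= 5 matched subjects")
    rows = []
    for m in mirna_ids:
        if m not in serum.values.index or m not in csf.values.index:
            rows.append({"mirna_id": m, "method": "missing", "r": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan})
            continue
        x = serum.values.loc[m, s_ids].to_numpy(dtype=float)
        y = csf.values.loc[m, c_ids].to_numpy(dtype=float)
        method, r, ci, p = normality_gated_correlation(x, y)
        rows.append({"mirna_id": m, "method": method, "r": r,
                     "ci_lo": ci[0], "ci_hi": ci[1], "p": p})
    return pd.DataFrame(rows).set_index("mirna_id")
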