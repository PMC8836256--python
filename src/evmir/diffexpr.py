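"""Pairwise negative-binomial differential expression.

The model is the standard NB GLM with log link and mean-dispersion
parameterization ``Var(Y) = mu + phi * mu^2``.  For each miRNA a one-way model
with a group effect is fitted by Newton scoring with effective library sizes
(raw library size x TMM factor) as offsets.  Dispersion is estimated by
Cox-Reid adjusted profile likelihood: a common value maximizing the summed APL
across miRNAs, and per-miRNA values shrunk toward the shared profile by
weighted likelihood.

Two test engines are provided:

``"ql"``
    Quasi-likelihood F-test: the deviance difference between null and full
    fits is scaled by an empirical-Bayes-moderated quasi-dispersion (scaled
    inverse-chi-square prior fitted to the per-miRNA deviance-based
    dispersions) and referred to an F distribution with moderated denominator
    degrees of freedom.

``"exact"``
    Conditional NB exact test for two groups at the common dispersion, on
    counts scaled to a common effective library size.

Calling uses the raw p-value threshold together with an absolute log2
fold-change threshold; BH-adjusted p-values are reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .matrix import CountMatrix, ValidationError
from .normalization import cpm, tmm_factors

# ---------------------------------------------------------------------------
# contrasts and result tables


@dataclass(frozen=True)
class ContrastSpec:
    """A pairwise contrast; log2FC > 0 means higher in ``group_a``."""

    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValidationError("contrast groups must differ")

    @property
    def name(self) -> str:
        return f"{self.group_a}_vs_{self.group_b}"


# ---------------------------------------------------------------------------
# NB GLM internals (vectorized over miRNAs)

_BETA_MIN = -60.0


def _fit_group_means(y: np.ndarray, offs: np.ndarray, phi: np.ndarray,
                     n_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """MLE of a single log-mean per miRNA given offsets and dispersion.

    y: genes x samples counts; offs: log effective library sizes (samples,);
    phi: dispersion, scalar or per-gene.  Returns (beta, fisher_info).
    """
    L = np.exp(offs)[None, :]
    phi = np.atleast_1d(np.asarray(phi, dtype=float))[:, None]
    tot = y.sum(axis=1)
    beta = np.log(np.maximum(tot, 0.5) / L.sum())
    for _ in range(n_iter):
        mu = np.exp(beta[:, None]) * L
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta = np.maximum(beta + step, _BETA_MIN)
    mu = np.exp(beta[:, None]) * L
    info = (mu / (1.0 + phi * mu)).sum(axis=1)
    return beta, info


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Summed NB log-likelihood per gene (genes x samples inputs)."""
    phi = np.maximum(np.atleast_1d(np.asarray(phi, dtype=float)), 1e-10)[:, None]
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    ll = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1.0)
          + r * np.log(r / (r + mu)) + special.xlogy(y, mu / (r + mu)))
    return ll.sum(axis=1)


def _nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """NB unit deviance summed per gene."""
    phi = np.maximum(np.atleast_1d(np.asarray(phi, dtype=float)), 1e-10)[:, None]
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    d = 2.0 * (special.xlogy(y, y / mu) - (y + r) * np.log((y + r) / (mu + r)))
    return np.maximum(d, 0.0).sum(axis=1)


def _apl(y: np.ndarray, offs: np.ndarray, group_idx: list[np.ndarray],
         phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    ll = np.zeros(y.shape[0])
    cr = np.zeros(y.shape[0])
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    for idx in group_idx:
        beta, info = _fit_group_means(y[:, idx], offs[idx], phi_arr)
        mu = np.exp(beta[:, None]) * np.exp(offs[idx])[None, :]
        ll += _nb_loglik(y[:, idx], mu, phi_arr)
        cr += 0.5 * np.log(np.maximum(info, 1e-300))
    return ll - cr


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series  # per-miRNA, shrunk toward the shared profile

    def for_mirnas(self, mirna_ids) -> np.ndarray:
        return self.tagwise.reindex(mirna_ids).fillna(self.common).to_numpy()


def estimate_dispersion(counts: CountMatrix, prior_df: float = 10.0,
                        factors: pd.Series | None = None,
                        grid_size: int = 21) -> DispersionEstimate:
    """Common and shrunk per-miRNA NB dispersions.

    The common dispersion maximizes the summed Cox-Reid adjusted profile
    likelihood over all miRNAs with nonzero counts.  Per-miRNA estimates
    maximize ``APL_g(phi) + w * mean_APL(phi)`` on a log-spaced grid around
    the common value, with weight ``w = prior_df / residual_df`` — a weighted
    likelihood that shrinks noisy per-miRNA profiles toward the shared one.
    """
    if factors is None:
        factors = tmm_factors(counts)
    groups = counts.meta["group"]
    for g, n in groups.value_counts().items():
        if n < 2:
            raise ValidationError(f"group {g!r} needs >= 2 samples")
    y = counts.counts.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"excluding {int((~nonzero).sum())} all-zero miRNAs from dispersion estimation")
    yz = y[nonzero]
    eff = (counts.library_sizes() * factors.reindex(counts.sample_ids)).to_numpy(dtype=float)
    offs = np.log(eff)
    gidx = [np.flatnonzero((groups == g).to_numpy()) for g in groups.unique()]

    def neg_total_apl(log_phi: float) -> float:
        return -float(_apl(yz, offs, gidx, np.exp(log_phi)).sum())

    res = optimize.minimize_scalar(neg_total_apl, bounds=(np.log(1e-6), np.log(5.0)),
                                   method="bounded", options={"xatol": 1e-3})
    common = float(np.exp(res.x))

    # tagwise: weighted-likelihood maximization on a grid around the common value
    grid = np.exp(np.linspace(np.log(max(common / 16, 1e-6)),
                              np.log(min(common * 16, 10.0)), grid_size))
    apl_mat = np.column_stack([_apl(yz, offs, gidx, g0) for g0 in grid])
    df_res = max(y.shape[1] - len(gidx), 1)
    w = prior_df / df_res
    crit = apl_mat + w * apl_mat.mean(axis=0)[None, :]
    best = crit.argmax(axis=1)
    tag = grid[best]
    tagwise = pd.Series(common, index=counts.counts.index, dtype=float)
    tagwise.iloc[np.flatnonzero(nonzero)] = tag
    return DispersionEstimate(common=common, tagwise=tagwise)


# ---------------------------------------------------------------------------
# empirical-Bayes squeezing of quasi-dispersions (scaled inverse-chi-square)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.max(np.abs(dif / y)) < 1e-8:
            break
    return y


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Moderate per-miRNA variances toward a common prior.

    Fits a scaled F / inverse-chi-square model to the observed variances by
    matching the moments of log(s2), returning (posterior variances,
    prior df, prior variance).  prior df = inf collapses all values to the
    common prior variance.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s2_prior = float(np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
        s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(emean))
        s2_post = np.full_like(s2, s2_prior)
    return s2_post, df_prior, s2_prior


# ---------------------------------------------------------------------------
# tests


def adjust_bh(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _exact_nb_pvalue(s1: int, n1: int, n2: int, total: int, phi: float) -> float:
    """Two-sided conditional NB exact test p-value for group sums."""
    if total == 0:
        return 1.0
    mu = total / (n1 + n2)
    if phi < 1e-8:
        # Poisson limit: conditional distribution is binomial
        d = stats.binom(total, n1 / (n1 + n2))
        probs_obs = d.logpmf(s1)
        sd = max(d.std(), 1.0)
        lo = max(0, int(np.floor(d.mean() - 15 * sd)))
        hi = min(total, int(np.ceil(d.mean() + 15 * sd)))
        lo, hi = min(lo, s1), max(hi, s1)
        k = np.arange(lo, hi + 1)
        logp = d.logpmf(k)
    else:
        r1, r2 = n1 / phi, n2 / phi
        m1, m2 = n1 * mu, n2 * mu
        d1 = stats.nbinom(r1, r1 / (r1 + m1))
        d2 = stats.nbinom(r2, r2 / (r2 + m2))
        var_c = 1.0 / (1.0 / max(d1.var(), 1.0) + 1.0 / max(d2.var(), 1.0))
        sd = np.sqrt(var_c)
        center = total * n1 / (n1 + n2)
        lo = max(0, int(np.floor(center - 20 * sd)))
        hi = min(total, int(np.ceil(center + 20 * sd)))
        lo, hi = min(lo, s1), max(hi, s1)
        k = np.arange(lo, hi + 1)
        logp = d1.logpmf(k) + d2.logpmf(total - k)
        probs_obs = d1.logpmf(s1) + d2.logpmf(total - s1)
    logp -= special.logsumexp(logp)
    probs_obs = logp[k == s1][0]
    keep = logp <= probs_obs + 1e-10
    return float(min(1.0, np.exp(special.logsumexp(logp[keep]))))


def de_test(counts: CountMatrix, contrast: ContrastSpec, engine: str = "ql",
            factors: pd.Series | None = None,
            dispersion: DispersionEstimate | None = None,
            prior_count: float = 0.5,
            p_threshold: float = 0.01, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Differential-expression table for one pairwise contrast.

    Returns a DataFrame indexed by miRNA ID with columns ``log2fc`` (positive
    means higher in ``contrast.group_a``), ``raw_p``, ``adj_p`` (BH),
    ``dispersion`` and ``call`` in {up, down, none}.
    """
    if engine not in ("ql", "exact"):
        raise ValidationError(f"unknown engine {engine!r}")
    for g in (contrast.group_a, contrast.group_b):
        if (counts.meta["group"] == g).sum() < 2:
            raise ValidationError(f"group {g!r} needs >= 2 samples")
    if factors is None:
        factors = tmm_factors(counts)
    sub = counts.subset_samples(
        counts.samples_in_group(contrast.group_a) + counts.samples_in_group(contrast.group_b))
    sub_factors = factors.reindex(sub.sample_ids)
    if dispersion is None:
        dispersion = estimate_dispersion(sub, factors=sub_factors)

    y = sub.counts.to_numpy(dtype=float)
    eff = (sub.library_sizes() * sub_factors).to_numpy(dtype=float)
    offs = np.log(eff)
    in_a = (sub.meta["group"] == contrast.group_a).to_numpy()
    idx_a, idx_b = np.flatnonzero(in_a), np.flatnonzero(~in_a)
    nonzero = y.sum(axis=1) > 0
    yz = y[nonzero]
    phi_tag = dispersion.for_mirnas(sub.counts.index[nonzero])

    raw_p = np.ones(y.shape[0])
    if engine == "ql":
        # full model: separate means per group; null: one shared mean
        beta_a, _ = _fit_group_means(yz[:, idx_a], offs[idx_a], phi_tag)
        beta_b, _ = _fit_group_means(yz[:, idx_b], offs[idx_b], phi_tag)
        beta_0, _ = _fit_group_means(yz, offs, phi_tag)
        mu_full = np.empty_like(yz)
        mu_full[:, idx_a] = np.exp(beta_a[:, None]) * eff[idx_a][None, :]
        mu_full[:, idx_b] = np.exp(beta_b[:, None]) * eff[idx_b][None, :]
        mu_null = np.exp(beta_0[:, None]) * eff[None, :]
        dev_full = _nb_deviance(yz, mu_full, phi_tag)
        dev_null = _nb_deviance(yz, mu_null, phi_tag)
        df_res = yz.shape[1] - 2
        if df_res < 1:
            raise ValidationError("degenerate design: no residual degrees of freedom")
        s2 = dev_full / df_res
        s2_post, df_prior, _ = squeeze_var(s2, df_res)
        df_total = df_res + (df_prior if np.isfinite(df_prior) else 1e6)
        fstat = np.maximum(dev_null - dev_full, 0.0) / np.maximum(s2_post, 1e-10)
        raw_p[nonzero] = stats.f.sf(fstat, 1, df_total)
    else:
        # conditional exact test on counts scaled to a common library size
        common = dispersion.common
        target = np.exp(np.mean(np.log(eff)))
        pseudo = np.rint(yz * (target / eff)[None, :]).astype(np.int64)
        n1, n2 = len(idx_a), len(idx_b)
        pv = np.ones(pseudo.shape[0])
        for i in range(pseudo.shape[0]):
            s1 = int(pseudo[i, idx_a].sum())
            tot = int(pseudo[i].sum())
            pv[i] = _exact_nb_pvalue(s1, n1, n2, tot, common)
        raw_p[nonzero] = pv

    raw_p = np.clip(raw_p, np.nextafter(0, 1), 1.0)
    norm = cpm(sub, sub_factors, prior_count=prior_count)
    mean_a = norm.values.iloc[:, idx_a].mean(axis=1)
    mean_b = norm.values.iloc[:, idx_b].mean(axis=1)
    log2fc = np.log2(mean_a / mean_b)
    log2fc[~nonzero] = 0.0

    det = pd.DataFrame({
        "log2fc": log2fc,
        "raw_p": raw_p,
        "adj_p": adjust_bh(raw_p),
        "dispersion": dispersion.for_mirnas(sub.counts.index),
    }, index=sub.counts.index)
    det.index.name = "mirna_id"
    det.attrs["contrast"] = contrast.name
    call_de(det, p_threshold, lfc_threshold)
    return det


def call_de(det: pd.DataFrame, p_threshold: float = 0.01,
            lfc_threshold: float = 1.0) -> tuple[set[str], set[str]]:
    """Annotate and return (up, down) sets at the raw-p / |log2FC| thresholds."""
    up = (det["raw_p"] < p_threshold) & (det["log2fc"] >= lfc_threshold)
    down = (det["raw_p"] < p_threshold) & (det["log2fc"] <= -lfc_threshold)
    det["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return set(det.index[up]), set(det.index[down])


# ---------------------------------------------------------------------------
# stage-specific double dissociation and Venn partition


@dataclass
class SpecificSets:
    cis_specific_down: set[str]
    rrms_specific_up: set[str]
    venn_partition: dict[str, set[str]]
    hospctl_concordant: dict[str, set[str]]

    def to_dict(self) -> dict:
        return {
            "cis_specific_down": sorted(self.cis_specific_down),
            "rrms_specific_up": sorted(self.rrms_specific_up),
            "venn_partition": {k: sorted(v) for k, v in self.venn_partition.items()},
            "hospctl_concordant": {k: sorted(v) for k, v in self.hospctl_concordant.items()},
        }


def _calls(det: pd.DataFrame) -> tuple[set[str], set[str]]:
    return set(det.index[det["call"] == "up"]), set(det.index[det["call"] == "down"])


def stage_specific_sets(de: dict[str, pd.DataFrame]) -> SpecificSets:
    """Derive CIS-specific down- and RRMS-specific up-regulated miRNA sets.

    ``de`` maps contrast names (``"A_vs_B"``) to called DE tables.  Required:
    CIS_vs_HealthCtl, RRMS_vs_HealthCtl, and either RRMS_vs_CIS or CIS_vs_RRMS.
    CIS-specific down = down in CIS vs HealthCtl and down in CIS vs RRMS;
    RRMS-specific up = up in RRMS vs HealthCtl and up in RRMS vs CIS.  The
    Venn partition over the three vs-HealthCtl contrasts retains direction.
    """
    for name in ("CIS_vs_HealthCtl", "RRMS_vs_HealthCtl"):
        if name not in de:
            raise ValidationError(f"missing contrast {name}")
    if "RRMS_vs_CIS" in de:
        rc_up, rc_down = _calls(de["RRMS_vs_CIS"])
    elif "CIS_vs_RRMS" in de:
        cr_up, cr_down = _calls(de["CIS_vs_RRMS"])
        rc_up, rc_down = cr_down, cr_up
    else:
        raise ValidationError("missing contrast RRMS_vs_CIS (or CIS_vs_RRMS)")

    cis_up, cis_down = _calls(de["CIS_vs_HealthCtl"])
    rrms_up, rrms_down = _calls(de["RRMS_vs_HealthCtl"])
    cis_specific_down = cis_down & rc_up       # down in CIS vs RRMS == up in RRMS vs CIS
    rrms_specific_up = rrms_up & rc_up

    venn: dict[str, set[str]] = {}
    per_group = {"CIS": (cis_up, cis_down), "RRMS": (rrms_up, rrms_down)}
    if "VI_vs_HealthCtl" in de:
        per_group["VI"] = _calls(de["VI_vs_HealthCtl"])
    names = list(per_group)
    for direction in ("up", "down"):
        sets = {g: per_group[g][0 if direction == "up" else 1] for g in names}
        universe = set().union(*sets.values())
        for mid in universe:
            members = frozenset(g for g in names if mid in sets[g])
            key = "&".join(sorted(members)) + ":" + direction
            venn.setdefault(key, set()).add(mid)

    hosp: dict[str, set[str]] = {}
    for g in names:
        cname = f"{g}_vs_HospCtl"
        if cname in de:
            h_up, h_down = _calls(de[cname])
            hosp[f"{g}:up"] = per_group[g][0] & h_up
            hosp[f"{g}:down"] = per_group[g][1] & h_down
    return SpecificSets(cis_specific_down, rrms_specific_up, venn, hosp)


STUDY_CONTRASTS = [
    ContrastSpec("CIS", "HealthCtl"), ContrastSpec("CIS", "HospCtl"),
    ContrastSpec("RRMS", "HealthCtl"), ContrastSpec("RRMS", "HospCtl"),
    ContrastSpec("VI", "HealthCtl"), ContrastSpec("VI", "HospCtl"),
    ContrastSpec("RRMS", "CIS"),
]
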