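"""Between-sample normalization: TMM scaling factors and counts-per-million.

TMM (trimmed mean of M-values) corrects for RNA-composition bias between
libraries: for each sample a log-ratio profile (M) against a reference sample
is formed over miRNAs expressed in both, doubly trimmed on M and on average
log-abundance (A), and a precision-weighted mean of the surviving M values
gives the scaling factor.  Factors are rescaled so their geometric mean is 1,
and effective library sizes are ``library_size * factor``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import CountMatrix, NormalizedMatrix, ValidationError


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    """TMM factor of one observation column against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        # single-log form keeps exact ties exactly tied, which matters for
        # the rank-based trimming
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        # delta-method variance of M under binomial sampling
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0:
        warnings.warn("no miRNAs usable for TMM; factor set to 1")
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        warnings.warn("no miRNAs survive TMM trimming; factor set to 1")
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                ref: str | None = None) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    The reference sample, unless given, is the one whose 75th count-proportion
    percentile is closest to the mean of those percentiles across samples.
    """
    mat = counts.counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("every sample must have library size > 0")
    mat = mat[mat.sum(axis=1) > 0]  # all-zero miRNAs carry no information
    if ref is None:
        f75 = np.percentile(mat, 75, axis=0) / lib
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.sample_ids.index(ref)
    refcol = mat[:, ref_idx]
    facs = np.array([
        _tmm_pair(mat[:, j], refcol, lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    facs = facs / np.exp(np.mean(np.log(facs)))
    return pd.Series(facs, index=counts.sample_ids, name="tmm_factor")


def cpm(counts: CountMatrix, factors: pd.Series | None = None,
        prior_count: float = 0.5) -> NormalizedMatrix:
    """TMM-scaled counts per million.

    ``value = (count + prior_i) / effective_library * 1e6`` where the prior is
    scaled per sample in proportion to its effective library size
    (``prior_i = prior_count * L_i / mean(L)``), so an equal pseudo-abundance
    is added everywhere.  ``prior_count = 0`` gives plain CPM whose columns sum
    to exactly 1e6.
    """
    if factors is None:
        factors = pd.Series(1.0, index=counts.sample_ids)
    factors = factors.reindex(counts.sample_ids)
    if factors.isna().any() or (factors <= 0).any():
        raise ValidationError("factors must be positive and aligned to samples")
    lib = counts.library_sizes().astype(float)
    eff = lib * factors
    if (eff <= 0).any():
        raise ValidationError("zero effective library size")
    prior = prior_count * eff / eff.mean()
    vals = (counts.counts.astype(float).add(prior, axis=1)).div(eff, axis=1) * 1e6
    return NormalizedMatrix(vals, factors, lib, prior_count, meta=counts.meta.copy())
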