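"""Synthetic data with planted ground truth emulating the study design.

The generator emits UMI count matrices for five subject groups (healthy
controls, hospitalized controls, CIS-remission, RRMS-relapse, viral
inflammatory controls), matched serum/CSF sample pairs with two expression
populations, and triplicate RT-qPCR plates with a UniSp6 spike-in.  Counts
are negative-binomial with variance ``mu + phi * mu^2``; baseline abundances
are log-uniform, pilot-calibrated so that the per-sample number of detected
miRNAs falls in the band observed in serum EV small-RNA sequencing at ~5
million reads per sample (roughly 700-2400, mean ~1800 of 2000 simulated).

Planted effects: a set of miRNAs down-regulated only in CIS, a set
up-regulated only in RRMS (the stage-specific double dissociation), and a
shared inflammation signature dysregulated equally in CIS, RRMS and VI, which
populates the overlap regions of the Venn partition without contaminating
the stage-specific sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ValidationError

DEFAULT_GROUP_SIZES = {"HealthCtl": 18, "HospCtl": 22, "CIS": 18, "RRMS": 16, "VI": 11}


@dataclass
class SimParams:
    """Generator configuration; defaults emulate the study conditions."""

    n_mirnas: int = 2000
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    library_size_mean: float = 5e6
    library_size_cv: float = 0.25
    dispersion: float = 0.2
    baseline_logmean_range: tuple[float, float] = (0.0, 5.0)
    n_cis_down: int = 6
    n_rrms_up: int = 9
    n_shared_up: int = 18
    n_shared_down: int = 11
    planted_log2fc: float = 2.0
    # fraction of the shared-signature effect also applied to CIS; 1.0 keeps
    # the shared signature out of the RRMS-vs-CIS contrast entirely
    shared_cis_fraction: float = 1.0
    dispersion_gamma_shape: float | None = None  # per-miRNA gamma dispersions if set
    amplification_factor: float = 5.0  # reads per UMI, for the bias check
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas <= 0:
            raise ValidationError("n_mirnas must be positive")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if any(n <= 1 for n in self.group_sizes.values()):
            raise ValidationError("every group needs > 1 subject")
        if self.planted_log2fc < 0:
            raise ValidationError("planted_log2fc must be >= 0")
        n_planted = self.n_cis_down + self.n_rrms_up + self.n_shared_up + self.n_shared_down
        if n_planted > self.n_mirnas:
            raise ValidationError("more planted miRNAs than miRNAs")


@dataclass
class SimTruth:
    """Ground-truth ledger for a simulated dataset."""

    cis_down_ids: set[str] = field(default_factory=set)
    rrms_up_ids: set[str] = field(default_factory=set)
    shared_up_ids: set[str] = field(default_factory=set)
    shared_down_ids: set[str] = field(default_factory=set)
    log2fc_by_group: pd.DataFrame | None = None  # miRNA x group true log2 shift vs baseline
    outlier_subject_ids: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "cis_down_ids": sorted(self.cis_down_ids),
            "rrms_up_ids": sorted(self.rrms_up_ids),
            "shared_up_ids": sorted(self.shared_up_ids),
            "shared_down_ids": sorted(self.shared_down_ids),
            "outlier_subject_ids": sorted(self.outlier_subject_ids),
        }


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, Var mu + phi mu^2) via gamma-Poisson mixture."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_mask = phi < 1e-12
    if poisson_mask.any():
        out[poisson_mask] = rng.poisson(mu[poisson_mask])
    nbm = ~poisson_mask
    if nbm.any():
        shape = 1.0 / phi[nbm]
        lam = rng.gamma(shape, phi[nbm] * mu[nbm])
        out[nbm] = rng.poisson(lam)
    return out


def simulate_counts(params: SimParams) -> tuple[CountMatrix, SimTruth]:
    """Simulate a serum UMI count matrix with planted stage-specific effects."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    g = params.group_sizes
    groups = np.repeat(list(g), list(g.values()))
    n_samples = len(groups)
    sample_ids = [f"S{i + 1:03d}_{grp}" for i, grp in enumerate(groups)]
    mirna_ids = [f"sim-miR-{i + 1:04d}" for i in range(params.n_mirnas)]

    lo, hi = params.baseline_logmean_range
    rel = 10.0 ** rng.uniform(lo, hi, size=params.n_mirnas)
    rel /= rel.sum()

    # plant effects on miRNAs abundant enough to be observable after filtering
    expected = rel * params.library_size_mean
    eligible = np.flatnonzero(expected >= 50.0)
    n_planted = params.n_cis_down + params.n_rrms_up + params.n_shared_up + params.n_shared_down
    if len(eligible) < n_planted:
        raise ValidationError("baseline abundance range leaves too few plantable miRNAs")
    chosen = rng.choice(eligible, size=n_planted, replace=False)
    k = 0
    cis_down = chosen[k:k + params.n_cis_down]; k += params.n_cis_down
    rrms_up = chosen[k:k + params.n_rrms_up]; k += params.n_rrms_up
    shared_up = chosen[k:k + params.n_shared_up]; k += params.n_shared_up
    shared_down = chosen[k:k + params.n_shared_down]

    lfc = pd.DataFrame(0.0, index=mirna_ids, columns=list(g))
    fc = params.planted_log2fc
    if "CIS" in lfc.columns:
        lfc.iloc[cis_down, lfc.columns.get_loc("CIS")] = -fc
    if "RRMS" in lfc.columns:
        lfc.iloc[rrms_up, lfc.columns.get_loc("RRMS")] = +fc
    for grp in ("CIS", "RRMS", "VI"):
        if grp not in lfc.columns:
            continue
        scale = params.shared_cis_fraction if grp == "CIS" else 1.0
        lfc.iloc[shared_up, lfc.columns.get_loc(grp)] += fc * scale
        lfc.iloc[shared_down, lfc.columns.get_loc(grp)] -= fc * scale

    sigma = np.sqrt(np.log1p(params.library_size_cv ** 2))
    lib = np.exp(rng.normal(np.log(params.library_size_mean) - sigma ** 2 / 2.0,
                            sigma, size=n_samples))

    if params.dispersion_gamma_shape is not None:
        shape = params.dispersion_gamma_shape
        phi_g = rng.gamma(shape, params.dispersion / shape, size=params.n_mirnas)
    else:
        phi_g = np.full(params.n_mirnas, params.dispersion)

    fold = 2.0 ** lfc.to_numpy()[:, [list(g).index(grp) for grp in groups]]
    mu = rel[:, None] * lib[None, :] * fold
    counts = _nb_draw(rng, mu, phi_g[:, None])

    umis = counts.sum(axis=0)
    reads = np.rint(umis * params.amplification_factor
                    * (1.0 + rng.normal(0.0, 0.01, size=n_samples))).astype(np.int64)
    edss = np.full(n_samples, np.nan)
    edss[groups == "CIS"] = np.clip(rng.normal(1.7, 0.9, (groups == "CIS").sum()), 0.0, 3.5)
    edss[groups == "RRMS"] = np.clip(rng.normal(2.3, 1.4, (groups == "RRMS").sum()), 1.0, 7.5)
    edss = np.round(edss * 2.0) / 2.0  # EDSS is scored in half points

    meta = pd.DataFrame({
        "group": groups, "compartment": "serum", "edss": edss, "total_reads": reads,
    }, index=pd.Index(sample_ids, name="sample_id"))
    cm = CountMatrix(pd.DataFrame(counts, index=mirna_ids, columns=sample_ids), meta)
    truth = SimTruth(
        cis_down_ids={mirna_ids[i] for i in cis_down},
        rrms_up_ids={mirna_ids[i] for i in rrms_up},
        shared_up_ids={mirna_ids[i] for i in shared_up},
        shared_down_ids={mirna_ids[i] for i in shared_down},
        log2fc_by_group=lfc,
    )
    return cm, truth


def inject_outlier_subjects(counts: CountMatrix, n_outliers: int, severity: float,
                            seed: int = 0) -> tuple[CountMatrix, SimTruth]:
    """Corrupt ``n_outliers`` subjects by rank-shuffling a ``severity`` fraction
    of their miRNA counts, destroying their correlation with the group mean."""
    if not (0 < severity <= 1):
        raise ValidationError("severity must be in (0, 1]")
    smallest = counts.meta["group"].value_counts().min()
    if n_outliers >= smallest:
        raise ValidationError("n_outliers must be smaller than the smallest group")
    rng = np.random.default_rng(seed)
    new = counts.counts.copy()
    truth = SimTruth()
    if n_outliers == 0:
        return CountMatrix(new, counts.meta.copy()), truth
    victims = rng.choice(counts.sample_ids, size=n_outliers, replace=False)
    n_rows = len(counts.mirna_ids)
    for s in victims:
        n_shuf = int(round(severity * n_rows))
        rows = rng.choice(n_rows, size=n_shuf, replace=False)
        col = new[s].to_numpy().copy()
        col[rows] = col[rows[rng.permutation(n_shuf)]]
        new[s] = col
    truth.outlier_subject_ids = set(map(str, victims))
    return CountMatrix(new, counts.meta.copy()), truth


@dataclass
class CsfTruth:
    high_serum_ids: set[str]
    subject_map: dict[str, str]  # serum sample id -> CSF sample id


def simulate_matched_csf(serum: CountMatrix, high_serum_fraction: float = 128 / 2151,
                         offset_log10: float = 2.0, noise_sd: float = 0.15,
                         seed: int = 0) -> tuple[CountMatrix, CsfTruth]:
    """Matched CSF counts: one population tracks serum, one sits
    ``offset_log10`` decades lower, with per-miRNA lognormal noise."""
    if not (0 < high_serum_fraction < 1):
        raise ValidationError("high_serum_fraction must be in (0, 1)")
    if serum.meta["group"].nunique() != 1:
        raise ValidationError("serum matrix must be restricted to a single group")
    rng = np.random.default_rng(seed)
    n = len(serum.mirna_ids)
    n_high = int(round(high_serum_fraction * n))
    high_idx = rng.choice(n, size=n_high, replace=False)
    log_mult = np.zeros(n)
    log_mult[high_idx] = -offset_log10
    if noise_sd > 0:
        log_mult = log_mult + rng.normal(0.0, noise_sd, size=n)
    mult = 10.0 ** log_mult
    vals = np.rint(serum.counts.to_numpy(dtype=float) * mult[:, None]).astype(np.int64)
    csf_ids = [f"{s}_CSF" for s in serum.sample_ids]
    meta = serum.meta.copy()
    meta.index = pd.Index(csf_ids, name="sample_id")
    meta["compartment"] = "CSF"
    csf = CountMatrix(pd.DataFrame(vals, index=serum.counts.index, columns=csf_ids), meta)
    truth = CsfTruth(
        high_serum_ids={serum.mirna_ids[i] for i in high_idx},
        subject_map=dict(zip(serum.sample_ids, csf_ids)),
    )
    return csf, truth


@dataclass
class QPCRTruth:
    displaced: set[tuple[str, str, int]]  # (sample, assay, replicate index)


def simulate_qpcr(counts: CountMatrix, mirna_ids, efficiency_slope: float = 1.0,
                  replicate_sd: float = 0.15, outlier_rate: float = 0.0,
                  seed: int = 0, intercept: float = 32.0,
                  unisp6_cq: float = 19.0, unisp6_sd: float = 0.1):
    """Triplicate Cq values per target miRNA plus duplicate UniSp6 spike-in.

    ``Cq = intercept - efficiency_slope * log2(CPM + 1) + N(0, replicate_sd)``;
    with probability ``outlier_rate`` per well one replicate is displaced by
    2-4 cycles and recorded in the truth ledger.  Returns (plate, truth).
    """
    from .qpcr import QPCRPlate  # local import to avoid a cycle

    mirna_ids = list(mirna_ids)
    if not mirna_ids:
        raise ValidationError("mirna_ids must be non-empty")
    missing = set(mirna_ids) - set(counts.mirna_ids)
    if missing:
        raise ValidationError(f"miRNAs absent from counts: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    lib = counts.library_sizes().astype(float)
    cpm_vals = counts.counts.div(lib, axis=1) * 1e6
    rows = []
    displaced: set[tuple[str, str, int]] = set()
    for s in counts.sample_ids:
        for m in mirna_ids:
            base = intercept - efficiency_slope * np.log2(cpm_vals.loc[m, s] + 1.0)
            cq = base + rng.normal(0.0, replicate_sd, size=3)
            if outlier_rate > 0 and rng.random() < outlier_rate:
                ridx = int(rng.integers(3))
                cq[ridx] += rng.choice([-1.0, 1.0]) * rng.uniform(2.0, 4.0)
                displaced.add((s, m, ridx))
            for ridx in range(3):
                rows.append((s, m, ridx, float(np.clip(cq[ridx], 1.0, 44.9))))
        ucq = unisp6_cq + rng.normal(0.0, unisp6_sd, size=2)
        for ridx in range(2):
            rows.append((s, "UniSp6", ridx, float(ucq[ridx])))
    plate = QPCRPlate(pd.DataFrame(rows, columns=["sample", "assay", "replicate", "cq"]))
    return plate, QPCRTruth(displaced=displaced)


def simulate_enrichment_inputs(query_mirnas, seed: int = 0, n_genes: int = 400,
                               n_pathways: int = 20, pathway_size: tuple[int, int] = (10, 40),
                               targets_per_mirna: tuple[int, int] = (8, 25),
                               enrichment_strength: float = 0.7):
    """Synthetic validated-target map and pathway collection with one planted
    enriched pathway whose genes dominate the query miRNAs' target sets.

    Returns (target_map, pathway_db_dict, planted_pathway_name).
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    pathways: dict[str, set[str]] = {}
    for p in range(n_pathways):
        size = int(rng.integers(pathway_size[0], pathway_size[1] + 1))
        pathways[f"PATH_{p + 1:02d}"] = set(rng.choice(genes, size=size, replace=False))
    planted = "PATH_01"
    planted_genes = sorted(pathways[planted])
    tmap: dict[str, set[str]] = {}
    for m in query_mirnas:
        k = int(rng.integers(targets_per_mirna[0], targets_per_mirna[1] + 1))
        k_in = min(int(round(enrichment_strength * k)), len(planted_genes))
        inside = rng.choice(planted_genes, size=k_in, replace=False)
        outside = rng.choice(genes, size=k - k_in, replace=False)
        tmap[m] = set(inside) | set(outside)
    return tmap, pathways, planted
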