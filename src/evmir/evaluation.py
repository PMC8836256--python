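"""Planted-truth recovery benchmarks.

Every function here generates synthetic data with the study-design defaults,
runs the corresponding pipeline stages, and measures how well the known
ground truth is recovered.  They power both the test suite and the
reproduction script, so the measured quantities are always recomputed from
scratch.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np

from . import qpcr as qpcr_mod
from .compartment import correlate_population, pair_compartments, split_populations
from .diffexpr import ContrastSpec, de_test, estimate_dispersion, stage_specific_sets
from .matrix import CountMatrix
from .normalization import cpm, tmm_factors
from .panel import build_panel, rank_markers, zscore_markers
from .qc import detect_outliers, filter_background, run_qc
from .pipeline import run_pipeline
from .synthetic import (SimParams, inject_outlier_subjects, simulate_counts,
                        simulate_matched_csf, simulate_qpcr)


def _derive(seed: int, offset: int) -> int:
    return (seed * 100003 + offset) % (2 ** 31)


def null_calibration(seed: int = 0, engine: str = "ql",
                     n_mirnas: int = 2000) -> dict:
    """Type-I error at raw p < 0.01 and dispersion recovery on a null
    two-group NB simulation (16 vs 18 subjects, phi = 0.2)."""
    params = SimParams(n_mirnas=n_mirnas, planted_log2fc=0.0,
                       group_sizes={"CIS": 16, "HealthCtl": 18}, seed=seed)
    cm, _ = simulate_counts(params)
    cm, _ = filter_background(cm)
    disp = estimate_dispersion(cm)
    det = de_test(cm, ContrastSpec("CIS", "HealthCtl"), engine=engine, dispersion=disp)
    return {
        "type_i_rate": float((det["raw_p"] < 0.01).mean()),
        "common_dispersion": disp.common,
        "n_mirnas_tested": int(len(det)),
    }


def run_de_stages(cm: CountMatrix, contrasts=None):
    """QC -> TMM -> DE on the study contrasts; returns (cleaned, factors, tables)."""
    cleaned, _ = run_qc(cm)
    factors = tmm_factors(cleaned)
    if contrasts is None:
        contrasts = [ContrastSpec("CIS", "HealthCtl"), ContrastSpec("RRMS", "HealthCtl"),
                     ContrastSpec("RRMS", "CIS")]
    tables = {c.name: de_test(cleaned, c, factors=factors) for c in contrasts}
    return cleaned, factors, tables


def stage_specific_recovery(n_seeds: int = 20, base_seed: int = 0,
                            n_null_markers: int = 20) -> dict:
    """Planted-set recovery and panel behavior over repeated simulations.

    Per seed: simulate at defaults (6 CIS-down, 9 RRMS-up, log2FC 2), run
    QC/TMM/DE on the three double-dissociation contrasts, and check that the
    derived stage-specific sets equal the truth exactly.  Also checks the
    panel properties on the RRMS-vs-HealthCtl separation: the selected panel
    AUC is at least the best single planted marker's (stop-rule guarantee)
    and all planted markers outrank a sample of null markers.
    """
    exact, panel_ge, rank_clean = 0, 0, 0
    for i in range(n_seeds):
        seed = _derive(base_seed, i)
        cm, truth = simulate_counts(SimParams(seed=seed))
        cleaned, factors, tables = run_de_stages(cm)
        sets = stage_specific_sets(tables)
        if (sets.cis_specific_down == truth.cis_down_ids
                and sets.rrms_specific_up == truth.rrms_up_ids):
            exact += 1

        norm = cpm(cleaned, factors)
        rng = np.random.default_rng(seed)
        planted = sorted(truth.rrms_up_ids)
        null_pool = [m for m in cleaned.mirna_ids
                     if m not in truth.rrms_up_ids | truth.cis_down_ids
                     | truth.shared_up_ids | truth.shared_down_ids]
        nulls = sorted(rng.choice(null_pool, size=n_null_markers, replace=False))
        subjects = cleaned.samples_in_group("RRMS") + cleaned.samples_in_group("HealthCtl")
        labels = [s in set(cleaned.samples_in_group("RRMS")) for s in subjects]
        z = zscore_markers(norm, planted + nulls, subjects)
        ranked, rocs = rank_markers(z, labels)
        if all(m in set(planted) for m in ranked[:len(planted)]):
            rank_clean += 1
        zp = z.loc[planted]
        ranked_p, rocs_p = rank_markers(zp, labels)
        res = build_panel(zp, labels, ranked_p, rocs_p)
        best_single = max(r.auc for r in rocs_p.values())
        if res.trajectory[len(res.selected_panel) - 1][1] >= best_single - 1e-12:
            panel_ge += 1
    return {
        "exact_recovery_rate": exact / n_seeds,
        "panel_auc_ge_best_single_rate": panel_ge / n_seeds,
        "planted_above_null_rate": rank_clean / n_seeds,
        "n_seeds": n_seeds,
    }


def outlier_recovery(n_seeds: int = 50, base_seed: int = 0, n_outliers: int = 6,
                     severity: float = 1.0) -> dict:
    """Fraction of simulations where the Tukey rule flags exactly the
    injected outlier subjects."""
    exact = 0
    for i in range(n_seeds):
        seed = _derive(base_seed, 1000 + i)
        cm, _ = simulate_counts(SimParams(seed=seed))
        cm, truth = inject_outlier_subjects(cm, n_outliers, severity, seed=seed + 1)
        filtered, _ = filter_background(cm)
        flagged, _, _ = detect_outliers(filtered, rule="tukey")
        if flagged == truth.outlier_subject_ids:
            exact += 1
    return {"exact_recovery_rate": exact / n_seeds, "n_seeds": n_seeds}


def compartment_recovery(seed: int = 0, n_mirnas: int = 2151) -> dict:
    """Population-split assignment accuracy and within-population serum-CSF
    correlation on the matched-CSF simulation."""
    params = SimParams(n_mirnas=n_mirnas, seed=seed)
    cm, _ = simulate_counts(params)
    serum = cm.subset_samples(cm.samples_in_group("RRMS"))
    csf, truth = simulate_matched_csf(serum, seed=seed + 1)
    # pairing considers only miRNAs detected (post-filter) in each compartment
    serum_f, _ = filter_background(serum)
    csf_f, _ = filter_background(csf)
    ser_norm = cpm(serum_f, prior_count=0.0)
    csf_norm = cpm(csf_f, prior_count=0.0)
    pairs = split_populations(pair_compartments(ser_norm, csf_norm, truth.subject_map))
    tab = pairs.table
    truth_label = tab.index.isin(truth.high_serum_ids)
    called = (tab["population"] == "high_serum").to_numpy()
    accuracy = float((called == truth_label).mean())
    r_sim, _, _ = correlate_population(pairs, "similar")
    r_high, _, _ = correlate_population(pairs, "high_serum")
    sizes = pairs.cluster_sizes
    return {
        "assignment_accuracy": accuracy,
        "r_similar": r_sim,
        "r_high_serum": r_high,
        "n_similar": int(sizes.get("similar", 0)),
        "n_high_serum": int(sizes.get("high_serum", 0)),
        "n_paired": int(len(tab)),
    }


def qpcr_consistency(seed: int = 0, outlier_rate: float = 0.1,
                     n_targets: int = 2) -> dict:
    """Delta-Cq vs normalized-count anticorrelation and replicate-outlier
    detection sensitivity on a simulated plate."""
    cm, truth = simulate_counts(SimParams(seed=seed))
    sub = cm.subset_samples(cm.samples_in_group("CIS") + cm.samples_in_group("RRMS"))
    targets = sorted(truth.rrms_up_ids)[:n_targets]
    plate, qtruth = simulate_qpcr(sub, targets, outlier_rate=outlier_rate, seed=seed + 1)
    plate = qpcr_mod.replicate_qc(plate)
    rec = plate.records
    flagged = set(rec[rec["flagged"]][["sample", "assay", "replicate"]].itertuples(
        index=False, name=None))
    sens = (len(flagged & qtruth.displaced) / len(qtruth.displaced)
            if qtruth.displaced else float("nan"))
    dcq = qpcr_mod.delta_cq(plate)
    norm = cpm(sub, tmm_factors(sub), prior_count=0.0)
    corr = qpcr_mod.crossplatform_correlation(dcq, norm.values)
    return {
        "replicate_sensitivity": sens,
        "n_displaced": len(qtruth.displaced),
        "worst_rho": float(corr["rho"].max()),
        "mean_rho": float(corr["rho"].mean()),
    }


def pipeline_determinism(seed: int, workdir) -> dict:
    """Run the demo pipeline twice with the same config and seed and compare
    every emitted file byte-for-byte."""
    workdir = Path(workdir)
    outs = []
    for rep in ("run1", "run2"):
        out = workdir / rep
        run_pipeline({"out_dir": str(out), "seed": seed})
        outs.append(out)
    files = sorted(p.name for p in outs[0].iterdir())
    identical = all(filecmp.cmp(outs[0] / f, outs[1] / f, shallow=False) for f in files)
    return {"identical": identical, "n_files": len(files)}
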