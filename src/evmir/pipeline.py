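"""End-to-end pipeline: simulate -> QC -> normalize -> DE -> stage-specific
sets -> biomarker panel -> enrichment -> serum/CSF comparison -> qPCR.

A single declarative config drives all stages; each stage writes its artifact
plus an entry in a run manifest (parameters, derived seed, output hashes).
The global seed fans out to per-stage seeds by hashing the stage name, so
stages are independently reproducible and identical config + seed give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import compartment as cmp
from . import diffexpr as de_mod
from . import enrichment as enr
from . import panel as panel_mod
from . import qc as qc_mod
from . import qpcr as qpcr_mod
from . import synthetic as sim
from .matrix import CountMatrix, ValidationError, read_counts, write_counts
from .normalization import cpm, tmm_factors

log = logging.getLogger("evmir")

DEFAULT_CONFIG: dict = {
    "out_dir": "evmir_run",
    "seed": 0,
    "inputs": {"counts": None, "meta": None},
    "simulate": {
        "n_mirnas": 2000, "library_size_mean": 5e6, "library_size_cv": 0.25,
        "dispersion": 0.2, "n_cis_down": 6, "n_rrms_up": 9,
        "planted_log2fc": 2.0, "n_outliers": 6, "outlier_severity": 1.0,
    },
    "qc": {"min_count": 10, "min_fraction": 0.5, "outlier_rule": "tukey"},
    "de": {"engine": "ql", "p_threshold": 0.01, "lfc_threshold": 1.0, "prior_count": 0.5},
    "panel": {"compare": ["CIS", "RRMS"]},
    "enrichment": {"alpha": 0.01, "min_mirnas": 3, "target_map": None, "gmt": None},
    "csf": {"high_serum_fraction": 128 / 2151, "offset_log10": 2.0, "noise_sd": 0.15},
    "qpcr": {"n_targets": 2, "replicate_sd": 0.15, "outlier_rate": 0.05, "max_dev": 0.5},
}


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2 ** 31)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValidationError("config must be a mapping")
    return _merge(DEFAULT_CONFIG, user)


def validate_config(config: dict) -> list[str]:
    """Range and path checks; all errors aggregated, not first-only."""
    errors: list[str] = []
    qc = config.get("qc", {})
    if not (0 < qc.get("min_fraction", 0.5) <= 1):
        errors.append("qc.min_fraction must be in (0, 1]")
    if qc.get("min_count", 10) < 0:
        errors.append("qc.min_count must be >= 0")
    if qc.get("outlier_rule") not in ("tukey", "quartile"):
        errors.append("qc.outlier_rule must be 'tukey' or 'quartile'")
    de = config.get("de", {})
    if not (0 < de.get("p_threshold", 0.01) <= 1):
        errors.append("de.p_threshold must be in (0, 1]")
    if de.get("lfc_threshold", 1.0) < 0:
        errors.append("de.lfc_threshold must be >= 0")
    if de.get("engine") not in ("ql", "exact"):
        errors.append("de.engine must be 'ql' or 'exact'")
    enrichment = config.get("enrichment", {})
    if not (0 < enrichment.get("alpha", 0.01) <= 1):
        errors.append("enrichment.alpha must be in (0, 1]")
    if enrichment.get("min_mirnas", 3) < 1:
        errors.append("enrichment.min_mirnas must be >= 1")
    csf = config.get("csf", {})
    if not (0 < csf.get("high_serum_fraction", 0.06) < 1):
        errors.append("csf.high_serum_fraction must be in (0, 1)")
    inputs = config.get("inputs") or {}
    for key in ("counts", "meta", "target_map", "gmt"):
        holder = inputs if key in ("counts", "meta") else enrichment
        p = holder.get(key)
        if p is not None and not Path(p).exists():
            errors.append(f"path for {key!r} does not exist: {p}")
    simc = config.get("simulate", {})
    if simc.get("dispersion", 0.2) <= 0:
        errors.append("simulate.dispersion must be > 0")
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


class PipelineRun:
    def __init__(self, config: dict):
        errors = validate_config(config)
        if errors:
            raise ValidationError("invalid config: " + "; ".join(errors))
        self.config = config
        self.out = Path(config["out_dir"])
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(config["seed"])
        self.manifest: dict = {"seed": self.seed, "stages": {}}

    def _record(self, stage: str, params: dict, files: list[Path], extra: dict | None = None) -> None:
        entry = {
            "seed": stage_seed(self.seed, stage),
            "parameters": params,
            "outputs": {f.name: _sha256(f) for f in files},
        }
        if extra:
            entry.update(extra)
        self.manifest["stages"][stage] = entry
        log.info("stage %s done: %s", stage, {f.name: None for f in files})

    # ------------------------------------------------------------------ stages

    def run(self) -> dict:
        try:
            counts, truth = self._stage_simulate_or_load()
            cleaned, qc_report = self._stage_qc(counts)
            norm = self._stage_normalize(cleaned)
            de_tables = self._stage_de(cleaned)
            sets = self._stage_specific(de_tables)
            self._stage_panel(norm, cleaned, sets)
            self._stage_enrichment(sets)
            self._stage_csf(cleaned)
            self._stage_qpcr(cleaned, sets)
        except Exception:
            (self.out / "FAILED").write_text("pipeline failed; partial outputs retained\n")
            raise
        manifest_path = self.out / "manifest.json"
        _json_dump(self.manifest, manifest_path)
        return self.manifest

    def _stage_simulate_or_load(self):
        inputs = self.config.get("inputs") or {}
        if inputs.get("counts"):
            counts = read_counts(inputs["counts"], inputs["meta"])
            self._record("load", {"counts": inputs["counts"]}, [])
            return counts, None
        simc = self.config["simulate"]
        params = sim.SimParams(
            n_mirnas=int(simc["n_mirnas"]),
            library_size_mean=float(simc["library_size_mean"]),
            library_size_cv=float(simc["library_size_cv"]),
            dispersion=float(simc["dispersion"]),
            n_cis_down=int(simc["n_cis_down"]), n_rrms_up=int(simc["n_rrms_up"]),
            planted_log2fc=float(simc["planted_log2fc"]),
            seed=stage_seed(self.seed, "simulate"),
        )
        counts, truth = sim.simulate_counts(params)
        if simc.get("n_outliers", 0):
            counts, otruth = sim.inject_outlier_subjects(
                counts, int(simc["n_outliers"]), float(simc["outlier_severity"]),
                seed=stage_seed(self.seed, "outliers"))
            truth.outlier_subject_ids = otruth.outlier_subject_ids
        cpath, mpath = self.out / "counts.tsv", self.out / "meta.tsv"
        write_counts(counts, cpath, mpath)
        tpath = self.out / "truth.json"
        _json_dump(truth.to_dict(), tpath)
        self._record("simulate", simc, [cpath, mpath, tpath])
        self.truth = truth
        return counts, truth

    def _stage_qc(self, counts: CountMatrix):
        qcc = self.config["qc"]
        cleaned, report = qc_mod.run_qc(counts, qcc["min_count"], qcc["min_fraction"],
                                        qcc["outlier_rule"])
        cpath, mpath = self.out / "counts_clean.tsv", self.out / "meta_clean.tsv"
        write_counts(cleaned, cpath, mpath)
        rpath = self.out / "qc.json"
        _json_dump(report.to_dict(), rpath)
        self._record("qc", qcc, [cpath, mpath, rpath],
                     {"rows_in": report.n_mirnas_in, "rows_out": report.n_mirnas_kept})
        return cleaned, report

    def _stage_normalize(self, cleaned: CountMatrix):
        factors = tmm_factors(cleaned)
        norm = cpm(cleaned, factors, prior_count=self.config["de"]["prior_count"])
        fpath = self.out / "tmm_factors.tsv"
        factors.to_frame().to_csv(fpath, sep="\t", index_label="sample_id")
        vpath = self.out / "cpm.tsv"
        norm.values.to_csv(vpath, sep="\t", index_label="mirna_id")
        self._record("normalize", {"prior_count": self.config["de"]["prior_count"]},
                     [fpath, vpath])
        self.factors = factors
        return norm

    def _stage_de(self, cleaned: CountMatrix):
        dec = self.config["de"]
        present = set(cleaned.meta["group"])
        tables: dict[str, pd.DataFrame] = {}
        files = []
        for contrast in de_mod.STUDY_CONTRASTS:
            if {contrast.group_a, contrast.group_b} <= present:
                det = de_mod.de_test(cleaned, contrast, engine=dec["engine"],
                                     factors=self.factors,
                                     prior_count=dec["prior_count"],
                                     p_threshold=dec["p_threshold"],
                                     lfc_threshold=dec["lfc_threshold"])
                tables[contrast.name] = det
                path = self.out / f"de_{contrast.name}.tsv"
                det.to_csv(path, sep="\t")
                files.append(path)
        self._record("de", dec, files)
        return tables

    def _stage_specific(self, de_tables):
        sets = de_mod.stage_specific_sets(de_tables)
        path = self.out / "specific_sets.json"
        _json_dump(sets.to_dict(), path)
        self._record("specific", {}, [path])
        return sets

    def _stage_panel(self, norm, cleaned: CountMatrix, sets):
        ga, gb = self.config["panel"]["compare"]
        markers = sorted(sets.cis_specific_down | sets.rrms_specific_up)
        out = {"compare": [ga, gb], "markers": markers}
        path = self.out / "panel.json"
        if not markers:
            out["note"] = "no stage-specific markers; panel skipped"
            _json_dump(out, path)
            self._record("panel", self.config["panel"], [path])
            return None
        subjects = cleaned.samples_in_group(ga) + cleaned.samples_in_group(gb)
        labels = [s in set(cleaned.samples_in_group(ga)) for s in subjects]
        z = panel_mod.zscore_markers(norm, markers, subjects)
        result = panel_mod.build_panel(z, labels)
        t, df, p = panel_mod.panel_group_test(result.subject_scores.to_numpy(), labels)
        out["panel"] = result.to_dict()
        out["group_test"] = {"t": t, "df": df, "p": p}
        edss = cleaned.meta.loc[subjects, "edss"] if "edss" in cleaned.meta.columns else None
        if edss is not None and edss.notna().all() and len(subjects) >= 8:
            method, r, ci, pc = panel_mod.correlate_panel_covariate(
                result.subject_scores.to_numpy(), edss.to_numpy())
            out["edss_correlation"] = {"method": method, "r": r, "ci": list(ci), "p": pc}
        _json_dump(out, path)
        self._record("panel", self.config["panel"], [path])
        return result

    def _stage_enrichment(self, sets):
        ec = self.config["enrichment"]
        query = sorted(sets.rrms_specific_up)
        files = []
        if ec.get("target_map") and ec.get("gmt"):
            tmap = enr.load_target_map(ec["target_map"])
            db = enr.load_gmt(ec["gmt"])
        else:
            if not query:
                path = self.out / "enrichment.tsv"
                pd.DataFrame().to_csv(path, sep="\t")
                self._record("enrichment", ec, [path])
                return None
            targets, paths, _ = sim.simulate_enrichment_inputs(
                query, seed=stage_seed(self.seed, "enrichment"))
            tmap = enr.TargetMap(targets, provenance="synthetic")
            db = enr.PathwayDB(paths)
            tpath, gpath = self.out / "targets_synthetic.tsv", self.out / "pathways_synthetic.gmt"
            enr.write_target_map(tmap, tpath)
            enr.write_gmt(db, gpath)
            files += [tpath, gpath]
        union, per, unmapped = enr.collect_targets(query, tmap)
        res = enr.ora(union, db, per_mirna=per)
        sig = enr.filter_pathways(res, ec["alpha"], ec["min_mirnas"])
        rpath, spath = self.out / "enrichment.tsv", self.out / "enrichment_significant.tsv"
        res.sort_values("adj_p").to_csv(rpath, sep="\t")
        sig.to_csv(spath, sep="\t")
        self._record("enrichment", ec, files + [rpath, spath],
                     {"n_query_mirnas": len(query), "n_unmapped": len(unmapped)})
        return sig

    def _stage_csf(self, cleaned: CountMatrix):
        cc = self.config["csf"]
        rrms_ids = cleaned.samples_in_group("RRMS")
        path = self.out / "compartment.json"
        if len(rrms_ids) < 5:
            _json_dump({"note": "too few RRMS subjects for compartment comparison"}, path)
            self._record("csf", cc, [path])
            return None
        serum = cleaned.subset_samples(rrms_ids)
        csf, truth = sim.simulate_matched_csf(
            serum, cc["high_serum_fraction"], cc["offset_log10"], cc["noise_sd"],
            seed=stage_seed(self.seed, "csf"))
        csf, _ = qc_mod.filter_background(csf)  # only miRNAs detected in CSF pair up
        ser_norm = cpm(serum, tmm_factors(serum), prior_count=0.0)
        csf_norm = cpm(csf, tmm_factors(csf), prior_count=0.0)
        pairs = cmp.pair_compartments(ser_norm, csf_norm, truth.subject_map)
        pairs = cmp.split_populations(pairs)
        out = {"cluster_sizes": pairs.cluster_sizes, "split_threshold": pairs.split_threshold,
               "correlations": {}}
        for pop in ("similar", "high_serum"):
            if (pairs.table["population"] == pop).sum() >= 5:
                for method in ("spearman", "pearson"):
                    r, ci, p = cmp.correlate_population(pairs, pop, method=method)
                    out["correlations"][f"{pop}:{method}"] = {"r": r, "ci": list(ci), "p": p}
        _json_dump(out, path)
        tabpath = self.out / "compartment_pairs.tsv"
        pairs.table.to_csv(tabpath, sep="\t", index_label="mirna_id")
        self._record("csf", cc, [path, tabpath])
        return pairs

    def _stage_qpcr(self, cleaned: CountMatrix, sets):
        qc_cfg = self.config["qpcr"]
        targets = sorted(sets.rrms_specific_up)[: int(qc_cfg["n_targets"])]
        path = self.out / "qpcr.json"
        cis, rrms = cleaned.samples_in_group("CIS"), cleaned.samples_in_group("RRMS")
        if not targets or len(cis) < 2 or len(rrms) < 2:
            _json_dump({"note": "qPCR stage skipped (no targets or too few subjects)"}, path)
            self._record("qpcr", qc_cfg, [path])
            return None
        sub = cleaned.subset_samples(cis + rrms)
        plate, truth = sim.simulate_qpcr(
            sub, targets, replicate_sd=qc_cfg["replicate_sd"],
            outlier_rate=qc_cfg["outlier_rate"], seed=stage_seed(self.seed, "qpcr"))
        plate = qpcr_mod.replicate_qc(plate, max_dev=qc_cfg["max_dev"])
        dcq = qpcr_mod.delta_cq(plate)
        labels = pd.Series([s in set(rrms) for s in sub.sample_ids], index=sub.sample_ids)
        ttests = qpcr_mod.compare_groups_dcq(dcq, labels)
        norm = cpm(sub, tmm_factors(sub), prior_count=0.0)
        corr = qpcr_mod.crossplatform_correlation(dcq, norm.values)
        out = {
            "targets": targets,
            "t_tests": ttests.to_dict(orient="index"),
            "crossplatform_spearman": corr.to_dict(orient="index"),
            "n_flagged_replicates": int(plate.records["flagged"].sum()),
        }
        _json_dump(out, path)
        ppath = self.out / "qpcr_plate.csv"
        qpcr_mod.write_plate(plate, ppath)
        dpath = self.out / "delta_cq.tsv"
        dcq.to_csv(dpath, sep="\t")
        self._record("qpcr", qc_cfg, [path, ppath, dpath])
        return dcq


def run_pipeline(config: dict | str | Path) -> dict:
    """Run all stages from a config mapping or YAML path; returns the manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    return PipelineRun(config).run()
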