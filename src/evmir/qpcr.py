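"""RT-qPCR Delta-Cq analysis: replicate QC, group comparison, and
cross-platform correlation against sequencing counts.

Delta Cq = mean Cq of the target miRNA (over unflagged replicates) minus the
mean UniSp6 spike-in Cq for the same sample; lower Delta Cq means higher
expression.  Technical-replicate outliers are flagged after per-assay
quantile normalization across samples, using a fixed-cycle deviation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ValidationError
from .panel import panel_group_test

UNISP6 = "UniSp6"


@dataclass
class QPCRPlate:
    """Long-format plate records: sample, assay, replicate index, Cq."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "assay", "replicate", "cq"}
        if not required <= set(self.records.columns):
            raise ValidationError(f"plate needs columns {sorted(required)}")
        cq = self.records["cq"]
        if ((cq <= 0) | (cq >= 45)).any():
            raise ValidationError("Cq values must lie in (0, 45)")
        has_spike = self.records[self.records["assay"] == UNISP6]["sample"].unique()
        missing = set(self.records["sample"].unique()) - set(has_spike)
        if missing:
            raise ValidationError(f"samples without {UNISP6}: {sorted(missing)[:5]}")
        if "flagged" not in self.records.columns:
            self.records = self.records.assign(flagged=False)

    @property
    def targets(self) -> list[str]:
        return sorted(set(self.records["assay"]) - {UNISP6})


def read_plate(path) -> QPCRPlate:
    return QPCRPlate(pd.read_csv(path))


def write_plate(plate: QPCRPlate, path) -> None:
    plate.records.to_csv(path, index=False)


def replicate_qc(plate: QPCRPlate, method: str = "quantile",
                 max_dev: float = 0.5) -> QPCRPlate:
    """Flag outlier technical replicates.

    Per assay, the replicate-indexed Cq columns are quantile-normalized
    across samples (each column's empirical distribution mapped onto the
    mean sorted profile); a replicate is flagged when its normalized value
    deviates from the well median by more than ``max_dev`` cycles.  Wells
    whose replicates all get flagged are marked missing downstream.
    """
    if method != "quantile":
        raise ValidationError(f"unknown replicate-QC method {method!r}")
    rec = plate.records.copy()
    rec["flagged"] = False
    for assay, sub in rec.groupby("assay"):
        wide = sub.pivot_table(index="sample", columns="replicate", values="cq")
        if wide.shape[1] < 2:
            raise ValidationError(f"assay {assay!r} has < 2 replicates per sample")
        complete = wide.dropna()
        if len(complete) >= 3:
            # align the replicate columns on their across-sample medians (a
            # robust quantile alignment that removes systematic inter-replicate
            # shifts without letting displaced values distort the reference),
            # then flag by deviation from the well median
            offsets = complete.median(axis=0)
            adjusted = wide.sub(offsets - offsets.mean(), axis=1)
            dev = adjusted.sub(adjusted.median(axis=1), axis=0).abs()
        else:
            dev = wide.sub(wide.median(axis=1), axis=0).abs()
        flagged_wells = dev > max_dev
        for sample in flagged_wells.index:
            for repl in flagged_wells.columns:
                if flagged_wells.loc[sample, repl]:
                    mask = ((rec["assay"] == assay) & (rec["sample"] == sample)
                            & (rec["replicate"] == repl))
                    rec.loc[mask, "flagged"] = True
    return QPCRPlate(rec)


def delta_cq(plate: QPCRPlate) -> pd.DataFrame:
    """Per (sample, target) Delta Cq = mean target Cq - mean UniSp6 Cq,
    over unflagged replicates; wells with no unflagged replicate are NaN."""
    rec = plate.records
    ok = rec[~rec["flagged"]]
    spike = ok[ok["assay"] == UNISP6].groupby("sample")["cq"].mean()
    if spike.empty:
        raise ValidationError("no usable UniSp6 measurements")
    rows = []
    for (sample, assay), grp in ok[ok["assay"] != UNISP6].groupby(["sample", "assay"]):
        if sample not in spike.index:
            raise ValidationError(f"sample {sample!r} lacks UniSp6")
        rows.append({"sample": sample, "target": assay,
                     "delta_cq": grp["cq"].mean() - spike[sample],
                     "n_replicates_used": len(grp)})
    all_flagged = rec[rec["assay"] != UNISP6].groupby(["sample", "assay"])["flagged"].all()
    for (sample, assay), flag in all_flagged.items():
        if flag:
            warnings.warn(f"all replicates flagged for ({sample}, {assay}); well missing")
            rows.append({"sample": sample, "target": assay,
                         "delta_cq": np.nan, "n_replicates_used": 0})
    return pd.DataFrame(rows).set_index(["sample", "target"]).sort_index()


def compare_groups_dcq(dcq: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Unpaired two-tailed pooled-variance t-test of Delta Cq per target,
    between the two groups given by binary ``labels`` (indexed by sample)."""
    rows = []
    for target, sub in dcq.reset_index().groupby("target"):
        sub = sub.dropna(subset=["delta_cq"])
        lab = labels.reindex(sub["sample"]).to_numpy()
        t, df, p = panel_group_test(sub["delta_cq"].to_numpy(), lab.astype(bool))
        rows.append({"target": target, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows).set_index("target")


def crossplatform_correlation(dcq: pd.DataFrame, normalized_counts: pd.DataFrame,
                              samples=None) -> pd.DataFrame:
    """Spearman rho of Delta Cq vs normalized sequencing counts per target.

    True signals are expected to correlate negatively (higher expression =
    lower Delta Cq).
    """
    rows = []
    for target, sub in dcq.reset_index().groupby("target"):
        sub = sub.dropna(subset=["delta_cq"])
        if samples is not None:
            sub = sub[sub["sample"].isin(samples)]
        if target not in normalized_counts.index:
            raise ValidationError(f"target {target!r} not in normalized counts")
        common = [s for s in sub["sample"] if s in normalized_counts.columns]
        if len(common) < 5:
            raise ValidationError(f"fewer than 5 subjects with both measurements for {target!r}")
        x = sub.set_index("sample").loc[common, "delta_cq"].to_numpy()
        y = normalized_counts.loc[target, common].to_numpy(dtype=float)
        res = stats.spearmanr(x, y)
        rows.append({"target": target, "rho": float(res.statistic),
                     "p": float(res.pvalue), "n": len(common)})
    return pd.DataFrame(rows).set_index("target")
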