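"""Core in-memory containers: UMI count matrices and normalized expression matrices.

A :class:`CountMatrix` couples a miRNA x sample table of non-negative integer
UMI counts with a per-sample metadata table (group label, compartment, optional
EDSS disability score, optional pre-deduplication read totals).  All downstream
stages accept and return these containers, so validation happens once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("HealthCtl", "HospCtl", "CIS", "RRMS", "VI")


class ValidationError(ValueError):
    """Raised when an input container or parameter violates its contract."""


@dataclass
class CountMatrix:
    """miRNA x sample UMI counts with sample metadata attached by ID.

    Parameters
    ----------
    counts
        DataFrame indexed by mature miRNA ID, columns are sample IDs,
        values non-negative integers (aggregated UMIs per miRNA).
    meta
        DataFrame indexed by sample ID.  Required column ``group``; optional
        columns ``compartment`` (serum/CSF), ``edss`` and ``total_reads``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate miRNA IDs")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs")
        vals = self.counts.to_numpy()
        if vals.size and vals.min() < 0:
            raise ValidationError("negative counts")
        if "group" not in self.meta.columns:
            raise ValidationError("metadata lacks a 'group' column")
        missing = self.counts.columns.difference(self.meta.index)
        if len(missing):
            raise ValidationError(f"samples missing from metadata: {list(missing)[:5]}")
        # align metadata to the count columns
        self.meta = self.meta.loc[self.counts.columns]

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> pd.Series:
        return self.meta["group"]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.meta.index[self.meta["group"] == group])

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.counts[sample_ids].copy(), self.meta.loc[sample_ids].copy())

    def subset_mirnas(self, mirna_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(mirna_ids)].copy(), self.meta.copy())

    def drop_samples(self, sample_ids) -> "CountMatrix":
        keep = [s for s in self.sample_ids if s not in set(sample_ids)]
        return self.subset_samples(keep)


@dataclass
class NormalizedMatrix:
    """TMM-scaled counts-per-million with the factors that produced them."""

    values: pd.DataFrame
    tmm_factors: pd.Series
    library_sizes: pd.Series
    prior_count: float = 0.0
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValidationError("TMM factors must be positive")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("normalized values must be finite")

    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm_factors


def read_counts(counts_path, meta_path) -> CountMatrix:
    """Read a count TSV (first column miRNA ID) and a metadata TSV (first column sample ID)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, counts_path, meta_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="mirna_id")
    if meta_path is not None:
        cm.meta.to_csv(meta_path, sep="\t", index_label="sample_id")
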