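"""Reading, validation and read-count filtering of multi-sample SNV tables.

The raw input is a long-format TSV with one row per (SNV, sample) cell:
``snv_id  sample_id  total_reads  variant_reads``, plus a sample-metadata
TSV ``sample_id  site_label  site_class`` where ``site_class`` is
``primary`` or ``metastasis``.

Read-count filtering keeps a cell only when the total read count exceeds 40
and the variant read count exceeds six (both strict).  Cells failing the rule
are *masked*: a low-count observation is treated as missing, not as evidence
of a zero variant allele fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SNV_COLUMNS = ["snv_id", "sample_id", "total_reads", "variant_reads"]
SAMPLE_COLUMNS = ["sample_id", "site_label", "site_class"]
SITE_CLASSES = ("primary", "metastasis")


class SnvTableError(ValueError):
    """Raised for malformed SNV or sample tables."""


@dataclass
class SnvMatrix:
    """Per-SNV, per-sample total and variant read counts.

    ``mask`` (optional) marks cells whose observation passed the read-count
    filter; ``None`` means the matrix is unfiltered.
    """

    snv_ids: list[str]
    sample_ids: list[str]
    total_reads: np.ndarray
    variant_reads: np.ndarray
    mask: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.total_reads = np.asarray(self.total_reads, dtype=np.int64)
        self.variant_reads = np.asarray(self.variant_reads, dtype=np.int64)
        shape = (len(self.snv_ids), len(self.sample_ids))
        if self.total_reads.shape != shape or self.variant_reads.shape != shape:
            raise SnvTableError(
                f"count matrices must have shape {shape}, got "
                f"{self.total_reads.shape} and {self.variant_reads.shape}"
            )
        if (self.total_reads < 0).any() or (self.variant_reads < 0).any():
            raise SnvTableError("read counts must be nonnegative")
        if (self.variant_reads > self.total_reads).any():
            i, j = np.argwhere(self.variant_reads > self.total_reads)[0]
            raise SnvTableError(
                f"variant reads exceed total reads at SNV {self.snv_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if len(set(self.snv_ids)) != len(self.snv_ids):
            raise SnvTableError("duplicate snv_id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SnvTableError("duplicate sample_id")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != shape:
                raise SnvTableError("mask shape mismatch")

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnvMatrix):
            return NotImplemented
        same_mask = (
            (self.mask is None and other.mask is None)
            or (
                self.mask is not None
                and other.mask is not None
                and np.array_equal(self.mask, other.mask)
            )
        )
        return (
            self.snv_ids == other.snv_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.total_reads, other.total_reads)
            and np.array_equal(self.variant_reads, other.variant_reads)
            and same_mask
        )


def read_snv_table(path) -> SnvMatrix:
    """Parse a long-format SNV read-count TSV into an :class:`SnvMatrix`.

    Missing (snv, sample) cells become total=0, variant=0.  Malformed rows
    (negative counts, variant > total, duplicates) raise
    :class:`SnvTableError` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snv_id": str, "sample_id": str})
    missing = [c for c in SNV_COLUMNS if c not in df.columns]
    if missing:
        raise SnvTableError(f"missing columns {missing} in {path}")
    for i, row in enumerate(df.itertuples(index=False)):
        total, variant = row.total_reads, row.variant_reads
        if pd.isna(total) or pd.isna(variant):
            raise SnvTableError(f"row {i + 2}: missing read count")
        if total < 0 or variant < 0:
            raise SnvTableError(f"row {i + 2}: negative read count")
        if variant > total:
            raise SnvTableError(
                f"row {i + 2}: variant_reads {variant} > total_reads {total} "
                f"(snv {row.snv_id}, sample {row.sample_id})"
            )
    dup = df.duplicated(subset=["snv_id", "sample_id"])
    if dup.any():
        i = int(np.argmax(dup.values))
        raise SnvTableError(f"row {i + 2}: duplicate (snv_id, sample_id) cell")

    snv_ids = list(dict.fromkeys(df["snv_id"]))
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    si = {s: k for k, s in enumerate(snv_ids)}
    sj = {s: k for k, s in enumerate(sample_ids)}
    total = np.zeros((len(snv_ids), len(sample_ids)), dtype=np.int64)
    variant = np.zeros_like(total)
    for row in df.itertuples(index=False):
        i, j = si[row.snv_id], sj[row.sample_id]
        total[i, j] = row.total_reads
        variant[i, j] = row.variant_reads
    return SnvMatrix(snv_ids, sample_ids, total, variant)


def write_snv_table(m: SnvMatrix, path) -> None:
    rows = []
    for i, snv in enumerate(m.snv_ids):
        for j, sample in enumerate(m.sample_ids):
            rows.append((snv, sample, int(m.total_reads[i, j]), int(m.variant_reads[i, j])))
    pd.DataFrame(rows, columns=SNV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_info(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SnvTableError(f"missing columns {missing} in {path}")
    return validate_sample_info(df)


def validate_sample_info(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["site_class"]) - set(SITE_CLASSES)
    if bad:
        raise SnvTableError(f"unknown site_class values: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise SnvTableError("duplicate sample_id in sample table")
    classes = df.groupby("site_label")["site_class"].nunique()
    if (classes > 1).any():
        label = classes[classes > 1].index[0]
        raise SnvTableError(f"site {label!r} declared with conflicting site classes")
    return df.reset_index(drop=True)


def write_sample_info(df: pd.DataFrame, path) -> None:
    df[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def site_classes_of(sample_info: pd.DataFrame) -> dict[str, str]:
    """Map site_label -> site_class."""
    return dict(zip(sample_info["site_label"], sample_info["site_class"]))


def filter_snvs(m: SnvMatrix, min_total: int = 40, min_variant: int = 6) -> SnvMatrix:
    """Apply the strict read-count inclusion rule.

    A cell is usable only when ``total_reads > min_total`` and
    ``variant_reads > min_variant``; failing cells are masked (missing, not
    zero-VAF).  SNVs with every cell masked are dropped.  Retained counts are
    never altered, so the operation is idempotent.
    """
    mask = (m.total_reads > min_total) & (m.variant_reads > min_variant)
    keep = mask.any(axis=1)
    return SnvMatrix(
        [s for s, k in zip(m.snv_ids, keep) if k],
        list(m.sample_ids),
        m.total_reads[keep],
        m.variant_reads[keep],
        mask=mask[keep],
    )


def compute_vaf(m: SnvMatrix) -> pd.DataFrame:
    """Variant allele fraction per usable cell; masked cells are NaN.

    On an unfiltered matrix (``mask is None``) this is a utility mode where
    every cell is used and zero-coverage cells return 0.0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(m.total_reads > 0, m.variant_reads / np.maximum(m.total_reads, 1), 0.0)
    if m.mask is not None:
        vaf = np.where(m.mask, vaf, np.nan)
    return pd.DataFrame(vaf, index=list(m.snv_ids), columns=list(m.sample_ids))
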