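"""Taxa abundance tables, sample metadata, and preprocessing filters.

The data model mirrors what comes out of a 16S rRNA amplicon workflow once
reads have been denoised and assigned to species: a samples x taxa matrix of
counts (or, after total-sum scaling, relative abundances), plus a per-sample
metadata table carrying the smoking-status phenotype.

Orientation is fixed throughout the package: samples are rows, taxa are
columns. All TSV I/O declares this in a leading comment line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TaxaTable",
    "SampleMetadata",
    "BinaryLabels",
    "SMOKING_STATUSES",
    "tss_normalize",
    "filter_low_coverage",
    "filter_low_abundance",
    "intersect_taxa",
    "binarize_smoking",
    "read_taxa_tsv",
    "write_taxa_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
]

SMOKING_STATUSES = ("never", "former", "current")

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TaxaTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and taxon ids as columns.
        Values are non-negative counts or relative abundances.
    normalized:
        True iff values are relative abundances (each row sums to 1).
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("abundance matrix contains NaN or infinite entries")
        if values.size and (values < 0).any():
            raise ValueError("abundance matrix contains negative entries")
        if self.normalized and values.size:
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_SUM_TOL)
            if bad.size:
                raise ValueError(
                    "normalized table has rows not summing to 1: "
                    f"{df.index[bad][:5].tolist()}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def select_samples(self, sample_ids: Iterable[str]) -> "TaxaTable":
        return TaxaTable(self.data.loc[list(sample_ids)], normalized=self.normalized)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample phenotype and cohort descriptors.

    Columns: sample_id (index), smoking_status in {never, former, current},
    sex in {female, male}, age_group (decade label), ethnicity (free label),
    study in {S1, S2}.
    """

    data: pd.DataFrame

    REQUIRED = ("smoking_status", "sex", "age_group", "ethnicity", "study")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if df["smoking_status"].isna().any():
            bad = df.index[df["smoking_status"].isna()].tolist()
            raise ValueError(f"smoking_status missing for samples: {bad[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    def smoking_status(self) -> pd.Series:
        return self.data["smoking_status"]


@dataclass(frozen=True)
class BinaryLabels:
    """Binary smoking labels: 0 = current smoker, 1 = non-current smoker.

    The positive class for confusion-matrix bookkeeping is the smoker
    (label 0, the minority class the study cares about).
    """

    labels: pd.Series  # index: sample_id, values in {0, 1}
    positive_class: int = field(default=0)

    def __post_init__(self) -> None:
        vals = set(self.labels.unique().tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {sorted(vals)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.index.tolist()

    def to_array(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)

    def class_counts(self) -> dict[int, int]:
        counts = self.labels.value_counts().to_dict()
        return {int(k): int(v) for k, v in counts.items()}


def tss_normalize(table: TaxaTable) -> TaxaTable:
    """Total-sum scaling: divide each sample's counts by its row total.

    Raises if the table is already normalized or any row sums to zero.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    values = table.values
    sums = values.sum(axis=1)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize zero-sum sample(s): {table.data.index[zero].tolist()}"
        )
    out = pd.DataFrame(
        values / sums[:, None], index=table.data.index, columns=table.data.columns
    )
    return TaxaTable(out, normalized=True)


def filter_low_coverage(table: TaxaTable, min_reads: int = 1000) -> TaxaTable:
    """Keep samples with strictly more than ``min_reads`` total counts."""
    if table.normalized:
        raise ValueError("coverage filter applies to count tables")
    sums = table.values.sum(axis=1)
    keep = sums > min_reads
    if not keep.any():
        raise ValueError(f"no sample exceeds {min_reads} reads")
    return TaxaTable(table.data.loc[keep], normalized=False)


def filter_low_abundance(table: TaxaTable, threshold: float = 1e-4) -> TaxaTable:
    """Drop taxa whose mean relative abundance across samples is < threshold.

    Operates on a normalized table; surviving rows are NOT re-normalized here
    (renormalization is an explicit, separate ``tss_normalize`` call).
    """
    if not table.normalized:
        raise ValueError("abundance filter applies to normalized tables")
    means = table.values.mean(axis=0)
    keep = means >= threshold
    if not keep.any():
        raise ValueError(f"all taxa below mean relative abundance {threshold}")
    out = table.data.loc[:, keep]
    # surviving rows may no longer sum to 1, so the flag must drop
    return TaxaTable(out, normalized=False)


def intersect_taxa(a: TaxaTable, b: TaxaTable) -> tuple[TaxaTable, TaxaTable]:
    """Restrict both tables to their shared taxa, in lexicographic order."""
    shared = sorted(set(a.taxon_ids) & set(b.taxon_ids))
    if not shared:
        raise ValueError("taxon intersection is empty")
    return (
        TaxaTable(a.data.loc[:, shared], normalized=False),
        TaxaTable(b.data.loc[:, shared], normalized=False),
    )


def binarize_smoking(meta: SampleMetadata) -> BinaryLabels:
    """Collapse never/former into non-current (1); current smokers get 0."""
    status = meta.smoking_status()
    unknown = status[~status.isin(SMOKING_STATUSES)]
    if len(unknown):
        raise ValueError(
            f"unknown smoking_status for samples: {dict(unknown.head())}"
        )
    labels = status.map({"current": 0, "never": 1, "former": 1}).astype(int)
    labels.name = "label"
    return BinaryLabels(labels)


_ORIENTATION_COMMENT = "# samples as rows, taxa as columns"


def write_taxa_tsv(table: TaxaTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_ORIENTATION_COMMENT + "\n")
        df = table.data.copy()
        df.index.name = "sample_id"
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_taxa_tsv(path: str | Path, normalized: bool = False) -> TaxaTable:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    return TaxaTable(df, normalized=normalized)


def write_metadata_tsv(meta: SampleMetadata, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_ORIENTATION_COMMENT + "\n")
        df = meta.data.copy()
        df.index.name = "sample_id"
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_metadata_tsv(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleMetadata(df)
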