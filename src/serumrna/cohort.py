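"""Core data types and tabular I/O for the serum RNA cohort.

Two containers carry the study data: :class:`SampleRecord` (one serum sample
with its donor covariates and, for cases, stage, histology, and time to
diagnosis in months) and :class:`CountMatrix` (non-negative integer RNA x
sample counts with a per-RNA class label from the ten circulating RNA
classes).  Both round-trip through tab-separated UTF-8 text with "." decimals
and empty cells for missing values; writers emit rows in lexicographic id
order so output is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RNA_CLASSES",
    "SampleRecord",
    "CountMatrix",
    "read_sample_table",
    "write_sample_table",
    "read_count_matrix",
    "write_count_matrix",
    "filter_low_counts",
    "ParseError",
]

#: The ten circulating RNA classes profiled in serum small-RNA sequencing.
RNA_CLASSES = (
    "miRNA",
    "miRNA_hairpin",
    "isomiR",
    "piRNA",
    "tRNA",
    "tRF",
    "snoRNA",
    "miscRNA",
    "lncRNA",
    "mRNA",
)

GROUPS = ("case", "control")
SEXES = ("male", "female")
SMOKING = ("current", "former", "never", "unknown")
CASE_STAGES = ("early", "locally_advanced", "advanced", "unknown")
STAGES = CASE_STAGES + ("not_applicable",)
CASE_HISTOLOGIES = ("NSCLC", "SCLC", "ADC", "other")
HISTOLOGIES = CASE_HISTOLOGIES + ("not_applicable",)

EVER_SMOKER = ("current", "former")

SAMPLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "group",
    "sex",
    "age_at_donation",
    "bdg",
    "smoking",
    "stage",
    "histology",
    "time_to_diagnosis",
)


class ParseError(ValueError):
    """A tabular input file could not be parsed or validated."""


@dataclass(frozen=True)
class SampleRecord:
    """One serum sample with donor covariates and case annotations.

    Times are stored in months before diagnosis (1 year = 12 months);
    controls carry no ``time_to_diagnosis`` and have stage and histology
    ``not_applicable``.
    """

    sample_id: str
    subject_id: str
    group: str
    sex: str
    age_at_donation: float
    bdg: str
    smoking: str
    stage: str = "not_applicable"
    histology: str = "not_applicable"
    time_to_diagnosis: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"sample {self.sample_id}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sample {self.sample_id}: unknown sex {self.sex!r}")
        if self.smoking not in SMOKING:
            raise ValueError(f"sample {self.sample_id}: unknown smoking {self.smoking!r}")
        if self.stage not in STAGES:
            raise ValueError(f"sample {self.sample_id}: unknown stage {self.stage!r}")
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"sample {self.sample_id}: unknown histology {self.histology!r}")
        if not math.isfinite(self.age_at_donation) or self.age_at_donation <= 0:
            raise ValueError(f"sample {self.sample_id}: invalid age {self.age_at_donation}")
        if self.group == "control":
            if self.time_to_diagnosis is not None:
                raise ValueError(f"control {self.sample_id} must not carry time_to_diagnosis")
            if self.stage != "not_applicable" or self.histology != "not_applicable":
                raise ValueError(
                    f"control {self.sample_id} must have stage and histology 'not_applicable'"
                )
        else:
            if self.time_to_diagnosis is None:
                raise ValueError(f"case {self.sample_id} requires time_to_diagnosis")
            if not 0 <= self.time_to_diagnosis <= 120:
                raise ValueError(
                    f"case {self.sample_id}: time_to_diagnosis {self.time_to_diagnosis}"
                    " outside [0, 120] months"
                )
            if self.stage == "not_applicable" or self.histology == "not_applicable":
                raise ValueError(f"case {self.sample_id} requires stage and histology")

    @property
    def is_ever_smoker(self) -> bool:
        return self.smoking in EVER_SMOKER


def months_to_years(months: float) -> float:
    return months / 12.0


def years_to_months(years: float) -> float:
    return years * 12.0


def samples_to_frame(samples: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tabulate sample records as a DataFrame with the canonical columns."""
    rows = [
        {
            "sample_id": s.sample_id,
            "subject_id": s.subject_id,
            "group": s.group,
            "sex": s.sex,
            "age_at_donation": s.age_at_donation,
            "bdg": s.bdg,
            "smoking": s.smoking,
            "stage": s.stage,
            "histology": s.histology,
            "time_to_diagnosis": s.time_to_diagnosis,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))


def write_sample_table(samples: Sequence[SampleRecord], path: str | Path) -> None:
    """Write sample records to TSV, rows sorted lexicographically by id."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in cohort")
    df = samples_to_frame(sorted(samples, key=lambda s: s.sample_id))
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a sample table; raises :class:`ParseError` naming the bad line."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            age = float(row.age_at_donation)
            ttd = float(row.time_to_diagnosis) if row.time_to_diagnosis != "" else None
            records.append(
                SampleRecord(
                    sample_id=row.sample_id,
                    subject_id=row.subject_id,
                    group=row.group,
                    sex=row.sex,
                    age_at_donation=age,
                    bdg=row.bdg,
                    smoking=row.smoking,
                    stage=row.stage if row.stage != "" else "not_applicable",
                    histology=row.histology if row.histology != "" else "not_applicable",
                    time_to_diagnosis=ttd,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from exc
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids")
    return records


@dataclass
class CountMatrix:
    """RNA x sample matrix of non-negative integer counts with class labels."""

    rna_ids: list[str]
    rna_class: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.rna_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.rna_ids)} RNAs x {len(self.sample_ids)} samples"
            )
        if len(self.rna_class) != len(self.rna_ids):
            raise ValueError("rna_class length must match rna_ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        bad = sorted({c for c in self.rna_class if c not in RNA_CLASSES})
        if bad:
            raise ValueError(f"unknown RNA classes: {bad}")
        if len(set(self.rna_ids)) != len(self.rna_ids):
            raise ValueError("duplicate rna_id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def class_of(self, rna_id: str) -> str:
        return self.rna_class[self.rna_ids.index(rna_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Column subset in the given order (ids must all be present)."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in count matrix: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return CountMatrix(
            rna_ids=list(self.rna_ids),
            rna_class=list(self.rna_class),
            sample_ids=list(sample_ids),
            counts=self.counts[:, cols],
        )

    def subset_rnas(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            rna_ids=[self.rna_ids[i] for i in idx],
            rna_class=[self.rna_class[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "rna_class", self.rna_class)
        df.insert(0, "rna_id", self.rna_ids)
        return df


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write counts to TSV with columns [rna_id, rna_class, <sample ids...>].

    Rows and sample columns are sorted lexicographically by id.
    """
    row_order = np.argsort(np.asarray(m.rna_ids, dtype=object))
    col_ids = sorted(m.sample_ids)
    ordered = m.subset_samples(col_ids).subset_rnas(row_order)
    ordered.to_frame().to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a count matrix TSV; counts must be non-negative integers."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["rna_id", "rna_class"]:
        raise ParseError(f"{path}: expected columns [rna_id, rna_class, <sample ids...>]")
    counts = df.iloc[:, 2:].to_numpy()
    try:
        return CountMatrix(
            rna_ids=df["rna_id"].astype(str).tolist(),
            rna_class=df["rna_class"].astype(str).tolist(),
            sample_ids=[str(c) for c in df.columns[2:]],
            counts=counts,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def filter_low_counts(
    m: CountMatrix, min_reads: int = 5, min_fraction: float = 0.20
) -> CountMatrix:
    """Retain RNAs with >= ``min_reads`` reads in >= ``min_fraction`` of samples.

    Both boundaries are inclusive; kept rows are bit-identical and the sample
    set is unchanged.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if m.counts.size == 0:
        raise ValueError("cannot filter an empty count matrix")
    frac = (m.counts >= min_reads).mean(axis=1)
    return m.subset_rnas(frac >= min_fraction)
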