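"""Expression breadth, level summaries, PEM, and the derived classifications.

Works on CAGE-style TPM tables (rows = transcripts, columns = samples).  A
transcript is 'on' in a sample when its TPM strictly exceeds the cutoff
(default 10 TPM, roughly 3 mRNA copies per cell at 300,000 mRNAs/cell).  The
breadth of expression (BoE) is the fraction of samples in which the
transcript is on.

Two families of level summaries are provided: across all samples (which is
mechanically coupled to breadth, since off samples contribute zeros) and
conditioned on the on samples only (which removes that circularity).  The
preferential expression measure (PEM) of a transcript in a sample is its TPM
there divided by its mean TPM over all samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BreadthClass",
    "QuadrantClass",
    "ExpressionTable",
    "LevelSummaries",
    "read_expression_table",
    "write_expression_table",
    "breadth",
    "level_summaries",
    "pem",
    "pem_avg",
    "tpm_to_copies",
    "classify_breadth",
    "classify_quadrant",
    "summarize_expression",
]

DEFAULT_ON_CUTOFF = 10.0
DEFAULT_CUTOFFS = (10.0, 100.0, 1000.0)


class BreadthClass(str, enum.Enum):
    UNEXPRESSED = "unexpressed"
    NARROW = "narrow"
    INTERMEDIATE = "intermediate"
    HOUSEKEEPING = "housekeeping"


class QuadrantClass(str, enum.Enum):
    A = "A"  # broad, Tfbs-rich
    B = "B"  # broad, Tfbs-poor
    C = "C"  # narrow, Tfbs-rich
    D = "D"  # narrow, Tfbs-poor


@dataclass(frozen=True)
class LevelSummaries:
    mean_all: float
    median_all: float
    max_all: float
    mean_on: float  # NaN when no sample exceeds the cutoff
    median_on: float  # NaN likewise


@dataclass(frozen=True)
class ExpressionTable:
    """A TPM matrix plus a per-sample class (tissue / primary_cell / cancer_cell_line)."""

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        if not self.values.columns.equals(self.sample_class.index):
            raise ValueError("sample_class index must match the table's columns")

    @property
    def tx_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, sample_class: str) -> "ExpressionTable":
        cols = self.sample_class.index[self.sample_class == sample_class]
        return ExpressionTable(self.values[cols], self.sample_class[cols])


def read_expression_table(
    source: str | Path | IO[str],
    sample_class: Mapping[str, str] | str = "tissue",
) -> ExpressionTable:
    """Read an OSC-style tab-delimited TPM table.

    Lines starting with '#' are header/comment lines and are skipped; the
    first non-comment line names the samples, the first column holds
    transcript accessions.  ``sample_class`` is either one class applied to
    every column or a per-sample mapping.
    """
    df = pd.read_csv(source, sep="\t", comment="#", index_col=0)
    if isinstance(sample_class, str):
        cls = pd.Series(sample_class, index=df.columns)
    else:
        cls = pd.Series({c: sample_class[c] for c in df.columns})
    return ExpressionTable(df.astype(float), cls)


def write_expression_table(table: ExpressionTable, stream: IO[str]) -> None:
    stream.write("# TPM expression table (rows = transcripts, columns = samples)\n")
    stream.write("# sample_class: " + ",".join(table.sample_class.astype(str)) + "\n")
    table.values.to_csv(stream, sep="\t", index_label="tx_id")


def breadth(expr_row: Sequence[float] | np.ndarray, cutoff_tpm: float = DEFAULT_ON_CUTOFF) -> float:
    """Fraction of samples in which TPM strictly exceeds the cutoff."""
    if cutoff_tpm < 0:
        raise ValueError("cutoff must be non-negative")
    x = np.asarray(expr_row, dtype=float)
    if x.size == 0:
        raise ValueError("expression row has no samples")
    return float(np.mean(x > cutoff_tpm))


def level_summaries(
    expr_row: Sequence[float] | np.ndarray, cutoff_tpm: float = DEFAULT_ON_CUTOFF
) -> LevelSummaries:
    """All-sample and breadth-conditioned ('on' samples only) level summaries."""
    x = np.asarray(expr_row, dtype=float)
    on = x[x > cutoff_tpm]
    return LevelSummaries(
        mean_all=float(x.mean()),
        median_all=float(np.median(x)),
        max_all=float(x.max()),
        mean_on=float(on.mean()) if on.size else float("nan"),
        median_on=float(np.median(on)) if on.size else float("nan"),
    )


def pem(expr_row: Sequence[float] | np.ndarray) -> np.ndarray:
    """Per-sample TPM divided by the mean TPM over all samples (mean PEM = 1)."""
    x = np.asarray(expr_row, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("PEM undefined for an all-zero expression row")
    return x / m


def pem_avg(table: ExpressionTable | pd.DataFrame, sample: str) -> float:
    """Unweighted mean over transcripts of PEM in one sample.

    Transcripts with an all-zero row (undefined PEM) are excluded.  A sample
    enriched in preferentially expressed genes scores above 1.
    """
    df = table.values if isinstance(table, ExpressionTable) else table
    means = df.mean(axis=1)
    ok = means > 0
    if not ok.any():
        raise ValueError("no transcript has a defined PEM")
    return float((df.loc[ok, sample] / means[ok]).mean())


def tpm_to_copies(tpm: float, total_mrna_per_cell: float = 300_000.0) -> float:
    """mRNA copies per cell implied by a TPM value (10 TPM ~ 3 copies at 3e5 mRNAs)."""
    if tpm < 0 or total_mrna_per_cell < 0:
        raise ValueError("tpm and total_mrna_per_cell must be non-negative")
    return tpm * total_mrna_per_cell / 1e6


def classify_breadth(boe: float) -> BreadthClass:
    """unexpressed (BoE=0) / narrow (<=0.33) / intermediate (<=0.66) / housekeeping."""
    if not (0 <= boe <= 1):
        raise ValueError("BoE must lie in [0, 1]")
    if boe == 0:
        return BreadthClass.UNEXPRESSED
    if boe <= 0.33:
        return BreadthClass.NARROW
    if boe <= 0.66:
        return BreadthClass.INTERMEDIATE
    return BreadthClass.HOUSEKEEPING


def classify_quadrant(
    tfbs_no: float, boe: float, tfbs_rich: float = 10, broad: float = 0.33
) -> QuadrantClass:
    """A: broad & rich, B: broad & poor, C: narrow & rich, D: narrow & poor.

    'Rich' is >= 10 binding sites; 'broad' is BoE > 0.33.
    """
    if tfbs_no < 0:
        raise ValueError("tfbs_no must be non-negative")
    is_broad = boe > broad
    is_rich = tfbs_no >= tfbs_rich
    if is_broad:
        return QuadrantClass.A if is_rich else QuadrantClass.B
    return QuadrantClass.C if is_rich else QuadrantClass.D


def summarize_expression(
    table: ExpressionTable,
    cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
    active_cutoff: float = DEFAULT_ON_CUTOFF,
) -> pd.DataFrame:
    """Tidy per-transcript summary: BoE per cutoff, levels, and breadth class."""
    vals = table.values.to_numpy()
    n = vals.shape[1]
    if n == 0:
        raise ValueError("expression table has no samples")
    out: dict[str, np.ndarray] = {}
    for c in cutoffs:
        out[f"boe_{c:g}"] = (vals > c).sum(axis=1) / n
    out["mean_all"] = vals.mean(axis=1)
    out["median_all"] = np.median(vals, axis=1)
    out["max_all"] = vals.max(axis=1)
    on_mask = vals > active_cutoff
    on_count = on_mask.sum(axis=1)
    mean_on = np.full(len(vals), np.nan)
    median_on = np.full(len(vals), np.nan)
    has_on = on_count > 0
    mean_on[has_on] = (vals * on_mask).sum(axis=1)[has_on] / on_count[has_on]
    for i in np.nonzero(has_on)[0]:
        median_on[i] = np.median(vals[i, on_mask[i]])
    out["mean_on"] = mean_on
    out["median_on"] = median_on
    df = pd.DataFrame(out, index=table.tx_ids)
    boe_col = f"boe_{active_cutoff:g}"
    df["breadth_class"] = [classify_breadth(b).value for b in df[boe_col]]
    return df
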