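"""Per-promoter binding-site metrics and promoter-scale estimators.

Four count variants are computed per transcript: the total number of mapped
binding sites (``tfbs_total``), the number of distinct TF labels
(``tfbs_unique``), and both again with RNA-polymerase-class labels excluded
(``tfbs_total_nopol2``, ``tfbs_unique_nopol2``).  The distinction matters
because highly transcribed genes accumulate polymerase peaks, and because the
upstream peak-merging pipelines can leave one TF with several sites in the
same promoter.

Also here: Tukey five-number summaries of the count distribution,
sequence-composition covariates (GC, CpG, CpG observed/expected), the
effective-promoter-size estimator (where the growth of the mean count with
window size linearizes into background), and the "stacking" randomization
test for mutually overlapping, TSS-piled binding sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .intervals import (
    GenomicInterval,
    PromoterWindow,
    TranscriptAnnotation,
    map_peaks_to_windows,
    overlap_length,
    promoter_window,
)

__all__ = [
    "POL2_LABELS",
    "SVM_POL2_LABELS",
    "DEFAULT_GRID",
    "ArchitectureProfile",
    "CountDistributionSummary",
    "CompositionProfile",
    "BoundaryEstimate",
    "StackingResult",
    "count_metrics",
    "profiles_to_frame",
    "label_count_matrix",
    "summarize_distribution",
    "compute_composition",
    "estimate_boundary",
    "pairwise_overlap_percent",
    "stacking_test",
]

# Polymerase-class antibodies excluded by the *_nopol2 count variants.
POL2_LABELS = frozenset({"Pol2", "Pol2-4H8", "POLR2A", "Pol3"})
# The predictor's no-polymerase control additionally drops the general
# initiation factor TAF1 (a constitutive component of the apparatus).
SVM_POL2_LABELS = POL2_LABELS | {"TAF1"}

# Window half-widths swept by the boundary estimator (bases each side of TSS).
DEFAULT_GRID = (250, 500, 1000, 2000, 3000, 4000, 5000, 7500, 10000)


@dataclass(frozen=True)
class ArchitectureProfile:
    tx_id: str
    window_half_width: int
    score_cutoff: int
    tfbs_total: int
    tfbs_unique: int
    tfbs_total_nopol2: int
    tfbs_unique_nopol2: int


@dataclass(frozen=True)
class CountDistributionSummary:
    tukey_five: tuple[float, float, float, float, float]
    mean: float
    sd: float
    quantile_90: float
    pct_1tf: float
    pct_2tf: float
    pct_le5tf: float


@dataclass(frozen=True)
class CompositionProfile:
    gc: float
    cpg_count: int
    cpg_oe: float


@dataclass(frozen=True)
class BoundaryEstimate:
    grid: tuple[int, ...]
    mean_counts: tuple[float, ...]
    smoothed: tuple[float, ...]
    derivative: tuple[float, ...]
    boundary: int


@dataclass(frozen=True)
class StackingResult:
    observed_mean_overlap_pct: float
    null_mean_overlap_pct: float
    t_statistic: float
    p_value: float
    n_pairs: int


def count_metrics(
    window_peaks: Mapping[str, Sequence[GenomicInterval]],
    pol2_labels: Iterable[str] = POL2_LABELS,
    *,
    window_half_width: int = 500,
    score_cutoff: int = 0,
) -> dict[str, ArchitectureProfile]:
    """The four per-transcript binding-site counts.

    ``tfbs_unique`` counts each distinct TF label once regardless of how many
    sites carry it; the ``_nopol2`` variants drop sites whose label is in
    ``pol2_labels``.
    """
    pol2 = frozenset(pol2_labels)
    out: dict[str, ArchitectureProfile] = {}
    for tx_id, peaks in window_peaks.items():
        labels = [p.label for p in peaks]
        nopol2 = [lab for lab in labels if lab not in pol2]
        out[tx_id] = ArchitectureProfile(
            tx_id=tx_id,
            window_half_width=window_half_width,
            score_cutoff=score_cutoff,
            tfbs_total=len(labels),
            tfbs_unique=len(set(labels)),
            tfbs_total_nopol2=len(nopol2),
            tfbs_unique_nopol2=len(set(nopol2)),
        )
    return out


def profiles_to_frame(profiles: Mapping[str, ArchitectureProfile]) -> pd.DataFrame:
    """One row per transcript, columns as in :class:`ArchitectureProfile`."""
    rows = [vars(p) for p in profiles.values()]
    df = pd.DataFrame(rows).set_index("tx_id")
    return df.sort_index()


def label_count_matrix(
    window_peaks: Mapping[str, Sequence[GenomicInterval]],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Transcript x TF-label matrix of site counts (the predictor's features)."""
    all_labels = labels if labels is not None else sorted(
        {p.label for peaks in window_peaks.values() for p in peaks}
    )
    idx = {lab: j for j, lab in enumerate(all_labels)}
    tx_ids = sorted(window_peaks)
    mat = np.zeros((len(tx_ids), len(all_labels)), dtype=int)
    for i, tx in enumerate(tx_ids):
        for p in window_peaks[tx]:
            j = idx.get(p.label)
            if j is not None:
                mat[i, j] += 1
    return pd.DataFrame(mat, index=tx_ids, columns=list(all_labels))


def _fivenum(x: np.ndarray) -> tuple[float, float, float, float, float]:
    # Tukey's five numbers with the classic hinge rule (R's fivenum): hinges
    # are medians of the halves including the overall median when n is odd.
    x = np.sort(x)
    n = len(x)
    n4 = math.floor((n + 3) / 2) / 2
    d = np.array([1.0, n4, (n + 1) / 2, n + 1 - n4, float(n)])
    lo = x[np.floor(d).astype(int) - 1]
    hi = x[np.ceil(d).astype(int) - 1]
    return tuple(0.5 * (lo + hi))  # type: ignore[return-value]


def summarize_distribution(counts: Sequence[int] | np.ndarray) -> CountDistributionSummary:
    """Tukey five numbers, moments, and the 1/2/up-to-5 TF percentages.

    ``pct_le5tf`` is the percentage of transcripts with between 1 and 5
    mapped sites (the "up to 5 TFs" column excludes zero-count genes, as do
    the 1 TF and 2 TFs columns).
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("counts must be non-empty")
    return CountDistributionSummary(
        tukey_five=_fivenum(x),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        quantile_90=float(np.quantile(x, 0.9)),
        pct_1tf=100.0 * float(np.mean(x == 1)),
        pct_2tf=100.0 * float(np.mean(x == 2)),
        pct_le5tf=100.0 * float(np.mean((x >= 1) & (x <= 5))),
    )


def compute_composition(sequence: str) -> CompositionProfile:
    """GC fraction, CpG dinucleotide count, and observed/expected CpG ratio.

    CpGoe = (#CG x effective length) / (#C x #G); Ns are excluded from the
    effective length and the ratio is defined as 0 when #C*#G = 0.  CpGoe is
    a classic proxy for germline methylation (methylated CpGs decay, so
    unmethylated promoters retain CpGoe near or above 1).
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    eff_len = sum(seq.count(b) for b in "ACGT")
    if eff_len == 0:
        raise ValueError("sequence contains no unambiguous bases")
    cpg = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    cpg_oe = (cpg * eff_len) / (n_c * n_g) if n_c * n_g > 0 else 0.0
    return CompositionProfile(gc=(n_c + n_g) / eff_len, cpg_count=cpg, cpg_oe=cpg_oe)


def estimate_boundary(
    annotations: Sequence[TranscriptAnnotation],
    peaks: Sequence[GenomicInterval],
    grid: Sequence[int] = DEFAULT_GRID,
    smoothing_span: float = 0.35,
    tolerance: float = 0.05,
    chrom_sizes: Mapping[str, int] | None = None,
) -> BoundaryEstimate:
    """Effective promoter half-width from the linearization of count growth.

    The mean per-transcript site count is computed at each half-width on the
    grid; a local-polynomial (lowess) smooth of mean count versus half-width
    is differentiated, and the boundary is the smallest grid point after
    which the absolute change of the derivative stays below
    ``tolerance * max|derivative|`` for all larger grid points - i.e. where
    TSS-proximal enrichment has decayed into the uniform background rate.
    """
    grid = tuple(int(g) for g in grid)
    if len(grid) < 5:
        raise ValueError("grid must have at least 5 points")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")

    means = []
    for hw in grid:
        windows = [promoter_window(tx, hw, chrom_sizes) for tx in annotations]
        mapped = map_peaks_to_windows(windows, peaks)
        means.append(float(np.mean([len(v) for v in mapped.values()])))
    g = np.asarray(grid, dtype=float)
    y = np.asarray(means)

    smoothed = lowess(y, g, frac=smoothing_span, it=0, return_sorted=False)
    if np.any(~np.isfinite(smoothed)):  # degenerate span on a short grid
        smoothed = y.copy()
    deriv = np.diff(smoothed) / np.diff(g)

    changes = np.abs(np.diff(deriv))  # change j sits at grid point j+1
    thresh = tolerance * float(np.max(np.abs(deriv)))
    above = np.nonzero(changes >= thresh)[0]
    # Boundary = smallest grid point after which every change is sub-threshold,
    # i.e. the grid point at the last super-threshold change (or the first
    # grid point if the derivative is constant throughout).
    boundary = grid[0] if above.size == 0 else grid[int(above[-1]) + 1]
    return BoundaryEstimate(
        grid=grid,
        mean_counts=tuple(float(v) for v in y),
        smoothed=tuple(float(v) for v in smoothed),
        derivative=tuple(float(v) for v in deriv),
        boundary=int(boundary),
    )


def pairwise_overlap_percent(peaks: Sequence[GenomicInterval]) -> list[float]:
    """100 * overlap / union for every unordered peak pair in one promoter.

    The union of the two intervals is the denominator, keeping each value in
    [0, 100] and symmetric.  Fewer than two peaks yields an empty list.
    """
    out: list[float] = []
    for i in range(len(peaks)):
        for j in range(i + 1, len(peaks)):
            a, b = peaks[i], peaks[j]
            ov = overlap_length(a, b)
            union = len(a) + len(b) - ov
            out.append(100.0 * ov / union)
    return out


def stacking_test(
    windows_with_peaks: Sequence[tuple[PromoterWindow, Sequence[GenomicInterval]]],
    n_randomizations: int = 1,
    seed: int | None = None,
) -> StackingResult:
    """Are binding sites "stacked" (mutually overlapping near the TSS)?

    Pools the pairwise overlap percentages across all promoters with >= 2
    peaks, then rebuilds the same promoters ``n_randomizations`` times with
    each peak given a uniform random start that keeps it inside its window
    (lengths and counts preserved), and compares the two pools with a Welch
    two-sample t-test.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    observed: list[float] = []
    eligible: list[tuple[PromoterWindow, Sequence[GenomicInterval]]] = []
    for win, peaks in windows_with_peaks:
        if len(peaks) >= 2:
            eligible.append((win, peaks))
            observed.extend(pairwise_overlap_percent(peaks))
    if not eligible:
        raise ValueError("no promoter has >= 2 peaks")

    null: list[float] = []
    for _ in range(n_randomizations):
        for win, peaks in eligible:
            lo, hi = win.interval.start, win.interval.end
            placed = []
            for p in peaks:
                length = min(len(p), hi - lo)
                start = int(rng.integers(lo, hi - length + 1))
                placed.append(GenomicInterval(p.chrom, start, start + length, p.strand, p.score, p.label))
            null.extend(pairwise_overlap_percent(placed))

    t, p = stats.ttest_ind(observed, null, equal_var=False)
    return StackingResult(
        observed_mean_overlap_pct=float(np.mean(observed)),
        null_mean_overlap_pct=float(np.mean(null)),
        t_statistic=float(t),
        p_value=float(p),
        n_pairs=len(observed),
    )
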