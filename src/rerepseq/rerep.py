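"""Re-replication detection from binned genomic DNA coverage.

Pipeline: 100-bp bin counts -> pseudocounted normalized scores ->
log2(mutant/wild-type) -> 1-kb sliding windows (500-bp step) -> genome-wide
Z-standardization -> Z > 2 segmentation with 500-bp gap merging -> TEs
overlapping a called region by >= 1 bp are re-replicating.  Also provides
coarse chromosomal views, heterochromatin read-fraction statistics, and
per-TE DNA read densities with a rank-sum comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import ReadPlacements, RegionSet, TEAnnotation
from .signal import BinnedSignal, bin_counts, triangular_smooth


def pseudocount(library_size_millions: float) -> float:
    """Pseudocount c = (library size in millions of mapping reads) / 10.

    Keeps every bin score strictly positive so log2 ratios are finite; a
    68-million-read library gets c = 6.8.
    """
    if library_size_millions <= 0:
        raise ValueError("library size must be positive")
    return library_size_millions / 10.0


@dataclass
class ScoreTrack:
    """Pseudocounted, depth-normalized read scores per 100-bp bin.

    score[i] = (n_i + c) / 0.1 kb / M  with M the library size in millions.
    """

    signal: BinnedSignal
    pseudocount: float
    library_size_millions: float


def score_track(
    counts: BinnedSignal,
    library_size_millions: float,
    pseudocount_value: float | None = None,
) -> ScoreTrack:
    """Convert raw bin counts into pseudocounted reads/kb/million scores."""
    c = (
        pseudocount(library_size_millions)
        if pseudocount_value is None
        else pseudocount_value
    )
    if c <= 0:
        raise ValueError("pseudocount must be positive")
    kb = counts.bin_width / 1000.0
    m = library_size_millions
    signal = counts.map(lambda v: (v + c) / kb / m, semantics="score")
    return ScoreTrack(
        signal=signal, pseudocount=c, library_size_millions=m
    )


def log2_ratio(mut: ScoreTrack, wt: ScoreTrack) -> BinnedSignal:
    """Elementwise log2(mutant score / wild-type score); finite everywhere."""
    if mut.signal.bin_width != wt.signal.bin_width:
        raise ValueError("score tracks have different bin widths")
    if set(mut.signal.values) != set(wt.signal.values):
        raise ValueError("score tracks cover different chromosomes")
    values = {
        c: np.log2(mut.signal.values[c] / wt.signal.values[c])
        for c in mut.signal.values
    }
    return BinnedSignal(
        values=values, bin_width=mut.signal.bin_width, semantics="log2_ratio"
    )


@dataclass
class WindowZ:
    """Sliding-window mean log2 ratios with their Z-standardization."""

    table: pd.DataFrame  # columns: chrom, start, end, value, z
    window_bp: int
    step_bp: int


def window_z(
    ratio: BinnedSignal,
    window_bp: int = 1000,
    step_bp: int = 500,
    per_chrom: bool = False,
) -> WindowZ:
    """Tile the ratio track into overlapping windows and Z-score them.

    Window value = arithmetic mean of its constituent fine-bin log2 ratios.
    Standardization uses the mean and SD over all windows (genome-wide by
    default; ``per_chrom`` standardizes each chromosome separately).  A
    constant track (SD = 0) maps to z = 0 everywhere.  Partial windows at
    chromosome ends are dropped so the Z population is homogeneous.
    """
    bw = ratio.bin_width
    if window_bp % bw or step_bp % bw:
        raise ValueError("window and step must be multiples of the bin width")
    if window_bp % step_bp:
        raise ValueError("step must divide the window")
    w_bins = window_bp // bw
    s_bins = step_bp // bw
    frames = []
    for chrom in sorted(ratio.values):
        v = np.asarray(ratio.values[chrom], dtype=float)
        n = len(v)
        if n < w_bins:
            continue
        csum = np.concatenate(([0.0], np.cumsum(v)))
        starts = np.arange(0, n - w_bins + 1, s_bins)
        means = (csum[starts + w_bins] - csum[starts]) / w_bins
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts * bw,
                    "end": (starts + w_bins) * bw,
                    "value": means,
                }
            )
        )
    if not frames:
        raise ValueError("no complete windows (chromosomes shorter than window)")
    table = pd.concat(frames, ignore_index=True)
    if len(table) < 2:
        raise ValueError("fewer than 2 windows: standard deviation undefined")

    def _standardize(values: np.ndarray) -> np.ndarray:
        mu = values.mean()
        sd = values.std(ddof=0)
        # a constant track has no signal; tolerate cumsum rounding noise
        if sd <= 1e-12 * max(1.0, abs(mu)):
            return np.zeros_like(values)
        return (values - mu) / sd

    if per_chrom:
        table["z"] = table.groupby("chrom")["value"].transform(
            lambda s: _standardize(s.to_numpy())
        )
    else:
        table["z"] = _standardize(table["value"].to_numpy())
    return WindowZ(table=table, window_bp=window_bp, step_bp=step_bp)


@dataclass
class RereplicationCalls:
    regions: RegionSet
    region_stats: pd.DataFrame  # per region: max_z, mean_log2_ratio
    rerep_te_ids: set


def call_regions(
    wz: WindowZ, z_cut: float = 2.0, merge_gap_bp: int = 500
) -> RegionSet:
    """Segment re-replicated regions: windows with z > z_cut, merged when
    separated by <= merge_gap_bp (overlapping and adjacent windows merge)."""
    passing = wz.table[wz.table["z"] > z_cut]
    if not len(passing):
        return RegionSet.from_tuples([], label="rerep")
    regions = RegionSet(
        passing[["chrom", "start", "end"]].copy(), label="rerep"
    )
    return regions.merge(gap=merge_gap_bp)


def region_stats(regions: RegionSet, wz: WindowZ) -> pd.DataFrame:
    """Per-region max z and mean window log2 ratio over contained windows."""
    rows = []
    t = wz.table
    for row in regions.table.itertuples(index=False):
        sel = (
            (t["chrom"] == row.chrom)
            & (t["start"] < row.end)
            & (t["end"] > row.start)
        )
        sub = t[sel]
        rows.append(
            (
                row.chrom,
                row.start,
                row.end,
                float(sub["z"].max()) if len(sub) else np.nan,
                float(sub["value"].mean()) if len(sub) else np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "max_z", "mean_log2_ratio"]
    )


def annotate_rerep_tes(regions: RegionSet, tes: TEAnnotation) -> set:
    """TE ids overlapping any called region by at least 1 bp (half-open
    touching does not count)."""
    out = set()
    merged = regions.merge()
    for chrom, grp in merged.table.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        sub = tes.table[tes.table["chrom"] == chrom]
        for te in sub.itertuples(index=False):
            # regions are disjoint and sorted, so ends are increasing
            idx = np.searchsorted(starts, te.end, side="left")
            if idx > 0 and ends[idx - 1] > te.start:
                out.add(te.te_id)
    return out


def call_rereplication(
    mut: ReadPlacements,
    wt: ReadPlacements,
    chrom_sizes: dict,
    tes: TEAnnotation | None = None,
    bin_width: int = 100,
    window_bp: int = 1000,
    step_bp: int = 500,
    z_cut: float = 2.0,
    merge_gap_bp: int = 500,
    per_chrom: bool = False,
) -> RereplicationCalls:
    """End-to-end caller from deduplicated placements to region/TE calls."""
    mut_counts = bin_counts(mut, chrom_sizes, bin_width)
    wt_counts = bin_counts(wt, chrom_sizes, bin_width)
    mut_scores = score_track(mut_counts, mut.library_size_millions)
    wt_scores = score_track(wt_counts, wt.library_size_millions)
    ratio = log2_ratio(mut_scores, wt_scores)
    wz = window_z(ratio, window_bp=window_bp, step_bp=step_bp, per_chrom=per_chrom)
    regions = call_regions(wz, z_cut=z_cut, merge_gap_bp=merge_gap_bp)
    stats_frame = region_stats(regions, wz)
    te_ids = annotate_rerep_tes(regions, tes) if tes is not None else set()
    return RereplicationCalls(
        regions=regions, region_stats=stats_frame, rerep_te_ids=te_ids
    )


def chromosome_view(
    mut: ReadPlacements,
    wt: ReadPlacements,
    chrom_sizes: dict,
    bin_bp: int = 100_000,
    smooth_iters: int = 10,
    mode: str = "log2",
):
    """Coarse chromosomal profiles for browser-style views.

    ``mode='density'`` returns (mut_density, wt_density) as normalized read
    densities (reads/base/million uniquely mapping reads), each smoothed
    triangularly ``smooth_iters`` times.  ``mode='log2'`` returns the
    smoothed log2 ratio of pseudocounted densities.
    """
    mut_counts = bin_counts(mut, chrom_sizes, bin_bp)
    wt_counts = bin_counts(wt, chrom_sizes, bin_bp)
    m_mut = mut.library_size_millions
    m_wt = wt.library_size_millions
    if mode == "density":
        out = []
        for counts, m in ((mut_counts, m_mut), (wt_counts, m_wt)):
            dens = counts.map(lambda v: v / bin_bp / m, semantics="density")
            out.append(
                dens.map(lambda v: triangular_smooth(v, smooth_iters))
            )
        return tuple(out)
    if mode == "log2":
        c_mut = pseudocount(m_mut)
        c_wt = pseudocount(m_wt)
        values = {}
        for chrom in chrom_sizes:
            dm = (mut_counts.values[chrom] + c_mut) / bin_bp / m_mut
            dw = (wt_counts.values[chrom] + c_wt) / bin_bp / m_wt
            values[chrom] = triangular_smooth(np.log2(dm / dw), smooth_iters)
        return BinnedSignal(
            values=values, bin_width=bin_bp, semantics="log2_ratio"
        )
    raise ValueError(f"unknown mode {mode!r}")


def het_fraction(reads: ReadPlacements, het: RegionSet) -> float:
    """Fraction of read placements falling inside heterochromatin regions."""
    n = len(reads)
    if n == 0:
        raise ValueError("no reads")
    mask = het.contains(
        reads.table["chrom"].to_numpy(), reads.table["pos5"].to_numpy()
    )
    return float(mask.sum()) / n


class HetComparison(NamedTuple):
    p_value: float
    method: str
    table: tuple


def compare_het_fractions(
    reads_a: ReadPlacements, reads_b: ReadPlacements, het: RegionSet
) -> HetComparison:
    """Two-sided test for a difference in heterochromatin read fraction.

    Uses the 2x2 table (in-het vs out-of-het counts by sample):
    chi-square with continuity correction, or Fisher's exact test when any
    cell is below 5.  The method used is reported alongside the p-value.
    """
    rows = []
    for reads in (reads_a, reads_b):
        n = len(reads)
        if n == 0:
            raise ValueError("empty sample")
        k = int(
            het.contains(
                reads.table["chrom"].to_numpy(),
                reads.table["pos5"].to_numpy(),
            ).sum()
        )
        rows.append((k, n - k))
    table = np.array(rows, dtype=np.int64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (zero margin)")
    if (table < 5).any():
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        method = "fisher_exact"
    else:
        p = float(stats.chi2_contingency(table, correction=True)[1])
        method = "chi2_yates"
    return HetComparison(
        p_value=min(p, 1.0), method=method, table=tuple(map(tuple, table))
    )


def te_dna_density(
    reads: ReadPlacements, tes: TEAnnotation, te_ids=None
) -> pd.Series:
    """Genomic DNA reads per kb of TE length per million mapping reads."""
    if te_ids is None:
        te_ids = tes.te_ids
    known = set(tes.te_ids)
    unknown = [t for t in te_ids if t not in known]
    if unknown:
        raise ValueError(f"unknown te_ids: {unknown[:5]}")
    m = reads.library_size_millions
    sub = tes.table.set_index("te_id").loc[list(te_ids)]
    chroms = reads.table["chrom"].to_numpy()
    pos = reads.table["pos5"].to_numpy()
    dens = []
    for te_id, row in sub.iterrows():
        sel = (chroms == row["chrom"]) & (pos >= row["start"]) & (pos < row["end"])
        length_kb = (row["end"] - row["start"]) / 1000.0
        dens.append(int(sel.sum()) / length_kb / m)
    return pd.Series(dens, index=list(te_ids), name="density")


def ranksum_compare(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when there are no ties; the fully tied case
    (both samples one constant) returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else "exact"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method)[1]
    )
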