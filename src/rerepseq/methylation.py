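"""Bisulfite methylation-level summaries and profiles.

The fundamental statistic is the pooled (coverage-weighted) methylation
level #C / (#C + #T), computed per sequence context (CG, CHG, CHH) over a
region, per chromosome bin, or in feature-anchored metaplot bins.  Zero
coverage yields a missing value (NaN), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import METHYLATION_CONTEXTS, MethylationCalls, RegionSet
from .signal import triangular_smooth


def _check_context(context: str) -> None:
    if context not in METHYLATION_CONTEXTS:
        raise ValueError(f"unknown context {context!r}")


def methylation_level(
    calls: MethylationCalls,
    context: str,
    region: tuple | None = None,
    per_site_mean: bool = False,
) -> float:
    """Pooled methylation level over a region (or everything).

    ``region`` is (chrom, start, end), 0-based half-open; ``None`` pools
    all records.  Both strands are pooled.  With ``per_site_mean`` the
    unweighted mean of per-site levels is returned instead of the pooled
    ratio of summed counts.  Returns NaN when total coverage is zero.
    """
    _check_context(context)
    t = calls.table
    sel = t["context"] == context
    if region is not None:
        chrom, start, end = region
        sel &= (t["chrom"] == chrom) & (t["pos"] >= start) & (t["pos"] < end)
    sub = t[sel]
    c = sub["count_c"].to_numpy(dtype=float)
    n = c + sub["count_t"].to_numpy(dtype=float)
    if per_site_mean:
        covered = n > 0
        if not covered.any():
            return float("nan")
        return float((c[covered] / n[covered]).mean())
    total = n.sum()
    if total == 0:
        return float("nan")
    return float(c.sum() / total)


def context_levels(calls: MethylationCalls, region=None) -> dict:
    """Pooled level for each of the three contexts."""
    return {
        ctx: methylation_level(calls, ctx, region=region)
        for ctx in METHYLATION_CONTEXTS
    }


@dataclass
class ChromosomeProfile:
    """Per-chromosome binned methylation levels; NaN marks no coverage."""

    context: str
    values: dict  # chrom -> np.ndarray of levels (NaN = missing)
    coverage: dict  # chrom -> np.ndarray of total read counts per bin
    bin_width: int


def _smooth_with_gaps(values: np.ndarray, n_iter: int) -> np.ndarray:
    """Triangular smoothing applied independently to contiguous
    non-missing runs."""
    out = values.copy()
    n = len(values)
    finite = np.isfinite(values)
    i = 0
    while i < n:
        if not finite[i]:
            i += 1
            continue
        j = i
        while j < n and finite[j]:
            j += 1
        out[i:j] = triangular_smooth(values[i:j], n_iter)
        i = j
    return out


def chromosome_profile(
    calls: MethylationCalls,
    chrom_sizes: dict,
    bin_bp: int,
    context: str,
    smooth_iters: int = 1,
) -> ChromosomeProfile:
    """Pooled methylation level in fixed bins along each chromosome."""
    _check_context(context)
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    t = calls.table[calls.table["context"] == context]
    values = {}
    coverage = {}
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_bp)
        sub = t[t["chrom"] == chrom]
        idx = sub["pos"].to_numpy() // bin_bp
        c = np.bincount(
            idx, weights=sub["count_c"].to_numpy(), minlength=n_bins
        )
        tot = c + np.bincount(
            idx, weights=sub["count_t"].to_numpy(), minlength=n_bins
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(tot > 0, c / np.maximum(tot, 1), np.nan)
        values[chrom] = _smooth_with_gaps(level, smooth_iters)
        coverage[chrom] = tot
    return ChromosomeProfile(
        context=context, values=values, coverage=coverage, bin_width=bin_bp
    )


@dataclass
class FeatureMetaplot:
    """Mean methylation over features aligned at TSS/TTS with flanks.

    Bins 0..n_flank-1 are the 5' flank, then n_body_bins scaled body bins,
    then the 3' flank.  Minus-strand features are reversed before
    aggregation so the 5' end is always on the left.
    """

    context: str
    level: np.ndarray  # mean per bin across features (NaN = never covered)
    n_features: int
    n_flank_bins: int
    n_body_bins: int
    flank_bp: int

    @property
    def tss_bin(self) -> int:
        return self.n_flank_bins

    @property
    def tts_bin(self) -> int:
        return self.n_flank_bins + self.n_body_bins


def feature_metaplot(
    calls: MethylationCalls,
    features: pd.DataFrame,
    context: str,
    flank_bp: int = 2000,
    n_flank_bins: int = 20,
    n_body_bins: int = 20,
    smooth_iters: int = 3,
) -> FeatureMetaplot:
    """Feature-anchored methylation metaplot.

    ``features`` needs columns chrom, start, end, strand.  Flank bins are
    fixed-width (``flank_bp / n_flank_bins`` bp); the body is length-scaled
    into ``n_body_bins`` fractional bins.  Per feature and bin the pooled
    level is computed; the profile is the mean over features with coverage
    in that bin, smoothed triangularly.
    """
    _check_context(context)
    if flank_bp % n_flank_bins:
        raise ValueError("flank_bp must be a multiple of n_flank_bins")
    fw = flank_bp // n_flank_bins
    n_total = 2 * n_flank_bins + n_body_bins
    t = calls.table[calls.table["context"] == context]
    sum_level = np.zeros(n_total)
    n_cov = np.zeros(n_total)
    n_features = 0
    for feat in features.itertuples(index=False):
        length = feat.end - feat.start
        if length <= 0:
            continue
        n_features += 1
        sub = t[
            (t["chrom"] == feat.chrom)
            & (t["pos"] >= feat.start - flank_bp)
            & (t["pos"] < feat.end + flank_bp)
        ]
        if not len(sub):
            continue
        pos = sub["pos"].to_numpy()
        if feat.strand == "-":
            rel = (feat.end - 1) - pos
        else:
            rel = pos - feat.start
        bins = np.empty(len(rel), dtype=np.int64)
        upstream = rel < 0
        body = (rel >= 0) & (rel < length)
        downstream = rel >= length
        bins[upstream] = (rel[upstream] + flank_bp) // fw
        bins[body] = n_flank_bins + (rel[body] * n_body_bins) // length
        bins[downstream] = (
            n_flank_bins + n_body_bins + (rel[downstream] - length) // fw
        )
        ok = (bins >= 0) & (bins < n_total)
        bins = bins[ok]
        c = np.bincount(
            bins, weights=sub["count_c"].to_numpy()[ok], minlength=n_total
        )
        tot = c + np.bincount(
            bins, weights=sub["count_t"].to_numpy()[ok], minlength=n_total
        )
        covered = tot > 0
        sum_level[covered] += c[covered] / tot[covered]
        n_cov[covered] += 1
    with np.errstate(invalid="ignore"):
        level = np.where(n_cov > 0, sum_level / np.maximum(n_cov, 1), np.nan)
    level = _smooth_with_gaps(level, smooth_iters)
    return FeatureMetaplot(
        context=context,
        level=level,
        n_features=n_features,
        n_flank_bins=n_flank_bins,
        n_body_bins=n_body_bins,
        flank_bp=flank_bp,
    )
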