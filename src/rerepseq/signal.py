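"""Binned-signal numerics: binning, smoothing, boundary metaplots.

These operators back both the copy-number tracks (re-replication caller)
and the methylation profiles, so they live in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ReadPlacements, RegionSet


@dataclass
class BinnedSignal:
    """Per-chromosome fixed-width bin values tiling from position 0.

    Bin ``i`` covers ``[i*bin_width, (i+1)*bin_width)``; the final bin may
    extend past the chromosome end.
    """

    values: dict  # chrom -> np.ndarray of float (or int for raw counts)
    bin_width: int
    semantics: str = "score"

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def map(self, fn, semantics: str | None = None) -> "BinnedSignal":
        return BinnedSignal(
            values={c: fn(v) for c, v in self.values.items()},
            bin_width=self.bin_width,
            semantics=semantics or self.semantics,
        )


@dataclass
class BoundaryProfile:
    """Mean signal around region boundaries, oriented into the region.

    Offset bin ``k`` covers ``[k*bin_width, (k+1)*bin_width)`` relative to
    the boundary; ``k < 0`` lies outside the region, ``k >= 0`` inside.
    Right boundaries are mirrored before aggregation so the orientation
    holds for both edges.
    """

    offsets: np.ndarray  # bin indices, contiguous
    mean: np.ndarray
    n_boundaries: int
    bin_width: int
    size_stratum: tuple = (0, float("inf"))

    @property
    def offsets_bp(self) -> np.ndarray:
        return self.offsets * self.bin_width


def bin_counts(
    reads: ReadPlacements, chrom_sizes: dict, bin_width: int
) -> BinnedSignal:
    """Count read 5' placements per fixed-width bin; conserves total reads."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = {}
    t = reads.table
    for chrom, size in chrom_sizes.items():
        n_bins = -(-size // bin_width)  # ceil division
        pos = t.loc[t["chrom"] == chrom, "pos5"].to_numpy()
        if (pos >= size).any():
            raise ValueError(f"placement beyond {chrom} length {size}")
        values[chrom] = np.bincount(pos // bin_width, minlength=n_bins).astype(
            np.int64
        )
    unknown = set(t["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"placements on chromosomes not in genome: {sorted(unknown)}")
    return BinnedSignal(values=values, bin_width=bin_width, semantics="count")


def moving_average(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Mean over a +/- ``halfwidth``-bin window, truncated at the edges."""
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n == 0 or halfwidth == 0:
        return v.copy()
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def triangular_smooth(values: np.ndarray, n_iter: int = 1) -> np.ndarray:
    """Iterated (0.25, 0.5, 0.25) convolution; endpoints copied unchanged."""
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    v = np.asarray(values, dtype=float).copy()
    if len(v) < 3:
        return v
    for _ in range(n_iter):
        out = v.copy()
        out[1:-1] = 0.25 * v[:-2] + 0.5 * v[1:-1] + 0.25 * v[2:]
        v = out
    return v


def _aggregate_bins(values: np.ndarray, factor: int) -> np.ndarray:
    """Mean-aggregate fine bins into coarse bins of ``factor`` fine bins."""
    n = len(values)
    n_coarse = -(-n // factor)
    padded = np.full(n_coarse * factor, np.nan)
    padded[:n] = values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(padded.reshape(n_coarse, factor), axis=1)


def boundary_metaplot(
    signal: BinnedSignal,
    regions: RegionSet,
    flank_bp: int,
    bin_width: int | None = None,
    size_strata=None,
    exclude_overlapping: bool = False,
) -> list:
    """Average a signal around region boundaries, oriented into the region.

    Both edges of every region contribute; right edges are mirrored so
    positive offsets always point into the region.  Boundaries are snapped
    to the fine-bin grid of ``signal``; each metaplot bin is the mean of
    the fine bins it covers.  ``size_strata`` is a list of
    ``(min_bp, max_bp)`` half-open size classes (default: one stratum
    covering everything; pass ``"quartiles"`` for quartiles of region
    size).  With ``exclude_overlapping`` a flank that intersects another
    region is dropped from the aggregation.
    """
    bin_width = bin_width or signal.bin_width
    if bin_width % signal.bin_width:
        raise ValueError("signal bin width must divide the metaplot bin width")
    factor = bin_width // signal.bin_width
    if flank_bp % bin_width:
        raise ValueError("flank_bp must be a multiple of bin_width")
    n_flank = flank_bp // bin_width

    t = regions.table
    sizes = (t["end"] - t["start"]).to_numpy()
    if size_strata is None:
        strata = [(0, float("inf"))]
    elif size_strata == "quartiles":
        qs = np.quantile(sizes, [0, 0.25, 0.5, 0.75, 1.0])
        strata = [
            (float(qs[i]), float(qs[i + 1]) + (1 if i == 3 else 0))
            for i in range(4)
        ]
    else:
        strata = list(size_strata)

    coarse = {
        c: (_aggregate_bins(v, factor) if factor > 1 else np.asarray(v, float))
        for c, v in signal.values.items()
    }
    merged = regions.merge()

    offsets = np.arange(-n_flank, n_flank)
    profiles = []
    for lo, hi in strata:
        total = np.zeros(len(offsets))
        count = np.zeros(len(offsets))
        n_boundaries = 0
        for row, size in zip(t.itertuples(index=False), sizes):
            if not (lo <= size < hi):
                continue
            if size < bin_width:
                warnings.warn(
                    f"region {row.chrom}:{row.start}-{row.end} shorter than "
                    "one bin; skipped"
                )
                continue
            v = coarse.get(row.chrom)
            if v is None:
                continue
            for boundary, direction in ((row.start, +1), (row.end, -1)):
                b = boundary // bin_width  # snap to the coarse grid
                if exclude_overlapping:
                    # outside flank: the flank_bp window beyond the boundary
                    if direction == 1:
                        out_iv = (max(boundary - flank_bp, 0), boundary)
                    else:
                        out_iv = (boundary, boundary + flank_bp)
                    if out_iv[1] > out_iv[0]:
                        from .core import RegionSet as _RS, intersection_bp

                        flank_set = _RS.from_tuples(
                            [(row.chrom, out_iv[0], out_iv[1])]
                        )
                        if intersection_bp(flank_set, merged) > 0:
                            continue
                if direction == 1:
                    bins = b + offsets
                else:
                    bins = b - 1 - offsets
                ok = (bins >= 0) & (bins < len(v))
                vals = v[bins[ok]]
                fin = np.isfinite(vals)
                total[ok] += np.where(fin, vals, 0.0)
                count[ok] += fin
                n_boundaries += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        profiles.append(
            BoundaryProfile(
                offsets=offsets.copy(),
                mean=mean,
                n_boundaries=n_boundaries,
                bin_width=bin_width,
                size_stratum=(lo, hi),
            )
        )
    return profiles


def profile_to_frame(profile: BoundaryProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset_bp": profile.offsets_bp,
            "mean": profile.mean,
            "n": profile.n_boundaries,
        }
    )
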