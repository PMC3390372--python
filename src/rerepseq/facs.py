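"""Flow-cytometry ploidy-peak quantitation.

Endoreduplicating nuclei produce fluorescence peaks at geometric spacing
(2C, 4C, 8C, 16C).  The re-replication index is the coefficient of
variation (CV) of the 8C peak: re-replicated heterochromatin broadens the
peak.  Peaks are detected on a smoothed histogram of log intensities,
where ploidy peaks have equal width and spacing, and each peak's CV is
measured on events gated in a symmetric multiplicative window.
"""

from __future__ import annotations

import numpy as np


def detect_peaks(intensities: np.ndarray, n_peaks: int) -> np.ndarray:
    """Locate ploidy peak centers, sorted ascending.

    A Freedman-Diaconis histogram of log intensities is smoothed with a
    3-bin moving average; the ``n_peaks`` highest local maxima are kept and
    each center is refined as the mean intensity of events within +/- 1.5
    bins of the peak (in log space).
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) == 0:
        raise ValueError("no events")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if (x <= 0).any():
        raise ValueError("intensities must be positive")
    lx = np.log(x)
    iqr = np.subtract(*np.percentile(lx, [75, 25]))
    if iqr == 0:
        if n_peaks > 1:
            raise PeakDetectionError(
                f"found 1 candidate peak, needed {n_peaks}",
                found=np.array([float(np.exp(lx[0]))]),
            )
        return np.array([float(np.exp(lx.mean()))])
    h = 2 * iqr / len(lx) ** (1 / 3)
    edges = np.arange(lx.min(), lx.max() + h, h)
    if len(edges) < 4:
        edges = np.linspace(lx.min(), lx.max(), 4)
    counts, edges = np.histogram(lx, bins=edges)
    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    # local maxima (plateaus resolved leftward)
    is_max = np.zeros(len(smooth), dtype=bool)
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(smooth) - 1 else -np.inf
        is_max[i] = smooth[i] > left and smooth[i] >= right and smooth[i] > 0
    cand = np.flatnonzero(is_max)
    if len(cand) < n_peaks:
        found = np.exp(centers[cand])
        raise PeakDetectionError(
            f"found {len(cand)} candidate peaks, needed {n_peaks}",
            found=np.sort(found),
        )
    top = cand[np.argsort(smooth[cand])[::-1][:n_peaks]]
    refined = []
    width = 1.5 * (edges[1] - edges[0])
    for i in np.sort(top):
        gate = np.abs(lx - centers[i]) <= width
        refined.append(float(x[gate].mean()) if gate.any() else float(np.exp(centers[i])))
    return np.sort(np.asarray(refined))


class PeakDetectionError(ValueError):
    def __init__(self, message: str, found: np.ndarray):
        super().__init__(message)
        self.found = found


def peak_cv(
    intensities: np.ndarray,
    center: float,
    gate_halfwidth_frac: float = 0.25,
    min_events: int = 50,
) -> float:
    """CV (percent) of events gated around a peak center.

    Gate: ``[center*(1-f), center*(1+f)]``.  Scale-invariant by
    construction; fewer than ``min_events`` gated events raises.
    """
    x = np.asarray(intensities, dtype=float)
    if center <= 0 or not 0 < gate_halfwidth_frac < 1:
        raise ValueError("invalid gate parameters")
    gate = x[
        (x >= center * (1 - gate_halfwidth_frac))
        & (x <= center * (1 + gate_halfwidth_frac))
    ]
    if len(gate) < min_events:
        raise ValueError(
            f"only {len(gate)} events in the gate (need >= {min_events})"
        )
    mean = gate.mean()
    sd = gate.std(ddof=1)
    return float(100.0 * sd / mean)


def normalize_cv(cv_sample: float, cv_wt: float) -> float:
    """CV relative to the wild-type CV."""
    if cv_wt <= 0:
        raise ValueError("wild-type CV must be positive")
    return cv_sample / cv_wt


def replicate_summary(cvs) -> tuple:
    """Mean and SD of per-replicate CVs (SD is NaN for a single replicate)."""
    v = np.asarray(list(cvs), dtype=float)
    if len(v) == 0:
        raise ValueError("no replicates")
    sd = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
    return float(v.mean()), sd
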