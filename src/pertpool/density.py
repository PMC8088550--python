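"""Kernel density estimation of the pooled opinion on the bounded 0-100 scale.

The pooled Monte-Carlo samples are visualised with a Gaussian KDE.  Because
the elicited quantities are probabilities, mass must not leak outside
[0, 100]; the estimator therefore bins the samples on a uniform grid and
smooths with a Gaussian kernel under reflecting boundaries at 0 and 100.
Binned smoothing keeps the cost linear in the grid size, which matters for
pools of ~10^6 draws.  The KDE is visualisation (and diagnostics) only — the
reported HDI always comes from the raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = ["DensityCurve", "estimate_kde", "count_modes"]

SCALE_LOW = 0.0
SCALE_HIGH = 100.0


@dataclass(frozen=True)
class DensityCurve:
    """Density evaluated on a uniform grid over [0, 100]; integrates to 1."""

    grid: np.ndarray
    density: np.ndarray
    kde_bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _scott_bandwidth(samples: np.ndarray) -> float:
    # Scott's plug-in rule for a Gaussian kernel in one dimension
    return float(np.std(samples, ddof=1) * samples.size ** (-1.0 / 5.0))


def estimate_kde(
    samples,
    grid_size: int = 512,
    kde_bandwidth: float | str = "auto",
) -> DensityCurve:
    """Gaussian KDE on a uniform [0, 100] grid with boundary reflection.

    ``kde_bandwidth="auto"`` applies Scott's rule to the sample spread.
    Raises when the samples are all identical (report a point mass instead).
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 or np.ptp(x) == 0.0:
        raise ValueError(
            "KDE needs at least 2 distinct samples; an all-identical pool "
            "is a point mass and should be reported as such"
        )
    if grid_size < 8:
        raise ValueError(f"grid_size must be >= 8, got {grid_size}")
    if kde_bandwidth == "auto":
        bw = _scott_bandwidth(x)
    else:
        bw = float(kde_bandwidth)
        if bw <= 0:
            raise ValueError(f"kde_bandwidth must be positive, got {kde_bandwidth}")

    grid = np.linspace(SCALE_LOW, SCALE_HIGH, grid_size)
    dx = (SCALE_HIGH - SCALE_LOW) / (grid_size - 1)
    edges = np.linspace(SCALE_LOW - dx / 2, SCALE_HIGH + dx / 2, grid_size + 1)
    counts, _ = np.histogram(np.clip(x, SCALE_LOW, SCALE_HIGH), bins=edges)
    # mode="reflect" mirrors mass at the 0 and 100 boundaries
    smooth = gaussian_filter1d(counts.astype(float), sigma=bw / dx, mode="reflect")
    density = smooth / np.trapezoid(smooth, grid)
    return DensityCurve(grid=grid, density=density, kde_bandwidth=bw)


def count_modes(curve: DensityCurve, prominence_frac: float = 0.05) -> int:
    """Number of local maxima with prominence above a fraction of the peak.

    Used to verify that disagreeing expert clusters show up as
    multimodality in the pooled density.
    """
    prominence = prominence_frac * float(curve.density.max())
    peaks, _ = find_peaks(curve.density, prominence=prominence)
    # an interior plateau or boundary mode: find_peaks misses peaks at the ends
    d = curve.density
    n = len(peaks)
    if d[0] > d[1] and d[0] - d[1:].min() > prominence:
        n += 1
    if d[-1] > d[-2] and d[-1] - d[:-1].min() > prominence:
        n += 1
    return n
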