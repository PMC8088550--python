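"""Highest-density intervals and the bandwidth-based consensus rule.

The 80% HDI is the narrowest contiguous interval containing 80% of the
pooled probability mass; its width ("bandwidth", upper minus lower bound) is
the consensus metric: a bandwidth of at most 50 percentage points counts as
relatively strong consensus among the experts, anything wider as relatively
weak.

The default estimator works on the raw pooled Monte-Carlo samples: sort,
slide a window of ceil(mass * m) consecutive order statistics, keep the
narrowest (leftmost on ties).  A density-threshold variant that may return a
union of intervals is provided as a diagnostic for multimodal pools only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HdiInterval",
    "hdi_from_samples",
    "hdi_bandwidth",
    "classify_consensus",
    "hdi_from_density",
    "DEFAULT_HDI_MASS",
    "DEFAULT_CONSENSUS_THRESHOLD",
    "STRONG",
    "WEAK",
]

DEFAULT_HDI_MASS = 0.80
DEFAULT_CONSENSUS_THRESHOLD = 50.0
STRONG = "strong"
WEAK = "weak"

MIN_SAMPLES = 10


@dataclass(frozen=True)
class HdiInterval:
    """A contiguous interval with target probability mass, in percent."""

    lower: float
    upper: float
    mass: float = DEFAULT_HDI_MASS

    def __post_init__(self) -> None:
        if not (0.0 < self.mass < 1.0):
            raise ValueError(f"mass must lie in (0, 1), got {self.mass}")
        if self.lower > self.upper:
            raise ValueError(f"lower={self.lower} exceeds upper={self.upper}")

    @property
    def bandwidth(self) -> float:
        return self.upper - self.lower

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def hdi_from_samples(samples, mass: float = DEFAULT_HDI_MASS) -> HdiInterval:
    """Narrowest contiguous interval covering ``mass`` of the samples.

    Sorts the m samples and scans all windows of w = ceil(mass * m)
    consecutive order statistics; returns the narrowest window, leftmost on
    ties.  Requires at least 10 samples.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    m = x.size
    if m < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples for an HDI, got {m}")
    w = math.ceil(mass * m)
    widths = x[w - 1 :] - x[: m - w + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: leftmost tie-break
    return HdiInterval(lower=float(x[i]), upper=float(x[i + w - 1]), mass=mass)


def hdi_bandwidth(h: HdiInterval) -> float:
    """Interval width: upper bound minus lower bound, in percentage points."""
    return h.bandwidth


def classify_consensus(
    bandwidth: float, threshold: float = DEFAULT_CONSENSUS_THRESHOLD
) -> str:
    """``strong`` iff bandwidth <= threshold (default 50), else ``weak``."""
    if bandwidth < 0:
        raise ValueError(f"bandwidth must be nonnegative, got {bandwidth}")
    return STRONG if bandwidth <= threshold else WEAK


def hdi_from_density(grid, density, mass: float = DEFAULT_HDI_MASS):
    """Diagnostic density-threshold HDI: may return a union of intervals.

    Cells are admitted in order of decreasing density until the accumulated
    mass reaches the target; contiguous admitted cells are merged.  Returns a
    list of (lower, upper) tuples.  Never feeds the reported summaries.
    """
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    if grid.shape != density.shape or grid.ndim != 1:
        raise ValueError("grid and density must be 1-D arrays of equal length")
    # trapezoid cell weights
    dx = np.gradient(grid)
    cell_mass = density * dx
    cell_mass = cell_mass / cell_mass.sum()
    order = np.argsort(density)[::-1]
    cum = np.cumsum(cell_mass[order])
    k = int(np.searchsorted(cum, mass)) + 1
    selected = np.zeros(grid.size, dtype=bool)
    selected[order[:k]] = True
    intervals = []
    start = None
    for i, s in enumerate(selected):
        if s and start is None:
            start = i
        elif not s and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))
    return intervals
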