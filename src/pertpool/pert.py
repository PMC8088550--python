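"""Beta-PERT representation of a single expert's three-point elicitation.

An expert answers an uncertain-likelihood question with three numbers on a
0-100% scale: the lowest plausible bound, the most likely value (mode), and
the highest plausible bound.  The PERT distribution turns that triplet into a
full probability density: a beta distribution rescaled to [low, high] with
shape parameters

    alpha = 1 + lam * (mode - low) / (high - low)
    beta  = 1 + lam * (high - mode) / (high - low)

where ``lam`` is the shape weight placed on the mode (canonically 4, giving
the classic mean (low + 4*mode + high) / 6).  A zero-width elicitation
(low == mode == high) is a legitimate answer — a certain expert — and is
represented as a point mass.

All quantities stay on the percent scale [0, 100] throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ElicitationError",
    "ThreePointElicitation",
    "PertDistribution",
    "fit_pert",
    "pert_mean",
    "pert_pdf",
    "pert_cdf",
    "sample_pert",
    "DEFAULT_SHAPE_LAMBDA",
]

DEFAULT_SHAPE_LAMBDA = 4.0

SCALE_LOW = 0.0
SCALE_HIGH = 100.0


class ElicitationError(ValueError):
    """Raised when a three-point elicitation violates its contract."""


@dataclass(frozen=True)
class ThreePointElicitation:
    """One expert's (low, mode, high) answer to one question, in percent.

    Invariant: 0 <= low <= mode <= high <= 100, all finite.
    """

    low: float
    mode: float
    high: float

    def __post_init__(self) -> None:
        for name in ("low", "mode", "high"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ElicitationError(f"{name} must be a finite number, got {v!r}")
            if not (SCALE_LOW <= v <= SCALE_HIGH):
                raise ElicitationError(
                    f"{name}={v} outside the percent scale [0, 100]"
                )
        if self.low > self.mode:
            raise ElicitationError(
                f"low={self.low} exceeds mode={self.mode} (low must be <= mode)"
            )
        if self.mode > self.high:
            raise ElicitationError(
                f"mode={self.mode} exceeds high={self.high} (mode must be <= high)"
            )

    @property
    def is_point(self) -> bool:
        return self.low == self.high


@dataclass(frozen=True)
class PertDistribution:
    """Fitted PERT density on [low, high]; a point mass when degenerate."""

    low: float
    high: float
    alpha: float
    beta_: float
    shape_lambda: float = DEFAULT_SHAPE_LAMBDA
    degenerate: bool = False

    @property
    def scale(self) -> float:
        return self.high - self.low

    def _frozen(self):
        if self.degenerate:
            raise ElicitationError(
                "degenerate (point-mass) distribution has no beta representation"
            )
        return stats.beta(self.alpha, self.beta_, loc=self.low, scale=self.scale)


def fit_pert(
    e: ThreePointElicitation, shape_lambda: float = DEFAULT_SHAPE_LAMBDA
) -> PertDistribution:
    """Fit the PERT (modified beta) density to a three-point elicitation.

    ``shape_lambda`` is the weight on the mode; 4 is the canonical choice.
    ``low == high`` yields a point mass with ``degenerate=True``.
    """
    if shape_lambda < 0:
        raise ElicitationError(f"shape_lambda must be >= 0, got {shape_lambda}")
    if e.is_point:
        return PertDistribution(
            low=e.low,
            high=e.high,
            alpha=np.nan,
            beta_=np.nan,
            shape_lambda=shape_lambda,
            degenerate=True,
        )
    width = e.high - e.low
    alpha = 1.0 + shape_lambda * (e.mode - e.low) / width
    beta_ = 1.0 + shape_lambda * (e.high - e.mode) / width
    return PertDistribution(
        low=e.low, high=e.high, alpha=alpha, beta_=beta_, shape_lambda=shape_lambda
    )


def pert_mean(d: PertDistribution) -> float:
    """Exact mean; for lambda=4 this equals (low + 4*mode + high) / 6."""
    if d.degenerate:
        return d.low
    # beta mean rescaled to [low, high]; identical to the classic PERT formula
    return d.low + d.scale * d.alpha / (d.alpha + d.beta_)


def pert_pdf(d: PertDistribution, x) -> np.ndarray | float:
    """Density per percent; zero outside [low, high].

    Raises for a degenerate distribution (no finite density exists).
    """
    frozen = d._frozen()
    x = np.asarray(x, dtype=float)
    out = np.where((x < d.low) | (x > d.high), 0.0, frozen.pdf(np.clip(x, d.low, d.high)))
    return out if out.ndim else float(out)


def pert_cdf(d: PertDistribution, x) -> np.ndarray | float:
    """Right-continuous CDF; a unit step at ``low`` when degenerate."""
    x = np.asarray(x, dtype=float)
    if d.degenerate:
        out = np.where(x >= d.low, 1.0, 0.0)
    else:
        out = d._frozen().cdf(np.clip(x, d.low, d.high))
    return out if out.ndim else float(out)


def sample_pert(d: PertDistribution, n: int, seed) -> np.ndarray:
    """Draw ``n`` values; reproducible for a fixed seed.

    ``seed`` may be anything :func:`numpy.random.default_rng` accepts,
    including an existing Generator.
    """
    if n < 1:
        raise ElicitationError(f"sample size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if d.degenerate:
        return np.full(n, d.low, dtype=float)
    draws = rng.beta(d.alpha, d.beta_, size=n)
    return d.low + d.scale * draws
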