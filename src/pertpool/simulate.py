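"""Synthetic expert panels with the statistical structure of elicitation data.

The generator emulates what a likelihood-elicitation survey produces:
15-18 experts per question, three-point answers on the bounded 0-100% scale,
asymmetric spreads, per-question skipping, and heterogeneous beliefs.
Beliefs follow a per-question Gaussian mixture: one cluster gives a unimodal
pooled opinion, two or more well-separated clusters give the multimodal
pools that signal disagreement.  The latent parameters are emitted alongside
the survey-format table so parameter recovery can be tested.

This is deliberately the simplest generator reproducing those features; it
makes no claim about expert psychology (no anchoring, no overconfidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SCHEMA, SurveyDataset
from .pool import DEFAULT_SEED

__all__ = ["QuestionSpec", "PanelConfig", "generate_panel"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuestionSpec:
    """Latent belief structure for one question: mixture of belief clusters."""

    scenario_id: str
    question_id: str
    question_label: str = ""
    centers: tuple[float, ...] = (50.0,)  # cluster means, percent
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.weights):
            raise ValueError("centers and weights must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"cluster weights must sum to 1, got {sum(self.weights)}")
        if any(w < 0 for w in self.weights):
            raise ValueError("cluster weights must be nonnegative")


@dataclass(frozen=True)
class PanelConfig:
    """Study-condition defaults: 18 invited experts, ~10% skipping.

    ``belief_sd`` is the between-expert spread within a cluster;
    ``spread_low`` / ``spread_high`` are the expected distances mode-low and
    high-mode (drawn with positive noise), reflecting that experts typically
    allow more room above than below their most likely value.
    """

    questions: tuple[QuestionSpec, ...]
    n_experts: int = 18
    belief_sd: float = 10.0
    spread_low: float = 10.0
    spread_high: float = 15.0
    skip_prob: float = 0.10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if not (0.0 <= self.skip_prob < 1.0):
            raise ValueError("skip_prob must lie in [0, 1)")
        if self.belief_sd < 0 or self.spread_low < 0 or self.spread_high < 0:
            raise ValueError("spreads and belief_sd must be nonnegative")
        if not self.questions:
            raise ValueError("at least one question is required")


def _positive_noise(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Positive draws with the given mean (gamma, shape 4); zero mean -> zeros."""
    if mean == 0.0:
        return np.zeros(n)
    return rng.gamma(shape=4.0, scale=mean / 4.0, size=n)


def _allocate_clusters(
    rng: np.random.Generator, weights: np.ndarray, n: int
) -> np.ndarray:
    """Assign experts to belief clusters in exact proportion to the weights.

    Largest-remainder allocation (remainders resolved at random), then a
    random permutation over experts.  Proportional rather than i.i.d.
    assignment guarantees the designed mixture shape — a 50/50 two-cluster
    question really splits a small panel in half, instead of occasionally
    collapsing to one dominant cluster by multinomial chance.
    """
    base = np.floor(weights * n).astype(int)
    short = n - base.sum()
    if short > 0:
        frac = weights * n - base
        p = frac / frac.sum() if frac.sum() > 0 else np.full(len(weights), 1 / len(weights))
        extra = rng.choice(len(weights), size=short, replace=True, p=p)
        np.add.at(base, extra, 1)
    k = np.repeat(np.arange(len(weights)), base)
    return rng.permutation(k)


def generate_panel(cfg: PanelConfig) -> tuple[SurveyDataset, pd.DataFrame]:
    """Generate a synthetic panel; returns (survey dataset, latent truth).

    For each expert x question: experts are split across belief clusters in
    proportion to the cluster weights, the latent belief
    theta ~ Normal(cluster mean, belief_sd); the mode is theta
    clipped to [0, 100], the bounds are the mode minus/plus positive noise
    around spread_low/spread_high, clipped and re-ordered.  Skips are
    Bernoulli(skip_prob).  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    expert_ids = [f"E{i + 1:02d}" for i in range(cfg.n_experts)]
    rows, latent_rows = [], []
    n_degenerate = 0
    n_elicited = 0

    for q in cfg.questions:
        k = _allocate_clusters(rng, np.asarray(q.weights), cfg.n_experts)
        theta = rng.normal(np.asarray(q.centers)[k], cfg.belief_sd)
        mode = np.clip(theta, 0.0, 100.0)
        low = np.clip(mode - _positive_noise(rng, cfg.spread_low, cfg.n_experts), 0.0, 100.0)
        high = np.clip(mode + _positive_noise(rng, cfg.spread_high, cfg.n_experts), 0.0, 100.0)
        low = np.minimum(low, mode)
        high = np.maximum(high, mode)
        skip = rng.random(cfg.n_experts) < cfg.skip_prob

        n_degenerate += int(np.sum((low == high) & ~skip))
        n_elicited += int(np.sum(~skip))
        for i, eid in enumerate(expert_ids):
            rows.append(
                {
                    "expert_id": eid,
                    "scenario_id": q.scenario_id,
                    "question_id": q.question_id,
                    "question_label": q.question_label,
                    "low": np.nan if skip[i] else low[i],
                    "mode": np.nan if skip[i] else mode[i],
                    "high": np.nan if skip[i] else high[i],
                }
            )
            latent_rows.append(
                {
                    "expert_id": eid,
                    "scenario_id": q.scenario_id,
                    "question_id": q.question_id,
                    "cluster": int(k[i]),
                    "cluster_center": q.centers[k[i]],
                    "theta": theta[i],
                    "skipped": bool(skip[i]),
                }
            )

    if n_elicited and n_degenerate / n_elicited > 0.5:
        log.warning(
            "boundary clipping degenerated %d/%d elicitations to point masses; "
            "clusters sit too close to the scale ends",
            n_degenerate,
            n_elicited,
        )
    records = pd.DataFrame(rows, columns=SCHEMA)
    latent = pd.DataFrame(latent_rows)
    return SurveyDataset(records=records, provenance="synthetic panel"), latent
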