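"""Per-question summaries and Table-style reports with density plots.

For every question, the responding experts' triplets are fitted, pooled
(50,000 draws each by default), and summarised as: number of responding
experts, pool mean, pool median, 80% highest-density interval, its
bandwidth, and the strong/weak consensus label.  Display values are rounded
half-up to one decimal; full precision is retained internally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .density import estimate_kde
from .hdi import (
    DEFAULT_CONSENSUS_THRESHOLD,
    DEFAULT_HDI_MASS,
    HdiInterval,
    classify_consensus,
    hdi_from_samples,
)
from .io import SurveyDataset
from .pool import (
    DEFAULT_SAMPLES_PER_EXPERT,
    DEFAULT_SEED,
    PooledOpinion,
    pool_opinions,
    pooled_mean,
    pooled_median,
)

__all__ = [
    "ReportConfig",
    "QuestionSummary",
    "summarize_question",
    "summarize_all",
    "build_report",
    "plot_question",
    "round1",
]

log = logging.getLogger(__name__)


def round1(x: float) -> float:
    """Round half-up to 1 decimal (display convention of the summary table)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReportConfig:
    """Pipeline settings, defaulting to the study's values."""

    samples_per_expert: int = DEFAULT_SAMPLES_PER_EXPERT
    hdi_mass: float = DEFAULT_HDI_MASS
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD
    kde_grid_size: int = 512
    kde_bandwidth: float | str = "auto"
    seed: int = DEFAULT_SEED

    @classmethod
    def from_mapping(cls, mapping) -> "ReportConfig":
        known = {k: v for k, v in dict(mapping).items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass(frozen=True)
class QuestionSummary:
    """One report row: n, mean, median, HDI, bandwidth, consensus label."""

    scenario_id: str
    question_id: str
    question_label: str
    n_experts: int
    mean: float
    median: float
    hdi: HdiInterval
    consensus: str
    is_overall: bool = False

    def as_row(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "question_id": self.question_id,
            "question_label": self.question_label,
            "overall": int(self.is_overall),
            "n_experts": self.n_experts,
            "mean": round1(self.mean),
            "median": round1(self.median),
            "hdi_lower": round1(self.hdi.lower),
            "hdi_upper": round1(self.hdi.upper),
            "bandwidth": round1(round1(self.hdi.upper) - round1(self.hdi.lower)),
            "consensus": self.consensus,
        }


def _is_overall(label: str) -> bool:
    return "overall" in str(label).lower()


def summarize_question(
    d: SurveyDataset,
    scenario_id: str,
    question_id: str,
    samples_per_expert: int = DEFAULT_SAMPLES_PER_EXPERT,
    seed: int = DEFAULT_SEED,
    hdi_mass: float = DEFAULT_HDI_MASS,
    consensus_threshold: float = DEFAULT_CONSENSUS_THRESHOLD,
) -> tuple[QuestionSummary, PooledOpinion]:
    """Pool one question's responders and summarise; returns (summary, pool)."""
    elicitations = d.elicitations_for(scenario_id, question_id)
    if not elicitations:
        raise ValueError(f"no responding experts for {scenario_id}/{question_id}")
    pool = pool_opinions(elicitations, samples_per_expert=samples_per_expert, seed=seed)
    hdi = hdi_from_samples(pool.samples, mass=hdi_mass)
    label_rows = d.questions
    sel = label_rows[
        (label_rows["scenario_id"].astype(str) == str(scenario_id))
        & (label_rows["question_id"].astype(str) == str(question_id))
    ]
    label = str(sel["question_label"].iloc[0]) if len(sel) else ""
    summary = QuestionSummary(
        scenario_id=str(scenario_id),
        question_id=str(question_id),
        question_label=label,
        n_experts=pool.n_experts,
        mean=pooled_mean(pool),
        median=pooled_median(pool),
        hdi=hdi,
        consensus=classify_consensus(hdi.bandwidth, threshold=consensus_threshold),
        is_overall=_is_overall(label),
    )
    return summary, pool


def summarize_all(d: SurveyDataset, config: ReportConfig = ReportConfig()):
    """Summarise every question, ordered by scenario then question.

    Questions with zero responders yield ``None`` in place of a summary (a
    "no data" marker) rather than aborting the run.
    """
    out = []
    for _, q in d.questions.sort_values(["scenario_id", "question_id"]).iterrows():
        sid, qid = q["scenario_id"], q["question_id"]
        if not d.elicitations_for(sid, qid):
            log.warning("no responding experts for %s/%s", sid, qid)
            out.append(((sid, qid), None, None))
            continue
        summary, pool = summarize_question(
            d,
            sid,
            qid,
            samples_per_expert=config.samples_per_expert,
            seed=config.seed,
            hdi_mass=config.hdi_mass,
            consensus_threshold=config.consensus_threshold,
        )
        out.append(((sid, qid), summary, pool))
    return out


def summaries_frame(results) -> pd.DataFrame:
    """Tabulate summarize_all output; no-data questions get a marker row."""
    rows = []
    for (sid, qid), summary, _ in results:
        if summary is None:
            rows.append(
                {
                    "scenario_id": sid,
                    "question_id": qid,
                    "question_label": "",
                    "overall": 0,
                    "n_experts": 0,
                    "mean": np.nan,
                    "median": np.nan,
                    "hdi_lower": np.nan,
                    "hdi_upper": np.nan,
                    "bandwidth": np.nan,
                    "consensus": "no data",
                }
            )
        else:
            rows.append(summary.as_row())
    return pd.DataFrame(rows)


def plot_question(
    pool: PooledOpinion,
    summary: QuestionSummary,
    path,
    config: ReportConfig = ReportConfig(),
) -> None:
    """Pooled density with the HDI shaded under the curve."""
    curve = estimate_kde(
        pool.samples, grid_size=config.kde_grid_size, kde_bandwidth=config.kde_bandwidth
    )
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(curve.grid, curve.density, color="black", lw=1.2)
    inside = (curve.grid >= summary.hdi.lower) & (curve.grid <= summary.hdi.upper)
    ax.fill_between(
        curve.grid[inside],
        curve.density[inside],
        color="#4a90d9",
        alpha=0.6,
        label=f"{summary.hdi.mass:.0%} HDI",
    )
    ax.axvline(summary.median, color="#b0413e", lw=1.0, ls="--", label="median")
    ax.set_xlim(0, 100)
    ax.set_xlabel("likelihood (%)")
    ax.set_ylabel("density")
    ax.set_title(
        f"{summary.scenario_id}/{summary.question_id} "
        f"(n={summary.n_experts}, {summary.consensus} consensus)",
        fontsize=9,
    )
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def build_report(
    d: SurveyDataset,
    out_dir,
    config: ReportConfig = ReportConfig(),
    plots: bool = False,
    plot_questions=None,
) -> pd.DataFrame:
    """Run the full per-question pipeline and write report files.

    Writes ``summaries.csv`` (machine-readable, deterministic for a fixed
    seed/config), ``summaries.md`` and ``run_log.json``; optionally one
    density plot per question (all, or the (scenario_id, question_id) pairs
    in ``plot_questions``).  Returns the summary frame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = summarize_all(d, config)
    frame = summaries_frame(results)

    csv_path = out_dir / "summaries.csv"
    frame.to_csv(csv_path, index=False, float_format="%.1f")
    (out_dir / "summaries.md").write_text(_markdown_table(frame))
    run_log = {
        "provenance": d.provenance,
        "software_version": __version__,
        "seed": config.seed,
        "samples_per_expert": config.samples_per_expert,
        "hdi_mass": config.hdi_mass,
        "consensus_threshold": config.consensus_threshold,
        "n_questions": int(len(frame)),
        "n_records_pooled": int(frame["n_experts"].sum()),
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")

    if plots or plot_questions:
        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        wanted = (
            None
            if plot_questions is None
            else {(str(s), str(q)) for s, q in plot_questions}
        )
        for (sid, qid), summary, pool in results:
            if summary is None:
                continue
            if wanted is not None and (str(sid), str(qid)) not in wanted:
                continue
            plot_question(pool, summary, fig_dir / f"{sid}_{qid}.png", config)
    return frame


def _markdown_table(frame: pd.DataFrame) -> str:
    cols = [
        "scenario_id",
        "question_id",
        "question_label",
        "n_experts",
        "mean",
        "median",
        "hdi_lower",
        "hdi_upper",
        "bandwidth",
        "consensus",
    ]
    header = "| " + " | ".join(cols) + " |"
    sep = "|" + "|".join(["---"] * len(cols)) + "|"
    lines = [header, sep]
    for _, row in frame.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            if isinstance(v, float) and not np.isnan(v):
                cells.append(f"{v:.1f}")
            elif isinstance(v, float):
                cells.append("—")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
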