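#!/usr/bin/env python
"""Plot the pooled opinion density for each overall-scenario question.

One panel per scenario: the kernel-density estimate of the pooled samples
with the 80% highest-density interval shaded and the pool median marked.
Split panels show up as bimodal curves with wide HDIs.  PNGs go to
results/report/figures/.  Run 01_simulate_panel.py first.
"""

from pathlib import Path

from pertpool import ReportConfig, build_report, read_survey

ROOT = Path(__file__).resolve().parent.parent
SURVEY = ROOT / "results" / "synthetic_survey.csv"


def main() -> None:
    ds = read_survey(SURVEY)
    overall = [
        (q.scenario_id, q.question_id)
        for _, q in ds.questions.iterrows()
        if "overall" in str(q.question_label).lower()
    ]
    build_report(
        ds, ROOT / "results" / "report", ReportConfig(seed=20210501),
        plots=True, plot_questions=overall,
    )
    fig_dir = ROOT / "results" / "report" / "figures"
    print(f"wrote {len(list(fig_dir.glob('*.png')))} density plots to {fig_dir}")


if __name__ == "__main__":
    main()
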