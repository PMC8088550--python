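#!/usr/bin/env python
"""Generate the synthetic nine-scenario expert panel used by the downstream steps.

Emulates a likelihood-elicitation survey: 18 invited experts, nine scenarios
each with an overall question and two sub-questions, ~10% skipping.  Some
questions have a single belief cluster (expected strong consensus), others a
split panel (expected multimodal pool, weak consensus).  Writes the
survey-format table and the latent truth to results/.
"""

from pathlib import Path

from pertpool import PanelConfig, QuestionSpec, generate_panel, write_survey

OUT = Path(__file__).resolve().parent.parent / "results"

# alternating panel structures: unimodal low/high-likelihood and split panels
QUESTIONS = []
for i, (center, split) in enumerate(
    [(65, False), (45, True), (25, False), (70, True), (40, True),
     (40, False), (30, True), (45, False), (25, False)],
    start=1,
):
    sid = f"S{i}"
    QUESTIONS += [
        QuestionSpec(sid, "Q1", f"Development of scenario {i}", centers=(min(center + 10, 95.0),)),
        QuestionSpec(sid, "Q2", f"Consequence of scenario {i}", centers=(center,)),
        QuestionSpec(
            sid, "Q3", f"Overall scenario {i} taking place within 5 years",
            centers=(center - 15.0, center + 25.0) if split else (float(center),),
            weights=(0.5, 0.5) if split else (1.0,),
        ),
    ]

CONFIG = PanelConfig(
    questions=tuple(QUESTIONS), n_experts=18, belief_sd=6.0,
    spread_low=10.0, spread_high=15.0, skip_prob=0.10, seed=20210501,
)


def main() -> None:
    ds, latent = generate_panel(CONFIG)
    OUT.mkdir(exist_ok=True)
    write_survey(ds, OUT / "synthetic_survey.csv")
    latent.to_csv(OUT / "synthetic_latent.csv", index=False)
    answered = ds.n_nonskipped
    print(f"wrote {OUT / 'synthetic_survey.csv'}: {len(ds.records)} expert x question "
          f"rows, {answered} answered ({answered / len(ds.records):.0%}), "
          f"{len(CONFIG.questions)} questions, {CONFIG.n_experts} experts")


if __name__ == "__main__":
    main()
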