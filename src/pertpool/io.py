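"""Reading and validating elicitation-survey exports.

The canonical schema is a long-format CSV with one row per expert x question:

    expert_id, scenario_id, question_id, question_label, low, mode, high

Empty low/mode/high cells mean the expert skipped that question (allowed:
questions outside an expert's expertise).  Experts who answered nothing are
dropped with a log entry.  A mapping file allows reading deposits whose
column names differ from this schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .pert import ElicitationError, ThreePointElicitation

__all__ = ["SCHEMA", "SurveyDataset", "read_survey", "write_survey"]

log = logging.getLogger(__name__)

SCHEMA = [
    "expert_id",
    "scenario_id",
    "question_id",
    "question_label",
    "low",
    "mode",
    "high",
]
_VALUE_COLS = ["low", "mode", "high"]
_KEY_COLS = ["expert_id", "scenario_id", "question_id"]


class SurveyFormatError(ValueError):
    """Raised for structurally invalid survey files."""


@dataclass(frozen=True)
class SurveyDataset:
    """Validated long-format elicitation table.

    Invariants: (expert_id, scenario_id, question_id) unique; every
    non-skipped row is a valid three-point elicitation.
    """

    records: pd.DataFrame = field(repr=False)
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in SCHEMA if c not in df.columns]
        if missing:
            raise SurveyFormatError(f"missing required columns: {missing}")
        dup = df.duplicated(subset=_KEY_COLS)
        if dup.any():
            keys = df.loc[dup, _KEY_COLS].iloc[0].tolist()
            raise SurveyFormatError(
                f"duplicate (expert, scenario, question) key: {keys}"
            )
        errors = []
        for idx, row in df[~self.skipped_mask(df)].iterrows():
            try:
                ThreePointElicitation(row["low"], row["mode"], row["high"])
            except ElicitationError as err:
                errors.append(
                    f"row {idx} (expert {row['expert_id']}, "
                    f"{row['scenario_id']}/{row['question_id']}): {err}"
                )
        if errors:
            raise SurveyFormatError(
                "invalid elicitations:\n  " + "\n  ".join(errors)
            )

    @staticmethod
    def skipped_mask(df: pd.DataFrame) -> pd.Series:
        partial = df[_VALUE_COLS].isna()
        some = partial.any(axis=1)
        all_ = partial.all(axis=1)
        bad = some & ~all_
        if bad.any():
            raise SurveyFormatError(
                f"rows {list(df.index[bad])} have partially missing values; a "
                "skip must leave low, mode and high all empty"
            )
        return all_

    @property
    def questions(self) -> pd.DataFrame:
        """Unique (scenario_id, question_id, question_label), input order."""
        return (
            self.records[["scenario_id", "question_id", "question_label"]]
            .drop_duplicates(subset=["scenario_id", "question_id"])
            .reset_index(drop=True)
        )

    @property
    def n_nonskipped(self) -> int:
        return int((~self.skipped_mask(self.records)).sum())

    def elicitations_for(
        self, scenario_id: str, question_id: str
    ) -> dict[str, ThreePointElicitation]:
        """Responding experts' triplets for one question, keyed by expert id."""
        df = self.records
        sel = df[
            (df["scenario_id"].astype(str) == str(scenario_id))
            & (df["question_id"].astype(str) == str(question_id))
        ]
        sel = sel[~self.skipped_mask(sel)]
        return {
            str(row["expert_id"]): ThreePointElicitation(
                row["low"], row["mode"], row["high"]
            )
            for _, row in sel.iterrows()
        }


def read_survey(
    path,
    column_map: Mapping[str, str] | None = None,
    provenance: str = "",
) -> SurveyDataset:
    """Read and validate a survey CSV.

    ``column_map`` renames source columns to the canonical schema
    (``{source_name: canonical_name}``), for reconciling external deposits
    whose headers differ.  Experts with every question blank are dropped
    with a log entry.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing required columns {missing}")
    df = df[SCHEMA].copy()
    for c in _VALUE_COLS:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as err:
            raise SurveyFormatError(f"{path}: non-numeric entry in {c!r}: {err}") from err

    empty = df.groupby("expert_id")[_VALUE_COLS].apply(lambda g: g.isna().all().all())
    dropped = list(empty.index[empty])
    if dropped:
        log.info("dropping expert(s) with no answered question: %s", dropped)
        df = df[~df["expert_id"].isin(dropped)].reset_index(drop=True)
    try:
        return SurveyDataset(records=df, provenance=provenance or str(path))
    except SurveyFormatError as err:
        raise SurveyFormatError(f"{path}: {err}") from err


def write_survey(ds: SurveyDataset, path) -> None:
    """Write the canonical-schema CSV (round-trips through read_survey)."""
    ds.records.to_csv(path, index=False)
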