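"""Domain types and delimited-text I/O for the medical-trust-game paradigm.

One trial is one row: a participant either chooses a treatment (doctor or
pharmacy) during the conditioning session, or is stimulated at the reference
intensity during the test session.  Stimulus forces are PINPRICK weights in
mN; ratings are magnitude estimates in percent of the 512 mN reference pain
(reference = 100, unbounded above).

Paradigm contingencies enforced by validation:

* conditioning + pharmacy  -> 256 mN (deterministic small relief)
* conditioning + doctor    -> 64 or 256 mN (probabilistic relief)
* conditioning never has choice ``control``
* test session             -> always 512 mN (reference intensity)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SESSIONS = ("conditioning", "test")
CHOICES = ("doctor", "pharmacy", "control")
WEIGHTS = (64, 256, 512)

COLUMNS = [
    "participant_id",
    "session",
    "trial_index",
    "choice",
    "stimulus_weight",
    "pain_rating",
    "cost",
]


class SchemaError(ValueError):
    """The file is missing required columns."""


class ValidationError(ValueError):
    """Rows violate the paradigm invariants; offending rows are listed."""


class ParseError(ValueError):
    """A cell could not be parsed as the declared type."""


@dataclass(frozen=True)
class TrialRecord:
    """A single observed or simulated trial."""

    participant_id: str
    session: str
    trial_index: int
    choice: str
    stimulus_weight: int
    pain_rating: float
    cost: float = 0.0

    def __post_init__(self) -> None:
        problems = _row_problems(
            self.session, self.trial_index, self.choice,
            self.stimulus_weight, self.pain_rating, self.cost,
        )
        if problems:
            raise ValidationError("; ".join(problems))


def _row_problems(session, trial_index, choice, weight, rating, cost) -> list[str]:
    out = []
    if session not in SESSIONS:
        out.append(f"unknown session {session!r}")
    if choice not in CHOICES:
        out.append(f"unknown choice {choice!r}")
    if weight not in WEIGHTS:
        out.append(f"stimulus_weight {weight!r} not in {WEIGHTS}")
    if not trial_index >= 1:
        out.append(f"trial_index {trial_index!r} < 1")
    if rating < 0:
        out.append(f"pain_rating {rating!r} < 0")
    if cost < 0:
        out.append(f"cost {cost!r} < 0")
    if out:
        return out
    if session == "conditioning":
        if choice == "control":
            out.append("conditioning trial with choice=control")
        elif choice == "pharmacy" and weight != 256:
            out.append(f"conditioning pharmacy trial at {weight} mN (must be 256)")
        elif choice == "doctor" and weight not in (64, 256):
            out.append(f"conditioning doctor trial at {weight} mN (must be 64 or 256)")
    elif session == "test" and weight != 512:
        out.append(f"test trial at {weight} mN (must be 512)")
    return out


@dataclass
class StudyDataset:
    """An ordered collection of trials spanning one or more participants.

    Backed by a pandas DataFrame with the fixed column schema in
    :data:`COLUMNS`; rows keep their insertion order.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        if len(self.df):
            self.df = self.df.astype(
                {
                    "participant_id": str,
                    "session": str,
                    "trial_index": int,
                    "choice": str,
                    "stimulus_weight": int,
                    "pain_rating": float,
                    "cost": float,
                }
            )

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[TrialRecord]) -> "StudyDataset":
        rows = [vars(r) for r in records]
        return cls(pd.DataFrame(rows, columns=COLUMNS))

    def to_records(self) -> list[TrialRecord]:
        return [TrialRecord(**row) for row in self.df.to_dict("records")]

    # -- basic properties --------------------------------------------------
    @property
    def participants(self) -> list[str]:
        return sorted(self.df["participant_id"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return self.df.equals(other.df)

    # -- validation --------------------------------------------------------
    def validate(self, require_both_sessions: bool = True) -> None:
        """Raise :class:`ValidationError` listing every offending row (0-based)."""
        problems: list[str] = []
        for i, row in enumerate(self.df.itertuples(index=False)):
            for p in _row_problems(
                row.session, row.trial_index, row.choice,
                row.stimulus_weight, row.pain_rating, row.cost,
            ):
                problems.append(f"row {i}: {p}")
        dup = self.df.duplicated(subset=["participant_id", "session", "trial_index"])
        for i in self.df.index[dup]:
            problems.append(f"row {i}: duplicate (participant, session, trial_index) key")
        if require_both_sessions and len(self.df):
            by = self.df.groupby("participant_id")["session"].agg(set)
            for pid, sessions in by.items():
                for s in SESSIONS:
                    if s not in sessions:
                        problems.append(f"participant {pid}: no {s} trials")
        if problems:
            raise ValidationError("\n".join(problems))


def read_trials(path: str | Path, delimiter: str = ",",
                require_both_sessions: bool = True) -> StudyDataset:
    """Read a trial-level CSV and validate it against the paradigm invariants."""
    try:
        df = pd.read_csv(path, delimiter=delimiter, dtype={"participant_id": str},
                         float_precision="round_trip")
    except ValueError as exc:  # pragma: no cover - pandas wraps odd inputs
        raise ParseError(str(exc)) from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in ("trial_index", "stimulus_weight", "pain_rating", "cost"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            raise ParseError(f"{path}: unparseable {col} in rows {bad or 'with missing values'}")
        df[col] = coerced
    ds = StudyDataset(df)
    ds.validate(require_both_sessions=require_both_sessions)
    return ds


def write_trials(dataset: StudyDataset, path: str | Path) -> None:
    """Write the dataset as UTF-8 CSV with the fixed field order.

    Output is byte-stable: the same dataset always serialises identically.
    """
    dataset.df.to_csv(path, index=False, columns=COLUMNS, encoding="utf-8")


def filter_trials(dataset: StudyDataset, session: str | None = None,
                  choice: str | None = None,
                  participant: str | None = None) -> StudyDataset:
    """Subset trials by any combination of predicates, preserving order."""
    mask = pd.Series(True, index=dataset.df.index)
    if session is not None:
        mask &= dataset.df["session"] == session
    if choice is not None:
        mask &= dataset.df["choice"] == choice
    if participant is not None:
        mask &= dataset.df["participant_id"] == participant
    return StudyDataset(dataset.df[mask].reset_index(drop=True))


def conditioning_arrays(dataset: StudyDataset, participant: str,
                        choice: str) -> tuple["pd.Series", "pd.Series"]:
    """(ratings, weights) of one participant's conditioning trials for one choice."""
    sub = filter_trials(dataset, session="conditioning", choice=choice,
                        participant=participant).df
    return sub["pain_rating"].to_numpy(), sub["stimulus_weight"].to_numpy()
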