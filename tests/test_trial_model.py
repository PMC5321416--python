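"""Round-trip I/O, paradigm-invariant validation, and filtering."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from painprior.trial_model import (COLUMNS, ParseError, SchemaError,
                                   StudyDataset, TrialRecord, ValidationError,
                                   filter_trials, read_trials, write_trials)


def _record(**kw):
    base = dict(participant_id="A", session="conditioning", trial_index=1,
                choice="doctor", stimulus_weight=64, pain_rating=10.0, cost=2.0)
    base.update(kw)
    return TrialRecord(**base)


# -- hypothesis strategy for valid datasets ---------------------------------

@st.composite
def valid_datasets(draw):
    records = []
    n_participants = draw(st.integers(1, 3))
    rating = st.floats(0.0, 150.0, allow_nan=False, width=32)
    for p in range(n_participants):
        pid = f"S{p}"
        n_cond = draw(st.integers(1, 5))
        for t in range(1, n_cond + 1):
            choice = draw(st.sampled_from(["doctor", "pharmacy"]))
            weight = draw(st.sampled_from([64, 256])) if choice == "doctor" else 256
            records.append(_record(participant_id=pid, trial_index=t,
                                   choice=choice, stimulus_weight=weight,
                                   pain_rating=float(draw(rating)),
                                   cost=2.0 if choice == "doctor" else 1.0))
        n_test = draw(st.integers(1, 4))
        for t in range(1, n_test + 1):
            choice = draw(st.sampled_from(["doctor", "pharmacy", "control"]))
            records.append(_record(participant_id=pid, session="test",
                                   trial_index=t, choice=choice,
                                   stimulus_weight=512,
                                   pain_rating=float(draw(rating)), cost=0.0))
    return StudyDataset.from_records(records)


@given(valid_datasets())
def test_write_read_round_trip_is_identity(tmp_path_factory, ds):
    path = tmp_path_factory.mktemp("io") / "trials.csv"
    write_trials(ds, path)
    again = read_trials(path)
    assert again == ds
    # byte stability: re-serialising the re-read dataset is identical
    path2 = path.with_suffix(".2.csv")
    write_trials(again, path2)
    assert path.read_bytes() == path2.read_bytes()


@given(valid_datasets())
def test_filter_partitions_sum_to_total(ds):
    parts = [len(filter_trials(ds, session=s)) for s in ("conditioning", "test")]
    assert sum(parts) == len(ds)
    choices = [len(filter_trials(ds, choice=c))
               for c in ("doctor", "pharmacy", "control")]
    assert sum(choices) == len(ds)


def test_filter_predicates_and_identity(tiny_study):
    sub = filter_trials(tiny_study, session="test", choice="doctor")
    assert set(sub.df["session"]) == {"test"}
    assert set(sub.df["choice"]) == {"doctor"}
    assert len(sub) == 2
    ident = filter_trials(tiny_study)
    assert ident == tiny_study


@pytest.mark.parametrize("kw,msg", [
    (dict(choice="pharmacy", stimulus_weight=512), "must be 256"),
    (dict(choice="control"), "choice=control"),
    (dict(session="test", stimulus_weight=64), "must be 512"),
    (dict(trial_index=0), "< 1"),
    (dict(pain_rating=-1.0), "< 0"),
])
def test_trial_record_rejects_paradigm_violations(kw, msg):
    with pytest.raises(ValidationError, match=msg):
        _record(**kw)


def test_read_reports_offending_rows(tmp_path, tiny_study):
    path = tmp_path / "bad.csv"
    df = tiny_study.df.copy()
    df.loc[2, "stimulus_weight"] = 512  # conditioning pharmacy trial at 512 mN
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="row 2"):
        read_trials(path)


def test_read_missing_column_is_schema_error(tmp_path, tiny_study):
    path = tmp_path / "bad.csv"
    tiny_study.df.drop(columns=["cost"]).to_csv(path, index=False)
    with pytest.raises(SchemaError, match="cost"):
        read_trials(path)


def test_read_unparseable_numeric_is_parse_error(tmp_path, tiny_study):
    path = tmp_path / "bad.csv"
    df = tiny_study.df.copy()
    df["pain_rating"] = df["pain_rating"].astype(object)
    df.loc[0, "pain_rating"] = "high"
    df.to_csv(path, index=False)
    with pytest.raises(ParseError, match="pain_rating"):
        read_trials(path)


def test_duplicate_keys_rejected(tiny_study):
    df = pd.concat([tiny_study.df, tiny_study.df.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValidationError, match="duplicate"):
        StudyDataset(df).validate()


def test_empty_dataset_writes_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_trials(StudyDataset(), path)
    assert path.read_text().strip() == ",".join(COLUMNS)
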