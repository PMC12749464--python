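"""Yearly partnership-state sequences from retrospective marriage histories.

Each person's marriage/dissolution events are expanded into a sequence of
36 yearly states covering ages 15–50 over the alphabet

    N = never/not married, M = married (first marriage), R = remarried,
    D = divorced, W = widowed.

The year of an event takes the *new* state: the year a marriage starts is
coded M (or R), the year it dissolves is coded D or W.  Interior gaps are
imputed by carrying the last observed state forward (LOCF), and every
sequence is checked against a legality matrix of plausible life-course
transitions (e.g. a married person cannot return to "not married" without
a recorded dissolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: state alphabet, in fixed index order
STATES = "NMRDW"
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
N_STATES = 5
AGE_MIN, AGE_MAX = 15, 50
SEQ_LEN = AGE_MAX - AGE_MIN + 1  # 36
MISSING = -1
MISSING_CHAR = "-"

END_REASONS = ("divorce", "widowhood", "ongoing")


@dataclass
class MarriageRecord:
    """One marriage spell: order 1 = first marriage; end_year None = ongoing."""

    person_id: str
    order: int
    start_year: int
    end_year: int | None = None
    end_reason: str | None = None  # divorce | widowhood | ongoing | None (unknown)

    def __post_init__(self) -> None:
        if self.end_year is not None and self.start_year > self.end_year:
            raise ValueError(
                f"{self.person_id}: marriage {self.order} starts {self.start_year} "
                f"after its end {self.end_year}"
            )


@dataclass
class PersonHistory:
    person_id: str
    birth_year: int | None
    gender: str | None = None
    records: list[MarriageRecord] = field(default_factory=list)

    def sorted_records(self) -> list[MarriageRecord]:
        return sorted(self.records, key=lambda r: (r.start_year, r.order))


def default_transition_rules() -> np.ndarray:
    """5x5 boolean legality matrix (from-state x to-state).

    N->D and N->W are illegal here; ``validate_sequence`` relaxes them when a
    marriage occurred earlier in the sequence.
    """
    legal = np.zeros((N_STATES, N_STATES), dtype=bool)
    np.fill_diagonal(legal, True)
    N, M, R, D, W = (STATE_INDEX[s] for s in "NMRDW")
    legal[N, M] = True
    legal[M, D] = legal[M, W] = True
    legal[R, D] = legal[R, W] = True
    legal[D, R] = True
    legal[W, R] = True
    return legal


TRANSITION_RULES = default_transition_rules()


@dataclass
class StateSequence:
    person_id: str
    states: np.ndarray          # int8[36], values 0..4
    imputed_mask: np.ndarray    # bool[36]

    def to_string(self) -> str:
        return "".join(STATES[s] for s in self.states)


@dataclass
class SequenceSet:
    """Row-aligned collection of full-length state sequences."""

    ids: list[str]
    states: np.ndarray            # int8[n, 36]
    imputed: np.ndarray | None = None  # bool[n, 36]

    def __len__(self) -> int:
        return self.states.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"a{a}" for a in range(AGE_MIN, AGE_MAX + 1)]
        chars = np.array(list(STATES))[self.states]
        df = pd.DataFrame(chars, columns=cols)
        df.insert(0, "person_id", self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SequenceSet":
        cols = [f"a{a}" for a in range(AGE_MIN, AGE_MAX + 1)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"sequence table lacks columns: {missing[:3]}...")
        states = encode(df[cols].to_numpy())
        if (states == MISSING).any():
            raise ValueError("sequence table contains missing states")
        return cls(ids=[str(i) for i in df["person_id"]], states=states)


def encode(chars: np.ndarray | Sequence[str]) -> np.ndarray:
    """Map state characters to integer codes; '-'/'' map to MISSING."""
    arr = np.asarray(chars)
    if arr.dtype.kind in "USO" and arr.ndim <= 2:
        flat = arr.ravel()
        out = np.empty(flat.shape, dtype=np.int8)
        for i, c in enumerate(flat):
            c = str(c)
            if c in STATE_INDEX:
                out[i] = STATE_INDEX[c]
            elif c in (MISSING_CHAR, "", "nan"):
                out[i] = MISSING
            else:
                raise ValueError(f"unknown state symbol {c!r}")
        return out.reshape(arr.shape)
    return arr.astype(np.int8)


def encode_str(s: str) -> np.ndarray:
    return encode(np.array(list(s)))


class InvalidPersonError(ValueError):
    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


def assign_states(history: PersonHistory) -> np.ndarray:
    """Expand one person's marriage records into a raw length-36 state vector.

    Returns int8[36] with MISSING (-1) where the state cannot be determined
    (a closed marriage whose end reason is unknown leaves the post-dissolution
    span undetermined until the next marriage starts).
    """
    if history.birth_year is None:
        raise InvalidPersonError("missing_birth_year", history.person_id)
    birth = int(history.birth_year)
    recs = history.sorted_records()
    for a, b in zip(recs, recs[1:]):
        if a.end_year is None or b.start_year < a.end_year:
            raise InvalidPersonError(
                "overlapping_records",
                f"{history.person_id}: marriages {a.order} and {b.order}",
            )

    raw = np.full(SEQ_LEN, STATE_INDEX["N"], dtype=np.int8)
    years = birth + AGE_MIN + np.arange(SEQ_LEN)
    horizon_end = years[-1]

    for k, rec in enumerate(recs):
        married_state = STATE_INDEX["M"] if rec.order == 1 else STATE_INDEX["R"]
        end = rec.end_year if rec.end_year is not None else horizon_end + 1
        in_marriage = (years >= rec.start_year) & (years < end)
        raw[in_marriage] = married_state
        if rec.end_year is None:
            continue
        next_start = recs[k + 1].start_year if k + 1 < len(recs) else horizon_end + 1
        after = (years >= rec.end_year) & (years < next_start)
        if rec.end_reason == "divorce":
            raw[after] = STATE_INDEX["D"]
        elif rec.end_reason == "widowhood":
            raw[after] = STATE_INDEX["W"]
        elif rec.end_reason in (None, "", "ongoing"):
            # closed marriage without a usable end reason: undetermined span
            raw[after] = MISSING
        else:
            raise ValueError(f"unknown end_reason {rec.end_reason!r}")
        # same-year dissolution and remarriage: later-ordered event wins
        if k + 1 < len(recs) and recs[k + 1].start_year == rec.end_year:
            pos = np.nonzero(years == rec.end_year)[0]
            if pos.size:
                raw[pos] = STATE_INDEX["R"]
    return raw


def impute_locf(raw: np.ndarray) -> StateSequence | tuple[np.ndarray, np.ndarray]:
    """Fill interior missing positions with the last observed state.

    Leading missing positions are never invented and the sequence is rejected;
    an all-missing vector is likewise rejected.
    Returns ``(states, imputed_mask)``.
    """
    raw = np.asarray(raw, dtype=np.int8)
    if (raw == MISSING).all():
        raise InvalidPersonError("all_missing")
    if raw[0] == MISSING:
        raise InvalidPersonError("leading_missing")
    states = raw.copy()
    mask = states == MISSING
    last = states[0]
    for i in range(len(states)):
        if states[i] == MISSING:
            states[i] = last
        else:
            last = states[i]
    return states, mask


def validate_sequence(
    states: np.ndarray, rules: np.ndarray | None = None
) -> list[tuple[int, str, str]]:
    """Return legality violations as (position, from_symbol, to_symbol).

    Position p is the index (age 15+p) of the *from* state.  N->D and N->W
    are tolerated only when an M or R state occurs earlier in the sequence.
    """
    if rules is None:
        rules = TRANSITION_RULES
    states = np.asarray(states)
    if ((states < 0) | (states >= N_STATES)).any():
        raise ValueError("sequence contains symbols outside the alphabet")
    N, M, R, D, W = (STATE_INDEX[s] for s in "NMRDW")
    violations: list[tuple[int, str, str]] = []
    ever_married = False
    for p in range(len(states) - 1):
        a, b = int(states[p]), int(states[p + 1])
        if a in (M, R):
            ever_married = True
        ok = rules[a, b]
        if not ok and a == N and b in (D, W) and ever_married:
            ok = True
        if not ok:
            violations.append((p, STATES[a], STATES[b]))
    return violations


def build_cohort(
    histories: Iterable[PersonHistory],
) -> tuple[SequenceSet, pd.DataFrame]:
    """assign_states -> impute_locf -> validate_sequence over a cohort.

    Persons that cannot yield a valid sequence are excluded and logged with a
    reason code (missing_birth_year, overlapping_records, all_missing,
    leading_missing, illegal_transition).
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    excluded: list[tuple[str, str]] = []
    for h in histories:
        try:
            raw = assign_states(h)
            states, mask = impute_locf(raw)
        except InvalidPersonError as e:
            excluded.append((h.person_id, e.reason))
            continue
        if validate_sequence(states):
            excluded.append((h.person_id, "illegal_transition"))
            continue
        ids.append(h.person_id)
        rows.append(states)
        masks.append(mask)
    seqs = SequenceSet(
        ids=ids,
        states=np.vstack(rows) if rows else np.empty((0, SEQ_LEN), dtype=np.int8),
        imputed=np.vstack(masks) if masks else np.empty((0, SEQ_LEN), dtype=bool),
    )
    log = pd.DataFrame(excluded, columns=["person_id", "reason"])
    return seqs, log


def cohort_from_raw(ids: Sequence[str], raw: np.ndarray) -> tuple[SequenceSet, pd.DataFrame]:
    """Cohort builder for raw state matrices (gaps coded MISSING / '-')."""
    raw = encode(raw)
    out_ids, rows, masks, excluded = [], [], [], []
    for pid, row in zip(ids, raw):
        try:
            states, mask = impute_locf(row)
        except InvalidPersonError as e:
            excluded.append((str(pid), e.reason))
            continue
        if validate_sequence(states):
            excluded.append((str(pid), "illegal_transition"))
            continue
        out_ids.append(str(pid))
        rows.append(states)
        masks.append(mask)
    seqs = SequenceSet(
        ids=out_ids,
        states=np.vstack(rows) if rows else np.empty((0, SEQ_LEN), dtype=np.int8),
        imputed=np.vstack(masks) if masks else np.empty((0, SEQ_LEN), dtype=bool),
    )
    return seqs, pd.DataFrame(excluded, columns=["person_id", "reason"])


def state_distribution(
    seqs: SequenceSet | np.ndarray, gender: Sequence[str] | None = None
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """5x36 table of state proportions by age; columns each sum to 1.

    With ``gender`` given (aligned to rows), returns one table per stratum.
    """
    states = seqs.states if isinstance(seqs, SequenceSet) else np.asarray(states_arr(seqs))
    if states.shape[0] == 0:
        raise ValueError("empty sequence set")
    if gender is not None:
        gender = np.asarray(gender)
        return {
            g: state_distribution(SequenceSet(ids=[], states=states[gender == g]))
            for g in pd.unique(gender)
        }
    counts = np.stack(
        [(states == s).sum(axis=0) for s in range(N_STATES)]
    ).astype(float)
    props = counts / states.shape[0]
    ages = list(range(AGE_MIN, AGE_MAX + 1))
    return pd.DataFrame(props, index=list(STATES), columns=ages)


def states_arr(x) -> np.ndarray:
    return x.states if isinstance(x, SequenceSet) else np.asarray(x, dtype=np.int8)


# ---------------------------------------------------------------------------
# file interfaces

def read_histories(persons_csv, marriages_csv) -> list[PersonHistory]:
    """Load PersonHistory records from the persons/marriages CSV pair."""
    persons = pd.read_csv(persons_csv, dtype={"person_id": str})
    marriages = pd.read_csv(marriages_csv, dtype={"person_id": str})
    return histories_from_frames(persons, marriages)


def histories_from_frames(
    persons: pd.DataFrame, marriages: pd.DataFrame
) -> list[PersonHistory]:
    by_person: dict[str, list[MarriageRecord]] = {}
    for row in marriages.itertuples(index=False):
        end_year = None if pd.isna(row.end_year) else int(row.end_year)
        reason = None if pd.isna(row.end_reason) else str(row.end_reason)
        by_person.setdefault(str(row.person_id), []).append(
            MarriageRecord(
                person_id=str(row.person_id),
                order=int(row.order),
                start_year=int(row.start_year),
                end_year=end_year,
                end_reason=reason,
            )
        )
    out = []
    for row in persons.itertuples(index=False):
        birth = None if pd.isna(row.birth_year) else int(row.birth_year)
        gender = getattr(row, "gender", None)
        out.append(
            PersonHistory(
                person_id=str(row.person_id),
                birth_year=birth,
                gender=None if gender is None or pd.isna(gender) else str(gender),
                records=by_person.get(str(row.person_id), []),
            )
        )
    return out


def write_sequences(seqs: SequenceSet, path) -> None:
    seqs.to_frame().to_csv(path, index=False)


def read_sequences(path) -> SequenceSet:
    return SequenceSet.from_frame(pd.read_csv(path, dtype={"person_id": str}))


def read_raw_sequences(path) -> tuple[list[str], np.ndarray]:
    """Wide CSV whose state cells may be '-' (missing)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [f"a{a}" for a in range(AGE_MIN, AGE_MAX + 1)]
    return [str(i) for i in df["person_id"]], encode(df[cols].to_numpy())
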