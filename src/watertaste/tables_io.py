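"""Participant-level records, 2x2 contingency tables, and their I/O.

The atomic analysis input is a 2x2 table from a two-arm randomized
discrimination test: each participant tastes a single water sample (tap
water or filtered water, assigned at random) and guesses which variety it
was.  The tap arm plays the role of the "positive" class, so sensitivity
is the probability of answering "tap" in the tap arm and specificity the
probability of answering "filtered" in the filtered arm.  That orientation
is fixed here, once, for the whole package.

Participant files are plain CSV, one row per interview, with a lower-case
label vocabulary.  Correctness of a guess is never stored: it is derivable
(``response == arm``), which makes inconsistent files unrepresentable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ARM_LABELS = ("tap", "filtered")
RESPONSE_LABELS = ("tap", "filtered")

#: The four baseline covariates, each with its ordered label set.
COVARIATES: Mapping[str, tuple[str, str]] = {
    "gender": ("male", "female"),
    "position": ("student", "faculty"),
    "dispenser_last_month": ("yes", "no"),
    "fountain_before": ("yes", "no"),
}

CSV_COLUMNS = (
    "participant_id",
    "gender",
    "position",
    "dispenser_last_month",
    "fountain_before",
    "arm",
    "response",
)


class SchemaError(ValueError):
    """A participant file does not match the documented column schema."""


class IntegrityError(ValueError):
    """A dataset-level invariant (e.g. unique participant ids) is violated."""


@dataclass(frozen=True)
class ParticipantRecord:
    """One interview: covariates, randomized arm, and the participant's guess."""

    participant_id: str
    gender: str
    position: str
    dispenser_last_month: str
    fountain_before: str
    arm: str
    response: str

    def __post_init__(self) -> None:
        for name, labels in COVARIATES.items():
            value = getattr(self, name)
            if value not in labels:
                raise ValueError(
                    f"invalid {name} label {value!r}; expected one of {labels}"
                )
        if self.arm not in ARM_LABELS:
            raise ValueError(f"invalid arm label {self.arm!r}; expected one of {ARM_LABELS}")
        if self.response not in RESPONSE_LABELS:
            raise ValueError(
                f"invalid response label {self.response!r}; expected one of {RESPONSE_LABELS}"
            )

    @property
    def correct(self) -> bool:
        """Whether the guess matched the served water variety (derived, never stored)."""
        return self.response == self.arm


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Arm-by-response counts with the tap arm as the positive class.

    ``a``: tap-arm participants replying "tap" (correct);
    ``b``: tap-arm participants replying "filtered";
    ``c``: filtered-arm participants replying "tap";
    ``d``: filtered-arm participants replying "filtered" (correct).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"cell {name} must be an integer, got {value!r}")
            if value < 0:
                raise ValueError(f"cell {name} must be non-negative, got {value}")

    @property
    def n1(self) -> int:
        """Tap-arm size."""
        return self.a + self.b

    @property
    def n2(self) -> int:
        """Filtered-arm size."""
        return self.c + self.d

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def __add__(self, other: "ContingencyTable2x2") -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d
        )


@dataclass
class StudyDataset:
    """An ordered collection of participant records with a provenance label."""

    records: list[ParticipantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise IntegrityError(f"duplicate participant_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)


def read_participants(path: str | Path) -> StudyDataset:
    """Read a participant CSV (one row per interview) into a :class:`StudyDataset`.

    Raises :class:`SchemaError` for a missing or unexpected column,
    :class:`ValueError` (with the offending row index) for an unknown
    category label, and :class:`IntegrityError` for duplicate ids.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in CSV_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s): {', '.join(extra)}")

    records: list[ParticipantRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        kwargs = {col: getattr(row, col) for col in CSV_COLUMNS}
        try:
            records.append(ParticipantRecord(**kwargs))
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return StudyDataset(records=records, provenance=str(path))


def write_participants(ds: StudyDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical CSV layout (row order preserved)."""
    frame = pd.DataFrame(
        [{col: getattr(r, col) for col in CSV_COLUMNS} for r in ds.records],
        columns=list(CSV_COLUMNS),
    )
    frame.to_csv(path, index=False)


def read_table_json(path: str | Path) -> ContingencyTable2x2:
    """Read an aggregated table from ``{"a":int,"b":int,"c":int,"d":int}`` JSON."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return ContingencyTable2x2(
            int(payload["a"]), int(payload["b"]), int(payload["c"]), int(payload["d"])
        )
    except KeyError as exc:
        raise SchemaError(f"aggregated-table JSON missing key {exc}") from exc


def write_table_json(t: ContingencyTable2x2, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"a": t.a, "b": t.b, "c": t.c, "d": t.d}, fh)
        fh.write("\n")


def aggregate(
    ds: StudyDataset, stratify_by: str | None = None
) -> dict[str, ContingencyTable2x2]:
    """Collapse a dataset into arm-by-response tables.

    Without stratification, returns a single table under the key ``"all"``.
    With ``stratify_by`` set to one of the four covariates, returns one
    table per category label (in the documented label order); the stratum
    tables sum cell-wise to the unstratified table.
    """
    if not ds.records:
        raise ValueError("cannot aggregate an empty dataset")

    def _count(records: Iterable[ParticipantRecord]) -> ContingencyTable2x2:
        a = b = c = d = 0
        for r in records:
            if r.arm == "tap":
                if r.response == "tap":
                    a += 1
                else:
                    b += 1
            else:
                if r.response == "tap":
                    c += 1
                else:
                    d += 1
        return ContingencyTable2x2(a, b, c, d)

    if stratify_by is None:
        return {"all": _count(ds.records)}
    if stratify_by not in COVARIATES:
        raise ValueError(
            f"unknown covariate {stratify_by!r}; expected one of {sorted(COVARIATES)}"
        )
    return {
        label: _count(r for r in ds.records if getattr(r, stratify_by) == label)
        for label in COVARIATES[stratify_by]
    }
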