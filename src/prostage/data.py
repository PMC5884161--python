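"""Patient records, staging labels, cohort CSV I/O and seeded splitting.

The prediction target is binary pathologic stage: organ-confined disease
(OCD, pT2 with no nodal spread) versus non-organ-confined disease (NOCD,
pT3+ or pN1).  NOCD is the positive class everywhere downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GLEASON_CATEGORIES",
    "CLINICAL_T_CATEGORIES",
    "PATH_T_CATEGORIES",
    "PATH_N_CATEGORIES",
    "Label",
    "PatientRecord",
    "CohortSplit",
    "LoadReport",
    "CategoryError",
    "derive_label",
    "read_cohort",
    "write_cohort",
    "split_cohort",
]

#: Biopsy Gleason categories; 7 is split into the prognostically distinct 3+4 / 4+3.
GLEASON_CATEGORIES: tuple[str, ...] = (
    "3", "4", "5", "6", "7(3+4)", "7(4+3)", "8", "9", "10",
)

#: Pre-treatment clinical tumor extent categories.
CLINICAL_T_CATEGORIES: tuple[str, ...] = (
    "T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b",
)

PATH_T_CATEGORIES: tuple[str, ...] = ("pT2a", "pT2b", "pT2c", "pT3a", "pT3b", "pT3c")
PATH_N_CATEGORIES: tuple[str, ...] = ("pN0", "pN1")


class CategoryError(ValueError):
    """A value falls outside its closed clinical category set."""


class Label(str, enum.Enum):
    """Binary pathologic stage; ``NOCD`` is the positive class."""

    OCD = "OCD"
    NOCD = "NOCD"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _match_category(value: object, categories: Sequence[str], what: str) -> str:
    """Match case-insensitively after trimming; ints are accepted for Gleason."""
    text = str(value).strip()
    lookup = {c.lower(): c for c in categories}
    # tolerate "7(3 + 4)" style spacing inside Gleason parentheses
    key = text.lower().replace(" ", "")
    folded = {c.lower().replace(" ", ""): c for c in categories}
    if text.lower() in lookup:
        return lookup[text.lower()]
    if key in folded:
        return folded[key]
    raise CategoryError(f"{what} value {value!r} not in {list(categories)}")


def derive_label(path_t: str, path_n: str) -> Label:
    """Map AJCC pathologic T and N stage to the binary OCD/NOCD label.

    NOCD (extraprostatic spread) iff pathologic T is pT3a/pT3b/pT3c or nodal
    stage is pN1; every pT2 sub-stage without nodal disease is OCD.
    """
    t = _match_category(path_t, PATH_T_CATEGORIES, "pathologic T")
    n = _match_category(path_n, PATH_N_CATEGORIES, "pathologic N")
    if t.startswith("pT3") or n == "pN1":
        return Label.NOCD
    return Label.OCD


@dataclass(frozen=True)
class PatientRecord:
    """One patient: the three predictors plus optional pathologic staging.

    Parameters
    ----------
    psa : float
        Initial serum PSA in ng/mL; must be positive.
    gleason : str
        Biopsy Gleason category, one of :data:`GLEASON_CATEGORIES`.
    clinical_t : str
        Clinical T stage, one of :data:`CLINICAL_T_CATEGORIES`.
    path_t, path_n : str, optional
        Post-surgical pathologic stage; when both are given the binary
        ``label`` is derived (or validated) against them.
    label : Label, optional
        OCD/NOCD outcome; required for training and evaluation.
    """

    psa: float
    gleason: str
    clinical_t: str
    path_t: str | None = None
    path_n: str | None = None
    label: Label | None = None
    record_id: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.psa) or self.psa <= 0:
            raise ValueError(f"psa must be positive and finite, got {self.psa!r}")
        object.__setattr__(
            self, "gleason", _match_category(self.gleason, GLEASON_CATEGORIES, "gleason")
        )
        object.__setattr__(
            self,
            "clinical_t",
            _match_category(self.clinical_t, CLINICAL_T_CATEGORIES, "clinical T"),
        )
        if self.path_t is not None:
            object.__setattr__(
                self, "path_t", _match_category(self.path_t, PATH_T_CATEGORIES, "pathologic T")
            )
        if self.path_n is not None:
            object.__setattr__(
                self, "path_n", _match_category(self.path_n, PATH_N_CATEGORIES, "pathologic N")
            )
        if self.label is not None and not isinstance(self.label, Label):
            object.__setattr__(self, "label", Label(_match_category(self.label, ("OCD", "NOCD"), "label").upper()))
        if self.path_t is not None:
            derived = derive_label(self.path_t, self.path_n or "pN0")
            if self.label is None:
                object.__setattr__(self, "label", derived)
            elif self.label != derived:
                raise ValueError(
                    f"label {self.label} inconsistent with pathologic stage "
                    f"({self.path_t}, {self.path_n or 'pN0'}) -> {derived}"
                )

    @property
    def is_labeled(self) -> bool:
        return self.label is not None


@dataclass(frozen=True)
class LoadReport:
    """Outcome of a cohort load: accepted count and per-row rejections."""

    n_loaded: int
    rejected: tuple[tuple[int, str], ...] = ()

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass(frozen=True)
class CohortSplit:
    """A seeded partition of a cohort into training and validation sets."""

    train: tuple[PatientRecord, ...]
    validation: tuple[PatientRecord, ...]
    seed: int
    fraction: float


_REQUIRED_COLUMNS = ("psa", "gleason", "clinical_t")
_OPTIONAL_COLUMNS = ("path_t", "path_n", "label", "id")


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[PatientRecord], LoadReport]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    The file must have a header row with at least ``psa``, ``gleason`` and
    ``clinical_t`` columns (names remappable via ``schema``, a mapping from
    canonical name to the column name in the file).  Rows that fail category
    or range validation are dropped and reported, not fatal.

    Returns
    -------
    (records, report)
        The accepted records and a :class:`LoadReport` counting rejects with
        per-row reasons (0-based data-row index).
    """
    schema = dict(schema or {})
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if frame.empty and frame.columns.empty:
        raise ValueError(f"cohort file {path} is empty")
    rename = {schema.get(name, name): name for name in _REQUIRED_COLUMNS + _OPTIONAL_COLUMNS}
    frame = frame.rename(columns={c: rename[c] for c in frame.columns if c in rename})
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required column(s): {missing}")
    if len(frame) == 0:
        raise ValueError(f"cohort file {path} has a header but no data rows")

    records: list[PatientRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row_d = dict(zip(frame.columns, row))

        def _opt(col: str) -> str | None:
            v = row_d.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                return None
            return str(v)

        try:
            psa = float(row_d["psa"])
            label = _opt("label")
            records.append(
                PatientRecord(
                    psa=psa,
                    gleason=str(row_d["gleason"]),
                    clinical_t=str(row_d["clinical_t"]),
                    path_t=_opt("path_t"),
                    path_n=_opt("path_n"),
                    label=Label(label.upper()) if label else None,
                    record_id=_opt("id"),
                )
            )
        except (ValueError, TypeError) as exc:
            rejected.append((i, str(exc)))
    return records, LoadReport(n_loaded=len(records), rejected=tuple(rejected))


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as the standard cohort CSV (UTF-8, comma-separated)."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.record_id if r.record_id is not None else "",
                "psa": repr(float(r.psa)),
                "gleason": r.gleason,
                "clinical_t": r.clinical_t,
                "path_t": r.path_t or "",
                "path_n": r.path_n or "",
                "label": r.label.value if r.label else "",
            }
        )
    pd.DataFrame(rows, columns=["id", "psa", "gleason", "clinical_t", "path_t", "path_n", "label"]).to_csv(
        path, index=False
    )


def split_cohort(
    cohort: Sequence[PatientRecord],
    fraction: float = 0.7,
    seed: int = 0,
) -> CohortSplit:
    """Split a cohort into train/validation by a seeded uniform permutation.

    The first ``round(fraction * n)`` records of the permutation form the
    training set.  The split is a partition (nothing lost or duplicated)
    and is deterministic for a fixed seed.  No stratification is applied.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n_train = int(round(fraction * len(cohort)))
    train = tuple(cohort[i] for i in order[:n_train])
    validation = tuple(cohort[i] for i in order[n_train:])
    return CohortSplit(train=train, validation=validation, seed=seed, fraction=fraction)


def labeled_only(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Records usable for training/evaluation (binary label present)."""
    return [r for r in records if r.is_labeled]
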