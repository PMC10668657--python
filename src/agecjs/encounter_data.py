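"""From raw encounter records to model-ready capture histories and covariates.

The field protocol assigns every captured vulture a calendar-year age code
(``1cy`` ... ``5cy+``, or ``unknown``). For analysis, captures are pooled
into six-month occasions, individuals whose age is unknown at every capture
are removed, and ages are re-assigned on a biological-cycle calendar in
which a bird's calendar-year age advances at the start of every second
semester (fledglings reach the site in summer/autumn). Age classes are
"juvenile" (1 year), "immature" (2-4 years) and "adult" (5 years or more).

Two covariate matrices drive the survival model:

* the age/residency matrix ``A`` (n x k-1) with categories
  1 = juvenile, 2 = newly-marked immature, 3 = resident immature,
  4 = newly-marked adult, 5 = resident adult; the newly-marked categories
  occur only on the interval starting at the first capture. Newly-marked
  juveniles are not split out: a resident-juvenile parameter would be
  non-estimable because juveniles age out of the class within a year.
* the trap-response matrix ``T`` (n x k-1) whose column ``t`` governs
  recapture at occasion ``t+1``: 1/2/3 if the bird was captured at
  occasion ``t`` as juvenile/immature/adult, 4 if it was not captured then.

Intervals are indexed by their starting occasion: column ``t`` (0-based) of
``A`` covers survival over occasions ``(t, t+1]``. Entries before an
individual's first capture are the explicit undefined marker ``-1``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .occasions import OccasionGrid

__all__ = [
    "AGE_CODES",
    "AGE_CLASS_NAMES",
    "JUVENILE",
    "IMMATURE",
    "ADULT",
    "UNDEFINED",
    "EncounterRecord",
    "CaptureHistory",
    "PoolingSummary",
    "age_class_of_years",
    "assign_age_trajectory",
    "pool_to_occasions",
    "build_age_covariate",
    "build_trap_covariate",
    "build_m_array",
    "read_encounters",
    "write_encounters",
    "write_capture_history",
    "read_capture_history",
    "write_covariate",
]

AGE_CODES = ("1cy", "2cy", "3cy", "4cy", "5cy+", "unknown")
_CODE_YEARS = {"1cy": 1, "2cy": 2, "3cy": 3, "4cy": 4, "5cy+": 5}

JUVENILE, IMMATURE, ADULT = 0, 1, 2
AGE_CLASS_NAMES = ("juvenile", "immature", "adult")

UNDEFINED = -1  # explicit marker for covariate cells before first capture


def age_class_of_years(years: int) -> int:
    """Collapse a calendar-cycle age in years to its analysis class."""
    if years < 1:
        raise ValueError(f"age in years must be >= 1, got {years}")
    if years == 1:
        return JUVENILE
    if years <= 4:
        return IMMATURE
    return ADULT


@dataclass(frozen=True)
class EncounterRecord:
    """One physical capture of one individual."""

    individual_id: str
    capture_date: _dt.date
    age_code: str

    def __post_init__(self) -> None:
        if self.age_code not in AGE_CODES:
            raise ValueError(
                f"unknown age code {self.age_code!r} for individual "
                f"{self.individual_id!r}; valid codes: {AGE_CODES}"
            )


@dataclass
class PoolingSummary:
    """Bookkeeping emitted by :func:`pool_to_occasions`."""

    n_records: int
    n_individuals_input: int
    n_retained: int
    n_unknown_age_dropped: int
    n_duplicate_records: int
    n_within_occasion_collapsed: int

    @property
    def unknown_age_fraction(self) -> float:
        if self.n_individuals_input == 0:
            return 0.0
        return self.n_unknown_age_dropped / self.n_individuals_input


@dataclass
class CaptureHistory:
    """Binary detection matrix with first captures and ages at first capture.

    Attributes
    ----------
    ids : array of individual identifiers (one per row)
    y : (n, k) uint8 detection matrix
    f : (n,) 0-based first-capture occasion indices
    age_at_first : (n,) calendar-cycle age in years at first capture
        (5 stands for "5 or more")
    grid : the occasion grid the history is pooled on
    """

    ids: np.ndarray
    y: np.ndarray
    f: np.ndarray
    age_at_first: np.ndarray
    grid: OccasionGrid

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.uint8)
        self.f = np.asarray(self.f, dtype=np.int64)
        self.age_at_first = np.asarray(self.age_at_first, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        n, k = self.y.shape
        if k != self.grid.k:
            raise ValueError(f"y has {k} columns but the grid has {self.grid.k}")
        if not (len(self.f) == len(self.ids) == len(self.age_at_first) == n):
            raise ValueError("row-aligned fields have inconsistent lengths")
        rows = np.arange(n)
        if n and not np.all(self.y[rows, self.f] == 1):
            raise ValueError("every individual must be detected at its first capture")
        for i in range(n):
            if self.y[i, : self.f[i]].any():
                raise ValueError(f"detections before first capture for row {i}")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.y.shape[1]

    @property
    def age_class_at_first(self) -> np.ndarray:
        return np.array([age_class_of_years(a) for a in self.age_at_first])

    def age_classes(self) -> np.ndarray:
        """(n, k) matrix of age classes per occasion; UNDEFINED before f."""
        out = np.full((self.n, self.k), UNDEFINED, dtype=np.int64)
        for i in range(self.n):
            out[i] = assign_age_trajectory(self.age_at_first[i], self.f[i], self.grid)
        return out

    @property
    def last(self) -> np.ndarray:
        """0-based occasion of the last detection per individual."""
        return self.k - 1 - np.argmax(self.y[:, ::-1], axis=1)


def assign_age_trajectory(age_years_at_first: int, first_occasion: int, grid: OccasionGrid) -> np.ndarray:
    """Deterministic per-occasion age-class sequence for one individual.

    The calendar-cycle age advances at every second-semester occasion after
    the first capture; classes are therefore non-decreasing in the order
    juvenile < immature < adult. Occasions before the first capture carry
    the UNDEFINED marker.
    """
    if age_years_at_first < 1:
        raise ValueError("age at first capture must be >= 1 year")
    out = np.full(grid.k, UNDEFINED, dtype=np.int64)
    years = age_years_at_first
    for t in range(first_occasion, grid.k):
        if t > first_occasion and grid.is_second_semester(t):
            years += 1
        out[t] = age_class_of_years(years)
    return out


# ---------------------------------------------------------------------------
# Pooling raw encounters
# ---------------------------------------------------------------------------


def _age_years_at_first(occs: list[int], codes: list[str], first: int, grid: OccasionGrid) -> int | None:
    """Back/forward-propagate the earliest known age code to the first occasion.

    Returns None when every capture of the individual has an unknown code.
    The calendar-cycle age increases by one at every second-semester
    occasion, so the age at the first occasion is the known age minus the
    number of S2 occasions strictly after ``first`` up to the known
    occasion. ``5cy+`` codes are treated as exactly five years, a lower
    bound, when propagated backwards. The result is floored at one year.
    """
    known = [(t, c) for t, c in zip(occs, codes) if c != "unknown"]
    if not known:
        return None
    t_known, code = min(known)
    years = _CODE_YEARS[code]
    n_s2 = sum(1 for t in range(first + 1, t_known + 1) if grid.is_second_semester(t))
    return max(1, years - n_s2)


def pool_to_occasions(records, grid: OccasionGrid) -> tuple[CaptureHistory, PoolingSummary]:
    """Pool raw encounter records into a six-month capture history.

    Multiple captures of an individual within one semester collapse to a
    single detection. Individuals whose every record carries an unknown age
    code are dropped (and counted); when any capture has a valid code, the
    age is propagated deterministically to the first capture occasion.

    Parameters
    ----------
    records
        Iterable of :class:`EncounterRecord`, or a DataFrame with columns
        ``individual_id``, ``capture_date`` (ISO-8601), ``age_code``.
    """
    if isinstance(records, pd.DataFrame):
        records = frame_to_records(records)
    records = list(records)
    if not records:
        raise ValueError("no encounter records supplied")

    seen_pairs: set[tuple[str, _dt.date]] = set()
    n_dup = 0
    per_ind: dict[str, dict[int, list[str]]] = {}
    n_within = 0
    for rec in records:
        occ = grid.occasion_of_date(rec.capture_date)  # raises for out-of-span dates
        key = (rec.individual_id, rec.capture_date)
        if key in seen_pairs:
            n_dup += 1
            continue
        seen_pairs.add(key)
        bucket = per_ind.setdefault(rec.individual_id, {})
        if occ in bucket:
            n_within += 1
        bucket.setdefault(occ, []).append(rec.age_code)

    ids, f, ages = [], [], []
    rows = []
    n_unknown = 0
    for ind in sorted(per_ind, key=lambda s: (min(per_ind[s]), s)):
        occ_codes = per_ind[ind]
        occs = sorted(occ_codes)
        flat_occs = [t for t in occs for _ in occ_codes[t]]
        flat_codes = [c for t in occs for c in occ_codes[t]]
        first = occs[0]
        age0 = _age_years_at_first(flat_occs, flat_codes, first, grid)
        if age0 is None:
            n_unknown += 1
            continue
        row = np.zeros(grid.k, dtype=np.uint8)
        row[occs] = 1
        ids.append(ind)
        f.append(first)
        ages.append(age0)
        rows.append(row)

    if not rows:
        raise ValueError("all individuals had unknown ages; nothing to analyse")
    history = CaptureHistory(
        ids=np.array(ids, dtype=object),
        y=np.vstack(rows),
        f=np.array(f),
        age_at_first=np.array(ages),
        grid=grid,
    )
    summary = PoolingSummary(
        n_records=len(records),
        n_individuals_input=len(per_ind),
        n_retained=history.n,
        n_unknown_age_dropped=n_unknown,
        n_duplicate_records=n_dup,
        n_within_occasion_collapsed=n_within,
    )
    return history, summary


# ---------------------------------------------------------------------------
# Covariate matrices
# ---------------------------------------------------------------------------

_NEWLY_MARKED = {IMMATURE: 2, ADULT: 4}
_RESIDENT = {JUVENILE: 1, IMMATURE: 3, ADULT: 5}


def build_age_covariate(history: CaptureHistory) -> np.ndarray:
    """Age/residency covariate ``A`` (n, k-1) over categories 1..5.

    Column ``t`` governs survival over the interval starting at occasion
    ``t``. The newly-marked categories (2 immature, 4 adult) apply only on
    the interval starting at the first capture; juveniles are never split
    into newly-marked/resident. Cells before the first capture are -1.
    """
    classes = history.age_classes()
    n, k = history.n, history.k
    A = np.full((n, k - 1), UNDEFINED, dtype=np.int64)
    for i in range(n):
        fi = history.f[i]
        for t in range(fi, k - 1):
            cls = classes[i, t]
            if t == fi and cls != JUVENILE:
                A[i, t] = _NEWLY_MARKED[cls]
            else:
                A[i, t] = _RESIDENT[cls]
    return A


def build_trap_covariate(history: CaptureHistory) -> np.ndarray:
    """Immediate trap-response covariate ``T`` (n, k-1) over categories 1..4.

    Column ``t`` governs recapture at occasion ``t+1``: 1/2/3 when the
    individual was captured at occasion ``t`` as juvenile/immature/adult
    (its class *at that previous occasion*), 4 when it was not captured at
    occasion ``t``. Cells before the first capture are -1.
    """
    classes = history.age_classes()
    n, k = history.n, history.k
    T = np.full((n, k - 1), UNDEFINED, dtype=np.int64)
    for i in range(n):
        fi = history.f[i]
        for t in range(fi, k - 1):
            if history.y[i, t]:
                T[i, t] = classes[i, t] + 1
            else:
                T[i, t] = 4
    return T


# ---------------------------------------------------------------------------
# m-array
# ---------------------------------------------------------------------------


def build_m_array(history: CaptureHistory) -> pd.DataFrame:
    """Release/next-re-encounter table.

    Row ``t`` (1-based occasion label) counts the individuals captured and
    released at occasion ``t`` by the occasion of their *next* re-encounter
    (or never). Row sums over the next-encounter columns plus the ``never``
    column equal the releases.
    """
    k = history.k
    m = np.zeros((k - 1, k - 1), dtype=np.int64)  # m[t, j]: released t, next seen j+1
    never = np.zeros(k - 1, dtype=np.int64)
    released = np.zeros(k - 1, dtype=np.int64)
    for i in range(history.n):
        dets = np.flatnonzero(history.y[i])
        for a, b in zip(dets, dets[1:]):
            released[a] += 1
            m[a, b - 1] += 1
        last = dets[-1]
        if last < k - 1:
            released[last] += 1
            never[last] += 1
    df = pd.DataFrame(
        m,
        index=pd.Index(range(1, k), name="release_occasion"),
        columns=[f"next_{j}" for j in range(2, k + 1)],
    )
    df["never"] = never
    df["released"] = released
    return df


# ---------------------------------------------------------------------------
# File formats (plain CSV)
# ---------------------------------------------------------------------------


def read_encounters(path: str | Path) -> list[EncounterRecord]:
    """Read an encounter CSV (individual_id, capture_date ISO-8601, age_code)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "age_code": str})
    missing = {"individual_id", "capture_date", "age_code"} - set(df.columns)
    if missing:
        raise ValueError(f"encounter file {path} lacks required columns: {sorted(missing)}")
    return frame_to_records(df)


def frame_to_records(df: pd.DataFrame) -> list[EncounterRecord]:
    dates = pd.to_datetime(df["capture_date"], format="ISO8601").dt.date
    return [
        EncounterRecord(str(i), d, str(c))
        for i, d, c in zip(df["individual_id"], dates, df["age_code"])
    ]


def write_encounters(records: list[EncounterRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "capture_date": [r.capture_date.isoformat() for r in records],
            "age_code": [r.age_code for r in records],
        }
    ).to_csv(path, index=False)


def write_capture_history(history: CaptureHistory, path: str | Path) -> None:
    """Matrix CSV: id, 1-based first occasion, age at first capture, y_1..y_k."""
    df = pd.DataFrame(history.y, columns=[f"y_{t}" for t in range(1, history.k + 1)])
    df.insert(0, "age_at_first", history.age_at_first)
    df.insert(0, "f", history.f + 1)
    df.insert(0, "id", history.ids)
    df.to_csv(path, index=False)


def read_capture_history(path: str | Path, grid: OccasionGrid) -> CaptureHistory:
    df = pd.read_csv(path, dtype={"id": str})
    ycols = [f"y_{t}" for t in range(1, grid.k + 1)]
    missing = {"id", "f", "age_at_first", *ycols} - set(df.columns)
    if missing:
        raise ValueError(f"capture-history file {path} lacks columns: {sorted(missing)}")
    return CaptureHistory(
        ids=df["id"].to_numpy(dtype=object),
        y=df[ycols].to_numpy(dtype=np.uint8),
        f=df["f"].to_numpy(dtype=np.int64) - 1,
        age_at_first=df["age_at_first"].to_numpy(dtype=np.int64),
        grid=grid,
    )


def write_covariate(matrix: np.ndarray, ids: np.ndarray, path: str | Path, prefix: str) -> None:
    """Write a covariate matrix CSV with the same row order as the history."""
    df = pd.DataFrame(matrix, columns=[f"{prefix}_{t}" for t in range(1, matrix.shape[1] + 1)])
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)
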