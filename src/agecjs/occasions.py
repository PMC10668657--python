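"""Six-month capture occasions and study-period structure.

Capture effort at the study site is year-round, but encounters are pooled
into calendar semesters (S1 = January-June, S2 = July-December) because
pooling improves the precision of survival estimates for slow-living
species. Occasions are further grouped into contiguous "periods" that
encode the food-availability regime at the site (before the waste
treatment centre opened; first after-period of substantial organic-matter
reduction; second after-period of extreme reduction).

All occasion indices in this package are 0-based internally; file formats
and printed reports use 1-based occasion numbers and ``YYYYS[12]`` labels.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

__all__ = ["OccasionGrid", "default_grid", "semester_of_month"]


def semester_of_month(month: int) -> int:
    """Map a calendar month to its semester (1 for Jan-Jun, 2 for Jul-Dec)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return 1 if month <= 6 else 2


@dataclass(frozen=True)
class OccasionGrid:
    """Ordered grid of consecutive six-month capture occasions.

    Parameters
    ----------
    occasions
        Tuple of ``(year, semester)`` pairs, consecutive with no gaps.
    period_starts
        ``(year, semester)`` of the first occasion of each period after
        the first; must be occasions on the grid, strictly increasing.
        An empty tuple puts every occasion in period 1.
    """

    occasions: tuple[tuple[int, int], ...]
    period_starts: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.occasions) < 2:
            raise ValueError("a grid needs at least two occasions")
        for (y0, s0), (y1, s1) in zip(self.occasions, self.occasions[1:]):
            expected = (y0, 2) if s0 == 1 else (y0 + 1, 1)
            if (y1, s1) != expected:
                raise ValueError(
                    f"occasions must be consecutive semesters; got {(y0, s0)} "
                    f"followed by {(y1, s1)}"
                )
        idx = [self.index_of(*ps) for ps in self.period_starts]
        if any(b >= a for a, b in zip(idx, [-1] + idx[:-1])):
            raise ValueError("period_starts must be strictly increasing")
        if any(i == 0 for i in idx):
            raise ValueError("the first occasion already starts period 1")

    # -- basic geometry -------------------------------------------------

    @property
    def k(self) -> int:
        """Number of capture occasions."""
        return len(self.occasions)

    @property
    def n_periods(self) -> int:
        return len(self.period_starts) + 1

    def index_of(self, year: int, semester: int) -> int:
        """0-based occasion index of ``(year, semester)``."""
        try:
            return self.occasions.index((year, semester))
        except ValueError:
            raise ValueError(f"({year}, S{semester}) is not on the grid") from None

    def period_of(self, t: int) -> int:
        """1-based period of the 0-based occasion index ``t``."""
        if not 0 <= t < self.k:
            raise ValueError(f"occasion index out of range: {t}")
        w = 1
        for ps in self.period_starts:
            if t >= self.index_of(*ps):
                w += 1
        return w

    def periods(self):
        """Array-like of the 1-based period of every occasion."""
        return [self.period_of(t) for t in range(self.k)]

    # -- calendar dates -------------------------------------------------

    def occasion_of_date(self, date: _dt.date) -> int:
        """0-based occasion index containing ``date``.

        Raises ``ValueError`` if the date falls outside the grid span.
        """
        key = (date.year, semester_of_month(date.month))
        try:
            return self.occasions.index(key)
        except ValueError:
            raise ValueError(
                f"date {date.isoformat()} falls outside the study window "
                f"{self.label(0)}..{self.label(self.k - 1)}"
            ) from None

    def is_second_semester(self, t: int) -> bool:
        return self.occasions[t][1] == 2

    def label(self, t: int) -> str:
        y, s = self.occasions[t]
        return f"{y}S{s}"

    def labels(self) -> list[str]:
        return [self.label(t) for t in range(self.k)]


def _span(start_year: int, start_semester: int, k: int) -> tuple[tuple[int, int], ...]:
    out = []
    y, s = start_year, start_semester
    for _ in range(k):
        out.append((y, s))
        y, s = (y, 2) if s == 1 else (y + 1, 1)
    return tuple(out)


def make_grid(
    start_year: int,
    start_semester: int,
    k: int,
    period_starts: tuple[tuple[int, int], ...] = (),
) -> OccasionGrid:
    """Build a grid of ``k`` consecutive semesters from a starting semester."""
    return OccasionGrid(_span(start_year, start_semester, k), tuple(period_starts))


def default_grid() -> OccasionGrid:
    """The 2012-2022 study grid: 22 semesters, three food-availability periods.

    Period 1 runs 2012S1-2015S1 (before the waste treatment centre),
    period 2 runs 2015S2-2018S1 (substantial organic-matter reduction) and
    period 3 runs 2018S2-2022S2 (extreme reduction). The centre opened
    mid-2015, so semester boundaries are the natural cut points; the 2018
    boundary is placed symmetrically at the S1/S2 break.
    """
    return make_grid(2012, 1, 22, period_starts=((2015, 2), (2018, 2)))
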