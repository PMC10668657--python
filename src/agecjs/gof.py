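"""Goodness-of-fit screens for the fully time-dependent CJS model.

Before fitting a structured survival model, capture-recapture practice is
to test the plain time-dependent Cormack-Jolly-Seber model against the
data with per-occasion contingency tests and to diagnose the two classic
violations:

* **transience** (Test3.SR): newly captured individuals are re-sighted
  less often than previously marked ones, the signature of one-visit
  passage individuals. The directional statistic ``z`` is positive when
  never-re-seen new captures are in excess.
* **immediate trap-dependence** (Test2.CT): capture at an occasion changes
  the probability of capture at the next one. By convention ``z`` is
  *negative* for trap-happiness (previously captured individuals are
  re-captured more than expected) and positive for trap-shyness.

Each component sums Pearson chi-square contributions of per-occasion 2x2
tables; the directional ``z`` sums the hypergeometric-standardised
deviation of the diagnostic cell over the same tables and is N(0,1) under
the null. Sparse tables (any expected cell below 2) are pooled into the
next occasion's table; tables still degenerate after pooling are dropped,
and the degrees of freedom equal the number of informative tables kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .encounter_data import CaptureHistory

__all__ = ["ComponentResult", "test3_sr", "test2_ct", "pearson_chi2_2x2"]

_MIN_EXPECTED = 2.0  # pooling threshold for sparse per-occasion tables


@dataclass
class ComponentResult:
    """Summed per-occasion contingency test for one GOF component."""

    component: str
    chi2: float
    df: int
    p_value: float
    z: float
    tables: list[np.ndarray] = field(default_factory=list)

    @property
    def informative(self) -> bool:
        return self.df > 0

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "chi2": round(self.chi2, 6),
            "df": self.df,
            "p": float(self.p_value),
            "z": round(self.z, 6),
            "tables": [t.tolist() for t in self.tables],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def pearson_chi2_2x2(table: np.ndarray) -> float:
    """Pearson chi-square statistic of a 2x2 table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    if n == 0 or (r == 0).any() or (c == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    expected = np.outer(r, c) / n
    return float(((table - expected) ** 2 / expected).sum())


def _cell_null_moments(table: np.ndarray) -> tuple[float, float]:
    """Hypergeometric mean and variance of cell (0, 0) given the margins."""
    table = np.asarray(table, dtype=float)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    mean = r[0] * c[0] / n
    var = r[0] * r[1] * c[0] * c[1] / (n * n * (n - 1.0)) if n > 1 else 0.0
    return mean, var


def _informative(table: np.ndarray) -> bool:
    table = np.asarray(table, dtype=float)
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    if n <= 1 or (r == 0).any() or (c == 0).any():
        return False
    expected = np.outer(r, c) / n
    return bool((expected >= _MIN_EXPECTED).all())


def _pool_tables(tables: list[np.ndarray]) -> list[np.ndarray]:
    """Pool sparse per-occasion tables into their right neighbour.

    Scanning in occasion order, a table failing the expected-count rule is
    carried into the next occasion's table. A sparse leftover at the end is
    merged into the last table kept (margins stay positive, so the merged
    table remains usable) or dropped when nothing was kept.
    """
    kept: list[np.ndarray] = []
    carry = np.zeros((2, 2), dtype=np.int64)
    for tab in tables:
        cur = tab + carry
        if _informative(cur):
            kept.append(cur)
            carry = np.zeros((2, 2), dtype=np.int64)
        else:
            carry = cur
    if carry.sum() and kept:
        merged = kept[-1] + carry
        if not _informative(merged):
            return kept  # keep the clean table; drop the sparse remainder
        kept[-1] = merged
    return kept


def _summed_component(component: str, tables: list[np.ndarray], flip_sign: bool) -> ComponentResult:
    kept = _pool_tables([t for t in tables if t.sum() > 0])
    if not kept:
        return ComponentResult(component, 0.0, 0, 1.0, 0.0, [])
    chi2 = 0.0
    dev = 0.0
    var = 0.0
    for tab in kept:
        chi2 += pearson_chi2_2x2(tab)
        mean, v = _cell_null_moments(tab)
        dev += tab[0, 0] - mean
        var += v
    df = len(kept)
    z = dev / np.sqrt(var) if var > 0 else 0.0
    if flip_sign:
        z = -z
    p = float(stats.chi2.sf(chi2, df))
    return ComponentResult(component, float(chi2), df, p, float(z), kept)


def test3_sr(history: CaptureHistory) -> ComponentResult:
    """Transience component of the CJS goodness-of-fit decomposition.

    For each occasion ``t`` strictly inside the study, individuals seen at
    ``t`` are cross-classified as {newly captured at t, seen before t} x
    {re-seen after t, never re-seen}. The diagnostic cell is "newly
    captured and never re-seen"; its excess makes ``z`` positive
    (transience). With fewer than three occasions no table is informative
    and an explicit empty result (df = 0) is returned.
    """
    y, f, k = history.y, history.f, history.k
    seen_after = np.zeros((history.n, k), dtype=bool)
    if k >= 2:
        seen_after[:, : k - 1] = np.cumsum(y[:, :0:-1], axis=1)[:, ::-1] > 0
    tables = []
    for t in range(1, k - 1):
        at_t = y[:, t] == 1
        new = at_t & (f == t)
        old = at_t & (f < t)
        reseen = seen_after[:, t]
        # rows: new / old; cols: never re-seen (diagnostic) / re-seen
        tab = np.array(
            [
                [int((new & ~reseen).sum()), int((new & reseen).sum())],
                [int((old & ~reseen).sum()), int((old & reseen).sum())],
            ],
            dtype=np.int64,
        )
        tables.append(tab)
    return _summed_component("Test3.SR", tables, flip_sign=False)


def test2_ct(history: CaptureHistory) -> ComponentResult:
    """Immediate trap-dependence component of the CJS goodness-of-fit.

    For each pair of adjacent occasions ``(t, t+1)``, individuals known to
    be in the marked population at both (seen at or before ``t`` and seen
    at or after ``t+1``) are cross-classified by capture at ``t`` versus
    capture at ``t+1``. The diagnostic cell is "captured at both"; its
    excess (trap-happiness) makes ``z`` negative, matching the standard
    sign convention for this component.
    """
    y, f, k = history.y, history.f, history.k
    tables = []
    for t in range(1, k - 2):
        seen_from_next = y[:, t + 1 :].sum(axis=1) > 0
        seen_strictly_later = y[:, t + 2 :].sum(axis=1) > 0
        in_pop = (f <= t) & seen_from_next
        caught_t = y[:, t] == 1
        caught_next = y[:, t + 1] == 1
        # rows: caught at t / not; cols: caught at t+1 (diagnostic) / later only
        tab = np.array(
            [
                [
                    int((in_pop & caught_t & caught_next).sum()),
                    int((in_pop & caught_t & ~caught_next & seen_strictly_later).sum()),
                ],
                [
                    int((in_pop & ~caught_t & caught_next).sum()),
                    int((in_pop & ~caught_t & ~caught_next & seen_strictly_later).sum()),
                ],
            ],
            dtype=np.int64,
        )
        tables.append(tab)
    return _summed_component("Test2.CT", tables, flip_sign=True)
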