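"""Batch-injection performance metrics.

Given per-group injection logs (each group = one plate row of samples), the
module builds the cumulative performance table and its derived statistics:

    R_suc = N_suc / N_total          success rate
    R_sur = N_sur / N_suc            next-day survival rate
    T_suc = T_total / N_suc          mean time per successful injection
    T_sur = T_total / N_sur          mean time per surviving sample

plus the stability statistics used to compare injection methods: the range
of the cumulative T_suc column and the sample standard deviation of the
per-group T_suc values, and head-to-head comparisons (relative time
reduction, relative success-count increase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class UndefinedRateError(ZeroDivisionError):
    """A rate or per-sample time is requested with a zero denominator."""


class InvalidTableError(ValueError):
    """Cumulative table rows are not monotone or otherwise ill-formed."""


class InvalidComparisonError(ValueError):
    """Two runs compared at different total sample counts."""


@dataclass(frozen=True)
class GroupRecord:
    """Incremental log of one group (one plate row of samples)."""

    group_index: int
    t_group: float
    n_suc_group: int

    def __post_init__(self):
        if self.t_group <= 0:
            raise InvalidTableError(f"group {self.group_index}: t_group must be > 0")
        if self.n_suc_group < 0:
            raise InvalidTableError(f"group {self.group_index}: n_suc_group must be >= 0")


@dataclass(frozen=True)
class CumulativeRow:
    """One row of the cumulative performance table.

    Rates are percentages; times are seconds.  Survival columns are present
    only where survival was scored (the final row of a run).
    Values are stored unrounded; ``rounded()`` applies the 2-decimal print
    precision.
    """

    N_total: int
    T_total: float
    N_suc: int
    R_suc: float
    T_suc: float
    N_sur: int | None = None
    R_sur: float | None = None
    T_sur: float | None = None

    def rounded(self) -> "CumulativeRow":
        rnd = lambda v: None if v is None else round(v, 2)
        return CumulativeRow(self.N_total, rnd(self.T_total), self.N_suc,
                             rnd(self.R_suc), rnd(self.T_suc), self.N_sur,
                             rnd(self.R_sur), rnd(self.T_sur))


def compute_rates(N_total: int, N_suc: int, N_sur: int | None,
                  T_total: float) -> CumulativeRow:
    """Derive all performance indices from the raw counts and total time."""
    if N_total < 1:
        raise InvalidTableError("N_total must be >= 1")
    if not 0 <= N_suc <= N_total:
        raise InvalidTableError("need 0 <= N_suc <= N_total")
    if N_suc == 0:
        raise UndefinedRateError("N_suc = 0: T_suc and R_sur are undefined")
    if N_sur is not None and not 0 <= N_sur <= N_suc:
        raise InvalidTableError("need 0 <= N_sur <= N_suc")

    R_suc = 100.0 * N_suc / N_total
    T_suc = T_total / N_suc
    R_sur = T_sur = None
    if N_sur is not None:
        if N_sur == 0:
            raise UndefinedRateError("N_sur = 0: T_sur is undefined")
        R_sur = 100.0 * N_sur / N_suc
        T_sur = T_total / N_sur
    return CumulativeRow(N_total, T_total, N_suc, R_suc, T_suc, N_sur, R_sur, T_sur)


def cumulative_table(groups: list[GroupRecord], group_size: int = 11,
                     n_sur_total: int | None = None) -> list[CumulativeRow]:
    """Accumulate group logs into the cumulative performance table.

    Row g covers the first g groups: N_total = group_size * g, T_total and
    N_suc are running sums.  Survival columns appear only on the final row,
    where next-day survival is scored for the whole run.
    """
    if not groups:
        raise InvalidTableError("no group records")
    rows = []
    T = 0.0
    n_suc = 0
    for g, rec in enumerate(sorted(groups, key=lambda r: r.group_index), start=1):
        T += rec.t_group
        n_suc += rec.n_suc_group
        n_sur = n_sur_total if g == len(groups) else None
        rows.append(compute_rates(group_size * g, n_suc, n_sur, T))
    return rows


def per_group_tsuc(cum: list[CumulativeRow]) -> list[float]:
    """Recover per-group mean injection times from a cumulative table.

    Differences consecutive rows to (t_group, n_suc_group) and returns
    t_group / n_suc_group for every group.
    """
    if not cum:
        raise InvalidTableError("empty table")
    out = []
    prev_T = 0.0
    prev_n = 0
    for row in cum:
        dT = row.T_total - prev_T
        dn = row.N_suc - prev_n
        if dT < 0 or dn < 0:
            raise InvalidTableError("cumulative table must be monotone in T_total and N_suc")
        if dn == 0:
            raise UndefinedRateError("a group with zero successes has no per-group T_suc")
        out.append(dT / dn)
        prev_T, prev_n = row.T_total, row.N_suc
    return out


def dispersion_stats(cum: list[CumulativeRow]) -> dict:
    """Stability statistics of a run.

    ``range_cumulative``: max - min of the cumulative T_suc column, at the
    2-decimal precision the column is reported with.  ``sd_per_group``:
    sample standard deviation (n-1 denominator) of the per-group T_suc
    values.  The two statistics deliberately use different views of the
    data: the range tracks the reported cumulative column, while the SD
    measures group-to-group repeatability.
    """
    if len(cum) < 2:
        raise InvalidTableError("need at least 2 rows for dispersion statistics")
    col = [round(r.T_suc, 2) for r in cum]
    per_group = per_group_tsuc(cum)
    sd = float(np.std(per_group, ddof=1))
    return {"range_cumulative": max(col) - min(col), "sd_per_group": sd}


def compare_runs(a: CumulativeRow, b: CumulativeRow) -> dict:
    """Head-to-head comparison of run ``a`` against baseline ``b`` at equal
    N_total: relative total-time reduction and success-count increase, in %."""
    if a.N_total != b.N_total:
        raise InvalidComparisonError(
            f"runs compared at different N_total ({a.N_total} vs {b.N_total})")
    if b.T_total <= 0 or b.N_suc <= 0:
        raise UndefinedRateError("baseline has zero time or zero successes")
    return {
        "time_reduction": 100.0 * (b.T_total - a.T_total) / b.T_total,
        "nsuc_increase": 100.0 * (a.N_suc - b.N_suc) / b.N_suc,
    }


# ---------------------------------------------------------------- CSV I/O

GROUP_LOG_COLUMNS = ["group_index", "t_group", "n_suc_group"]


def read_group_log(path) -> tuple[list[GroupRecord], int | None]:
    """Read a per-group CSV log (columns group_index, t_group, n_suc_group
    and optionally n_sur_total on any row)."""
    df = pd.read_csv(path)
    missing = [c for c in GROUP_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidTableError(f"group log missing columns: {missing}")
    groups = [GroupRecord(int(r.group_index), float(r.t_group), int(r.n_suc_group))
              for r in df.itertuples()]
    n_sur = None
    if "n_sur_total" in df.columns:
        vals = df["n_sur_total"].dropna()
        if len(vals):
            n_sur = int(vals.iloc[-1])
    return groups, n_sur


def table_to_dataframe(rows: list[CumulativeRow], round_print: bool = True) -> pd.DataFrame:
    """Cumulative table as a DataFrame in report column order."""
    use = [r.rounded() for r in rows] if round_print else rows
    return pd.DataFrame({
        "N_total": [r.N_total for r in use],
        "T_total": [r.T_total for r in use],
        "N_suc": [r.N_suc for r in use],
        "R_suc": [r.R_suc for r in use],
        "T_suc": [r.T_suc for r in use],
        "N_sur": [r.N_sur if r.N_sur is not None else math.nan for r in use],
        "R_sur": [r.R_sur if r.R_sur is not None else math.nan for r in use],
        "T_sur": [r.T_sur if r.T_sur is not None else math.nan for r in use],
    })


def write_cumulative_csv(rows: list[CumulativeRow], path) -> None:
    table_to_dataframe(rows).to_csv(path, index=False)
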