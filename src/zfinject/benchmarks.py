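"""Reference benchmark runs for the metrics calculus.

Two published cumulative logs of an 88-sample batch (8 groups of 11:
48 embryos + 40 two-day-old larvae) serve as fixed reference inputs:
one from an automatic robotic microinjection system, one from a skilled
manual operator on the same task.  Only the raw measurements are stored —
cumulative time, cumulative success count, and the final next-day survival
count; every derived quantity (rates, per-sample times, dispersion) is
recomputed by :mod:`zfinject.metrics`.
"""

from __future__ import annotations

from .metrics import CumulativeRow, GroupRecord, compute_rates

GROUP_SIZE = 11

# (N_total, T_total [s], N_suc) per cumulative row; final next-day survivors
AUTOMATIC_RAW = [
    (11, 137.83, 10),
    (22, 299.86, 20),
    (33, 444.73, 31),
    (44, 577.94, 41),
    (55, 705.21, 52),
    (66, 835.56, 62),
    (77, 982.63, 72),
    (88, 1124.42, 81),
]
AUTOMATIC_N_SUR = 76

MANUAL_RAW = [
    (11, 366.08, 9),
    (22, 710.49, 19),
    (33, 1021.02, 30),
    (44, 1348.16, 41),
    (55, 1684.65, 51),
    (66, 2063.27, 59),
    (77, 2452.78, 68),
    (88, 2872.65, 75),
]
MANUAL_N_SUR = 67


def _to_groups(raw) -> list[GroupRecord]:
    groups = []
    prev_T, prev_n = 0.0, 0
    for g, (_, T, n) in enumerate(raw, start=1):
        groups.append(GroupRecord(g, round(T - prev_T, 2), n - prev_n))
        prev_T, prev_n = T, n
    return groups


def automatic_group_log() -> tuple[list[GroupRecord], int]:
    """Per-group log of the automatic run, recovered by differencing."""
    return _to_groups(AUTOMATIC_RAW), AUTOMATIC_N_SUR


def manual_group_log() -> tuple[list[GroupRecord], int]:
    """Per-group log of the manual run, recovered by differencing."""
    return _to_groups(MANUAL_RAW), MANUAL_N_SUR


def _final_row(raw, n_sur) -> CumulativeRow:
    N_total, T_total, N_suc = raw[-1]
    return compute_rates(N_total, N_suc, n_sur, T_total)


def automatic_final_row() -> CumulativeRow:
    return _final_row(AUTOMATIC_RAW, AUTOMATIC_N_SUR)


def manual_final_row() -> CumulativeRow:
    return _final_row(MANUAL_RAW, MANUAL_N_SUR)
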