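"""Larval photomotor response: AUC summaries and lowest-effect levels.

Movement is tracked per well in 6-s bins over minutes 6-24 of an
alternating light/dark schedule.  Per period (light, dark) the test
statistic is the area under the log-transformed movement curve,
AUC = sum of ln(movement + 1) over the period's bins of the first
light+dark cycle after calibration.  Dead or malformed animals are
excluded; a treatment with more than 30% of wells excluded is removed
entirely.  Each retained concentration is compared to the day-matched
control by a two-sided Student's t-test with Holm correction across
concentrations within a period, and the lowest effect level (LEL) is
the lowest concentration whose effect is confirmed at the next-highest
tested concentration in the same direction (the top concentration needs
no confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AssaySchedule
from .stats import holm_adjust, student_t_two_sided

__all__ = [
    "LelResult",
    "compute_auc",
    "auc_table",
    "apply_exclusions",
    "call_lel",
]

PERIODS = ("light", "dark")


@dataclass(frozen=True)
class LelResult:
    """Per-period lowest-effect-level call for one chemical."""

    chemical: str
    period: str
    lel_um: float | None
    direction: str | None  # "hypo" (less movement) or "hyper"
    p_adjusted: dict
    all_removed: bool = False


def compute_auc(trace: pd.DataFrame, schedule: AssaySchedule | None = None,
                log_base: float | None = None) -> tuple:
    """(auc_light, auc_dark) of one well over the first cycle.

    AUC is the rectangular sum of log(movement + 1) over the period's
    6-s bins; natural log by default, ``log_base`` for another base.
    Raises if the first cycle is not fully covered.
    """
    schedule = schedule or AssaySchedule()
    t = trace["t_start_s"].to_numpy(dtype=float)
    m = trace["movement"].to_numpy(dtype=float)
    if np.any(m < 0):
        raise ValueError("movement must be nonnegative")
    out = []
    for _, start, end in schedule.first_cycle:
        sel = (t >= start) & (t < end)
        expected = int(round((end - start) / schedule.bin_seconds))
        if sel.sum() != expected:
            raise ValueError(
                f"first cycle [{start}, {end}) s needs {expected} bins, "
                f"found {int(sel.sum())}")
        vals = np.log1p(m[sel])
        if log_base is not None:
            vals = vals / np.log(log_base)
        out.append(float(vals.sum()))
    return tuple(out)


def auc_table(traces: pd.DataFrame, schedule: AssaySchedule | None = None
              ) -> pd.DataFrame:
    """Per-well AUCs: one row per well with auc_light, auc_dark."""
    schedule = schedule or AssaySchedule()
    rows = []
    keys = ["chemical", "conc_um", "plate", "well"]
    for (chem, conc, plate, well), sub in traces.groupby(keys, sort=True):
        excluded = bool(sub["excluded"].iloc[0]) if "excluded" in sub else False
        if excluded:
            continue
        al, ad = compute_auc(sub, schedule)
        rows.append((chem, conc, plate, well, al, ad))
    return pd.DataFrame(rows, columns=keys + ["auc_light", "auc_dark"])


def apply_exclusions(traces: pd.DataFrame, max_excluded_frac: float = 0.30):
    """Drop excluded wells; remove treatments with > 30% wells excluded.

    Returns (retained traces, list of removed (chemical, conc_um)).
    """
    removed = []
    keep = []
    for (chem, conc), sub in traces.groupby(["chemical", "conc_um"],
                                            sort=True):
        wells = sub.groupby(["plate", "well"])["excluded"].first()
        frac = float(wells.mean())
        if frac > max_excluded_frac:
            removed.append((chem, conc))
        else:
            keep.append(sub[~sub["excluded"]])
    retained = (pd.concat(keep, ignore_index=True) if keep
                else traces.iloc[0:0])
    return retained, removed


def _scan_lel(concs, padj, signs, alpha):
    """Ascending scan with next-concentration confirmation."""
    for i, c in enumerate(concs):
        if padj[i] > alpha:
            continue
        if i == len(concs) - 1:  # highest tested: no successor needed
            return c, signs[i]
        if padj[i + 1] <= alpha and signs[i + 1] == signs[i]:
            return c, signs[i]
    return None, None


def call_lel(aucs: pd.DataFrame, alpha: float = 0.05,
             control_conc: float = 0.0) -> list:
    """Per-chemical, per-period LEL calls from a per-well AUC table.

    The Holm family is the set of positive concentrations within one
    (chemical, period); light and dark are separate families.  The
    day-matched control is the ``control_conc`` group of the same
    chemical's table.
    """
    results = []
    for chem, sub in aucs.groupby("chemical", sort=True):
        control = sub[sub.conc_um == control_conc]
        treated_concs = sorted(c for c in sub.conc_um.unique()
                               if c != control_conc)
        for period in PERIODS:
            col = f"auc_{period}"
            if control.empty or not treated_concs:
                results.append(LelResult(chem, period, None, None, {},
                                         all_removed=True))
                continue
            ctrl = control[col].to_numpy()
            pvals, signs = [], []
            for c in treated_concs:
                trt = sub.loc[sub.conc_um == c, col].to_numpy()
                res = student_t_two_sided(trt, ctrl)
                pvals.append(res.p_value)
                signs.append(res.direction)
            padj = holm_adjust(pvals)
            lel, sign = _scan_lel(treated_concs, padj, signs, alpha)
            direction = None if sign is None else ("hyper" if sign > 0
                                                   else "hypo")
            results.append(LelResult(
                chem, period, lel, direction,
                dict(zip(treated_concs, (float(p) for p in padj)))))
    return results


def lel_table(results) -> pd.DataFrame:
    """Tidy LEL table (chemical, period, lel_um, direction)."""
    return pd.DataFrame(
        [(r.chemical, r.period, r.lel_um, r.direction) for r in results],
        columns=["chemical", "period", "lel_um", "direction"])
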