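"""Per-breath tidal breathing indices and per-subject epoch averages.

Seven indices per breath:

========  =============================================================
tI        expiratory start minus inspiratory start (s)
tE        expiratory end minus expiratory start (s)
tTot      tI + tE (s)
RR        60 / tTot (breaths per minute)
tI/tE     inspiratory to expiratory time ratio
tI/tTot   duty cycle, fraction of the breath spent inspiring
IE50      TIF50 / TEF50 — the ratio of inspiratory to expiratory flow
          (or TA displacement rate, for SLP) at 50 % of the breath's
          tidal excursion; a shape statistic of the tidal flow-volume
          (rate-level) loop
========  =============================================================

Timing indices come from the markers alone.  IE50 needs both the level
trace (volume / displacement) and its rate (flow / displacement rate): for
each breath the 50 % level is the midpoint between the level at inspiratory
start and at expiratory start, and TIF50 / TEF50 are |rate| linearly
interpolated where each limb crosses that midpoint.  A limb crossing the
midpoint more than once (non-monotone limb) contributes the time-weighted
mean |rate| over all crossings and the breath is flagged for QC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .breaths import BreathMarkers
from .errors import DataError
from .trace import Trace

__all__ = [
    "PARAMETERS",
    "timing_indices",
    "ie50",
    "displacement_rate",
    "breath_table",
    "average_subject",
    "rr_to_ttot_discrepancy",
]

PARAMETERS = ["RR", "tI", "tE", "tTot", "tI_over_tE", "tI_over_tTot", "IE50"]


def timing_indices(markers: BreathMarkers) -> pd.DataFrame:
    """Six timing-derived indices per breath, straight from the markers."""
    tI = markers.exp_start - markers.insp_start
    tE = markers.exp_end - markers.exp_start
    tTot = markers.exp_end - markers.insp_start
    return pd.DataFrame(
        {
            "breath_id": np.arange(markers.n_breaths),
            "insp_start_s": markers.insp_start,
            "tI": tI,
            "tE": tE,
            "tTot": tTot,
            "RR": 60.0 / tTot,
            "tI_over_tE": tI / tE,
            "tI_over_tTot": tI / tTot,
        }
    )


def displacement_rate(level: Trace) -> Trace:
    """First derivative of a level trace by central differences.

    This is how the SLP displacement rate is obtained — the SLP device has
    no native rate channel.
    """
    rate = np.gradient(level.values) * level.fs
    out = level.with_values(rate)
    out.label = level.label + "_rate"
    return out


def _limb_crossings(
    t: np.ndarray, level: np.ndarray, rate: np.ndarray, mid: float
) -> tuple[float, bool]:
    """Mean |rate| where a limb crosses ``mid``; flag when crossings > 1.

    With several crossings each contributes with a weight proportional to
    the time span it governs (half the gap to each neighbouring crossing),
    so brief re-crossings of the midpoint do not dominate.
    """
    y = level - mid
    s = np.sign(y)
    cross = np.nonzero(s[:-1] * s[1:] < 0)[0]
    exact = np.nonzero(y == 0)[0]
    t_cross, r_cross = [], []
    for k in cross:
        frac = y[k] / (y[k] - y[k + 1])
        tc = t[k] + frac * (t[k + 1] - t[k])
        t_cross.append(tc)
        r_cross.append(abs(rate[k] + frac * (rate[k + 1] - rate[k])))
    for k in exact:
        t_cross.append(t[k])
        r_cross.append(abs(rate[k]))
    if not t_cross:
        return np.nan, False
    order = np.argsort(t_cross)
    tc = np.asarray(t_cross)[order]
    rc = np.asarray(r_cross)[order]
    if tc.size == 1:
        return float(rc[0]), False
    w = np.empty_like(tc)
    w[0] = (tc[1] - tc[0]) / 2
    w[-1] = (tc[-1] - tc[-2]) / 2
    if tc.size > 2:
        w[1:-1] = (tc[2:] - tc[:-2]) / 2
    if w.sum() == 0:
        w = np.ones_like(w)
    return float(np.average(rc, weights=w)), True


def ie50(
    level: Trace, rate: Trace, markers: BreathMarkers
) -> pd.DataFrame:
    """Per-breath IE50 = TIF50/TEF50 from a level trace and its rate trace.

    Both traces must share a time base.  Breaths with (near-)zero tidal
    excursion get a missing IE50; non-monotone limbs are flagged.
    """
    if abs(level.fs - rate.fs) > 1e-6 * level.fs or abs(level.t0 - rate.t0) > 1e-9:
        raise DataError("level and rate traces must share a time base")
    t = level.times
    rows = []
    for b in range(markers.n_breaths):
        a, m, c = markers.insp_start[b], markers.exp_start[b], markers.exp_end[b]
        v_a = float(np.interp(a, t, level.values))
        v_m = float(np.interp(m, t, level.values))
        excursion = v_m - v_a
        if abs(excursion) < 1e-12 * max(1.0, float(np.ptp(level.values))):
            rows.append((b, np.nan, np.nan, np.nan, True, "zero tidal excursion"))
            continue
        mid = 0.5 * (v_a + v_m)
        insp = slice(*np.searchsorted(t, [a, m]))
        expi = slice(*np.searchsorted(t, [m, c]))
        tif50, flag_i = _limb_crossings(
            t[insp], level.values[insp], rate.values[insp], mid
        )
        tef50, flag_e = _limb_crossings(
            t[expi], level.values[expi], rate.values[expi], mid
        )
        if not np.isfinite(tif50) or not np.isfinite(tef50) or tef50 == 0:
            rows.append((b, tif50, tef50, np.nan, True, "midpoint not crossed"))
            continue
        rows.append((b, tif50, tef50, tif50 / tef50, flag_i or flag_e, ""))
    return pd.DataFrame(
        rows,
        columns=["breath_id", "TIF50", "TEF50", "IE50", "ie50_flagged", "ie50_note"],
    )


def breath_table(
    markers: BreathMarkers,
    level: Trace,
    rate: Trace,
    device: str = "",
    subject: str = "",
    session: str = "",
) -> pd.DataFrame:
    """All seven indices per breath, keyed by subject, device, session."""
    df = timing_indices(markers).merge(
        ie50(level, rate, markers)[["breath_id", "IE50", "ie50_flagged"]],
        on="breath_id",
    )
    df.insert(0, "subject", subject)
    df.insert(1, "device", device)
    df.insert(2, "session", session)
    return df


def average_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted arithmetic mean of each parameter over a subject's epoch.

    Ratio parameters are averaged as per-breath ratios, not ratios of
    means.  One row per (subject, device, session) with the breath count.
    """
    if table.empty:
        raise DataError("cannot average an empty breath table")
    keys = ["subject", "device", "session"]
    grouped = table.groupby(keys, sort=True)
    out = grouped[PARAMETERS].mean().reset_index()
    out["n_breaths"] = grouped.size().to_numpy()
    return out


def rr_to_ttot_discrepancy(rr: float, delta_rr: float = 2.0) -> float:
    """|Delta tTot| implied by an RR discrepancy at a given rate.

    Since RR = 60/tTot, a device disagreement of ``delta_rr`` breaths/min at
    rate ``rr`` corresponds to an absolute tTot disagreement of
    |60/rr - 60/(rr + delta_rr)| seconds — the propagation used to judge
    whether a tTot limit of agreement is clinically consequential.
    """
    if rr <= 0 or rr + delta_rr <= 0:
        raise DataError("respiratory rates must be positive")
    return abs(60.0 / rr - 60.0 / (rr + delta_rr))
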