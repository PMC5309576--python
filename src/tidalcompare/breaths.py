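"""Breath detection, artifact screening, and inter-device breath pairing.

Respiratory cycles are delimited on the level trace (volume for PNT,
TA displacement for SLP): an inspiratory start is a trough, an expiratory
start the following peak, and the expiratory end the next trough.
Candidate extrema come from zero crossings of the first derivative; the
derivative (never the signal itself, whose raw values feed the timing
indices) is lightly smoothed so that measurement noise does not make the
zero crossings chatter.  Where the original workflow relied on visual
screening of candidates, explicit rules on breath duration and amplitude
stand in, and every exclusion is logged with its reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .trace import Trace

__all__ = [
    "Extrema",
    "BreathMarkers",
    "ScreeningRules",
    "BreathPairing",
    "detect_extrema",
    "screen_breaths",
    "pair_breaths",
]

TROUGH, PEAK = -1, 1


@dataclass
class Extrema:
    """Alternating trough/peak candidates on one trace."""

    times: np.ndarray  # s
    indices: np.ndarray  # sample indices into the trace
    kinds: np.ndarray  # -1 trough, +1 peak
    values: np.ndarray  # raw signal values at the extrema

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ScreeningRules:
    """Programmatic stand-in for visual screening of candidate breaths."""

    min_tTot: float = 0.5  # s
    max_tTot: float = 15.0  # s
    min_amplitude_fraction: float = 0.25  # of the median breath amplitude
    enforce_alternation: bool = True

    def __post_init__(self) -> None:
        if self.min_tTot <= 0 or self.max_tTot <= 0:
            raise ConfigError("duration thresholds must be positive")
        if self.max_tTot <= self.min_tTot:
            raise ConfigError("max_tTot must exceed min_tTot")
        if not (0 < self.min_amplitude_fraction < 1):
            raise ConfigError("min_amplitude_fraction must be in (0, 1)")


@dataclass
class BreathMarkers:
    """Per-breath inspiratory-start / expiratory-start / expiratory-end times."""

    insp_start: np.ndarray
    exp_start: np.ndarray
    exp_end: np.ndarray
    amplitude: np.ndarray = field(default_factory=lambda: np.array([]))
    exclusions: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.insp_start = np.asarray(self.insp_start, dtype=float)
        self.exp_start = np.asarray(self.exp_start, dtype=float)
        self.exp_end = np.asarray(self.exp_end, dtype=float)
        if not (
            self.insp_start.size == self.exp_start.size == self.exp_end.size
        ):
            raise DataError("marker arrays must have equal length")
        if self.insp_start.size:
            if not (
                np.all(self.insp_start < self.exp_start)
                and np.all(self.exp_start < self.exp_end)
            ):
                raise DataError("markers must satisfy insp < exp_start < exp_end")
            if not np.all(np.diff(self.insp_start) > 0) or not np.all(
                self.exp_end[:-1] <= self.insp_start[1:] + 1e-9
            ):
                raise DataError("breaths must be time-ordered and non-overlapping")

    @property
    def n_breaths(self) -> int:
        return self.insp_start.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "breath_id": np.arange(self.n_breaths),
                "insp_start_s": self.insp_start,
                "exp_start_s": self.exp_start,
                "exp_end_s": self.exp_end,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Markers plus the exclusion log, one row per kept or excluded breath."""
        df = self.to_frame()
        df["excluded_reason"] = ""
        excl = pd.DataFrame(
            {
                "breath_id": -1,
                "insp_start_s": [t for t, _ in self.exclusions],
                "exp_start_s": np.nan,
                "exp_end_s": np.nan,
                "excluded_reason": [r for _, r in self.exclusions],
            }
        )
        pd.concat([df, excl], ignore_index=True).to_csv(path, index=False)


@dataclass
class BreathPairing:
    """One-to-one correspondence between breaths of two devices."""

    pairs: list[tuple[int, int]]
    unpaired_a: list[int]
    unpaired_b: list[int]

    def __post_init__(self) -> None:
        a_idx = [i for i, _ in self.pairs]
        b_idx = [j for _, j in self.pairs]
        if len(set(a_idx)) != len(a_idx) or len(set(b_idx)) != len(b_idx):
            raise DataError("pairing is not one-to-one")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


# --------------------------------------------------------------------------


def detect_extrema(trace: Trace, derivative_smoothing: float = 0.2) -> Extrema:
    """Find alternating troughs/peaks from zero crossings of the derivative.

    The first derivative is estimated by central differences and smoothed
    with a moving average of width ``derivative_smoothing`` seconds (the
    smoothing touches only the derivative used for detection, never the
    values used later for parameter computation).  Sign changes of the
    smoothed derivative mark extremum neighbourhoods; the extremum is then
    refined to the most extreme *raw* sample nearby.  Consecutive same-kind
    extrema are collapsed to the more extreme one so the output alternates.
    """
    if len(trace) < int(trace.fs):
        raise DataError("trace must be at least 1 s long")
    x = trace.values
    d = np.gradient(x)
    w = max(1, int(round(derivative_smoothing * trace.fs)))
    if w > 1:
        d = np.convolve(d, np.ones(w) / w, mode="same")

    s = np.sign(d)
    # carry the last non-zero sign through exact zeros (plateaus)
    nz = s != 0
    if not nz.any():
        empty = np.array([])
        return Extrema(empty, empty.astype(int), empty.astype(int), empty)
    idx_nz = np.nonzero(nz)[0]
    signs = s[idx_nz]
    changes = np.nonzero(np.diff(signs) != 0)[0]

    half = w // 2 + 2
    cand_idx, cand_kind = [], []
    prev_k = -1
    for m, c in enumerate(changes):
        i, j = idx_nz[c], idx_nz[c + 1]
        kind = PEAK if signs[c] > 0 else TROUGH
        # refine to the most extreme raw sample, but never across a
        # neighbouring candidate so indices stay strictly increasing
        lo = max(0, i - half, prev_k + 1)
        hi = min(x.size, j + half + 1)
        if m + 1 < changes.size:
            hi = min(hi, idx_nz[changes[m + 1]] + 1)
        if lo >= hi:
            continue
        k = lo + (np.argmax(x[lo:hi]) if kind == PEAK else np.argmin(x[lo:hi]))
        cand_idx.append(int(k))
        cand_kind.append(kind)
        prev_k = int(k)

    # collapse consecutive same-kind candidates to the more extreme one
    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for k, kind in zip(cand_idx, cand_kind):
        if keep_kind and keep_kind[-1] == kind:
            prev = keep_idx[-1]
            better = (kind == PEAK and x[k] > x[prev]) or (
                kind == TROUGH and x[k] < x[prev]
            )
            if better:
                keep_idx[-1] = k
        else:
            keep_idx.append(k)
            keep_kind.append(kind)

    idx = np.asarray(keep_idx, dtype=int)
    # sub-sample refinement: vertex of the parabola through the extremum
    # sample and its neighbours (clamped to +/- 1 sample), removing the
    # half-sample quantisation bias toward an extremum's flatter side
    offsets = np.zeros(idx.size)
    for n, k in enumerate(idx):
        if 0 < k < x.size - 1:
            denom = x[k - 1] - 2.0 * x[k] + x[k + 1]
            if abs(denom) > 1e-300:
                offsets[n] = np.clip(0.5 * (x[k - 1] - x[k + 1]) / denom, -1.0, 1.0)
    return Extrema(
        times=trace.t0 + (idx + offsets) / trace.fs,
        indices=idx,
        kinds=np.asarray(keep_kind, dtype=int),
        values=x[idx] if idx.size else np.array([]),
    )


def _prune_reversals(
    candidates: Extrema, threshold: float
) -> tuple[Extrema, list[tuple[float, str]]]:
    """Iteratively drop adjacent extremum pairs whose excursion is small.

    An excursion below ``threshold`` between two neighbouring extrema is a
    reversal that does not correspond to an inspiratory trough / expiratory
    peak — noise chatter around a flat extremum, or a low-amplitude
    artifact oscillation.  Removing the pair keeps the sequence
    alternating; when the removed member was more extreme than its
    same-kind neighbour, the neighbour inherits its position.
    """
    times = list(candidates.times)
    idx = list(candidates.indices)
    kinds = list(candidates.kinds)
    values = list(candidates.values)
    log: list[tuple[float, str]] = []
    while len(values) >= 2:
        exc = np.abs(np.diff(values))
        j = int(np.argmin(exc))
        if exc[j] >= threshold:
            break
        log.append(
            (times[j], f"low-excursion oscillation pruned ({exc[j]:.4g} < {threshold:.4g})")
        )
        # candidate at j+1 has the same kind as j-1; keep the more extreme
        # one, preferring the later position on near-ties (an inspiratory
        # start is the last trough before the rise, so after pruning an
        # oscillation in a flat pause the marker must sit at its end)
        if j > 0:
            k, v_new, v_old = kinds[j + 1], values[j + 1], values[j - 1]
            better = (k == PEAK and v_new > v_old) or (
                k == TROUGH and v_new < v_old
            )
            if better or abs(v_new - v_old) < 0.05 * threshold:
                times[j - 1], idx[j - 1], values[j - 1] = (
                    times[j + 1], idx[j + 1], values[j + 1],
                )
        del times[j : j + 2], idx[j : j + 2], kinds[j : j + 2], values[j : j + 2]
    return (
        Extrema(
            times=np.asarray(times),
            indices=np.asarray(idx, dtype=int),
            kinds=np.asarray(kinds, dtype=int),
            values=np.asarray(values),
        ),
        log,
    )


def screen_breaths(
    candidates: Extrema, rules: ScreeningRules | None = None
) -> BreathMarkers:
    """Assemble trough-peak-trough breaths and drop the ones a rule rejects.

    Candidate extrema are first pruned of low-excursion reversals (noise
    chatter, artifact oscillations) below the amplitude floor; surviving
    breaths violating the duration window or the amplitude rule are then
    removed.  Every removal is logged with a reason.  Partial breaths at
    the epoch edges are dropped implicitly because a breath needs all three
    markers.
    """
    rules = rules or ScreeningRules()
    prune_log: list[tuple[float, str]] = []
    if len(candidates) >= 2:
        # full-scale envelope of the candidates; chatter excursions are a
        # small fraction of it regardless of how many chatter extrema exist
        scale = float(np.ptp(candidates.values))
        if scale > 0:
            candidates, prune_log = _prune_reversals(
                candidates, rules.min_amplitude_fraction * scale
            )
    if len(candidates) < 3:
        return BreathMarkers(
            np.array([]), np.array([]), np.array([]), np.array([]),
            exclusions=prune_log + [(np.nan, "fewer than three extrema")],
        )

    kinds, times, values = candidates.kinds, candidates.times, candidates.values
    raw = []  # (insp, exp_start, exp_end, amplitude)
    i = 0
    while i + 2 < len(kinds):
        if kinds[i] == TROUGH and kinds[i + 1] == PEAK and kinds[i + 2] == TROUGH:
            amp = values[i + 1] - values[i]
            raw.append((times[i], times[i + 1], times[i + 2], amp))
            i += 2  # next breath starts at this ending trough
        else:
            i += 1

    if not raw:
        return BreathMarkers(
            np.array([]), np.array([]), np.array([]), np.array([]),
            exclusions=prune_log + [(np.nan, "no trough-peak-trough triple")],
        )

    med_amp = float(np.median([b[3] for b in raw]))
    kept, exclusions = [], []
    for insp, pk, end, amp in raw:
        ttot = end - insp
        if ttot < rules.min_tTot:
            exclusions.append((insp, f"tTot {ttot:.3f}s below min {rules.min_tTot}s"))
        elif ttot > rules.max_tTot:
            exclusions.append((insp, f"tTot {ttot:.3f}s above max {rules.max_tTot}s"))
        elif amp < rules.min_amplitude_fraction * med_amp:
            exclusions.append(
                (insp, f"amplitude {amp:.4g} below "
                       f"{rules.min_amplitude_fraction:.2f} x median {med_amp:.4g}")
            )
        else:
            kept.append((insp, pk, end, amp))

    if not kept:
        return BreathMarkers(
            np.array([]), np.array([]), np.array([]), np.array([]),
            exclusions=prune_log + exclusions
            + [(np.nan, "no breath survived screening")],
        )
    arr = np.array(kept)
    return BreathMarkers(
        insp_start=arr[:, 0],
        exp_start=arr[:, 1],
        exp_end=arr[:, 2],
        amplitude=arr[:, 3],
        exclusions=prune_log + exclusions,
    )


def pair_breaths(
    a: BreathMarkers, b: BreathMarkers, tolerance: float = 0.5
) -> BreathPairing:
    """Greedy one-to-one nearest-match on inspiratory-start times.

    Matching by temporal proximity (rather than ordinal index) survives a
    breath missed by one device.  Breaths without a partner within
    ``tolerance`` seconds are left unpaired and excluded from paired
    analyses.
    """
    if a.n_breaths == 0 or b.n_breaths == 0:
        return BreathPairing([], list(range(a.n_breaths)), list(range(b.n_breaths)))
    dist = np.abs(a.insp_start[:, None] - b.insp_start[None, :])
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i, j in order:
        if dist[i, j] > tolerance:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((int(i), int(j)))
        used_a.add(int(i))
        used_b.add(int(j))
    pairs.sort()
    return BreathPairing(
        pairs=pairs,
        unpaired_a=[i for i in range(a.n_breaths) if i not in used_a],
        unpaired_b=[j for j in range(b.n_breaths) if j not in used_b],
    )
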