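"""Synthetic paired PNT/SLP tidal-breathing recordings with known ground truth.

The generator emulates a 45-second epoch of quiet (or post-exercise) tidal
breathing recorded simultaneously by two devices:

* a pneumotachograph ("PNT") producing airflow at 100 Hz, with volume
  obtained — as in the real acquisition chain — by integrating the flow;
* a structured light plethysmograph ("SLP") producing an uncalibrated
  thoraco-abdominal displacement trace at 30 Hz, related to volume by a
  device gain, slow baseline drift, independent noise, an unknown
  inter-device time offset, and (optionally) breath-timing distortion.

Breath morphology
-----------------
Each breath is built from two smooth limbs shaped by a symmetric Beta
distribution.  During inspiration of duration ``tI`` the volume rises as
the regularised incomplete Beta function

    v(u) = A * I_u(a, a),     u = t / tI in [0, 1]

and during expiration of duration ``tE`` it falls as ``A * (1 -
I_w(b, b))``.  Flow is the analytic derivative, ``A * Beta_pdf(u; a, a) /
tI``.  The concentration parameter sets how sharply flow peaks mid-limb;
because the symmetric Beta median is exactly 1/2, the flow magnitude at
the 50 %-volume crossing has the closed form ``A * f(a) / tI`` with

    f(a) = Beta_pdf(1/2; a, a) = 0.5**(2a - 2) / B(a, a)

so the breath's IE50 (inspiratory over expiratory flow at 50 % tidal
volume) is exactly ``(tE / tI) * f(a) / f(b)``.  Given a target IE50 the
concentrations are solved per breath, which makes every downstream IE50
estimate checkable against an exact analytic value.  In the physiological
IE50 range the concentrations stay near 2-3, giving markers (troughs and
peaks) with finite curvature — no artificially flat extrema.

Breath-to-breath variability of ``tI`` and ``tE`` is gamma-distributed
(positive support) with configurable mean and coefficient of variation.
Artifact breaths — short, low-amplitude oscillations such as swallows or
sensor glitches — are inserted at a configurable per-breath rate and
flagged in the ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .errors import ConfigError, DataError
from .trace import Trace

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PairedRecording",
    "simulate_breath_train",
    "render_waveforms",
    "make_cohort",
    "write_recording",
    "read_recording",
]

_LN2 = math.log(2.0)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Generator settings for one paired recording.

    Defaults describe resting tidal breathing of an adult (respiratory rate
    ~13.5 breaths/min, inspiratory fraction ~0.42, IE50 ~1.2); the
    :meth:`post_exercise` preset describes elevated breathing (~43
    breaths/min).  Amplitudes are in litres for PNT and arbitrary units for
    the uncalibrated SLP displacement.
    """

    epoch_length: float = 45.0  # s of breathing to cover
    n_breaths: int | None = None  # if set, overrides epoch_length
    mean_tI: float = 1.85  # s, mean inspiratory time
    mean_tE: float = 2.60  # s, mean expiratory time
    cv_timing: float = 0.10  # CV of per-breath tI and tE
    target_IE50: float = 1.2  # dimensionless loop-shape index
    tidal_amplitude: float = 0.5  # L, tidal volume
    slp_gain: float = 1.0  # au per L, uncalibrated device gain
    noise_sd_pnt: float = 0.005  # L/s, white noise on flow
    noise_sd_slp: float = 0.003  # au, white noise on displacement
    drift_amplitude: float = 0.05  # au, slow SLP baseline drift
    drift_period: float = 40.0  # s
    inter_device_offset: float = 0.5  # s, SLP delayed relative to PNT
    slp_marker_jitter_sd: float = 0.0  # s, SLP breath-timing distortion
    fs_pnt: float = 100.0  # Hz
    fs_slp: float = 30.0  # Hz
    artifact_rate: float = 0.05  # artifact breaths per breath
    seed: int = 0

    def validate(self) -> None:
        if self.mean_tI <= 0 or self.mean_tE <= 0:
            raise ConfigError("mean_tI and mean_tE must be positive")
        if self.n_breaths is None and self.epoch_length <= 0:
            raise ConfigError("epoch_length must be positive")
        if self.n_breaths is not None and self.n_breaths < 1:
            raise ConfigError("n_breaths must be >= 1")
        if self.cv_timing < 0:
            raise ConfigError("cv_timing must be non-negative")
        if self.target_IE50 <= 0:
            raise ConfigError("target_IE50 must be positive")
        if self.tidal_amplitude <= 0:
            raise ConfigError("tidal_amplitude must be positive")
        if not (self.fs_pnt > self.fs_slp > 0):
            raise ConfigError("require fs_pnt > fs_slp > 0")
        if not (0 <= self.artifact_rate < 1):
            raise ConfigError("artifact_rate must be in [0, 1)")
        if self.drift_period <= 0:
            raise ConfigError("drift_period must be positive")

    @classmethod
    def resting(cls, **overrides) -> "SimConfig":
        """Quiet-breathing preset (RR ~13.5 brpm)."""
        return dataclasses.replace(cls(), **overrides)

    @classmethod
    def post_exercise(cls, **overrides) -> "SimConfig":
        """Elevated-breathing preset (RR ~43 brpm, near-symmetric breaths)."""
        base = cls(mean_tI=0.66, mean_tE=0.73, target_IE50=0.99)
        return dataclasses.replace(base, **overrides)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """True breath timings and parameters implied by a simulation.

    All marker arrays are in seconds from the start of the PNT time base.
    ``exp_end[i] == insp_start[i + 1]`` because breaths are contiguous.
    """

    insp_start: np.ndarray
    exp_start: np.ndarray
    exp_end: np.ndarray
    amplitude: np.ndarray  # per-breath tidal excursion
    IE50: np.ndarray
    is_artifact: np.ndarray  # bool per breath
    inter_device_offset: float = 0.0

    @property
    def n_breaths(self) -> int:
        return self.insp_start.size

    @property
    def tI(self) -> np.ndarray:
        return self.exp_start - self.insp_start

    @property
    def tE(self) -> np.ndarray:
        return self.exp_end - self.exp_start

    @property
    def tTot(self) -> np.ndarray:
        return self.tI + self.tE

    @property
    def RR(self) -> np.ndarray:
        return 60.0 / self.tTot

    @property
    def tI_over_tE(self) -> np.ndarray:
        return self.tI / self.tE

    @property
    def tI_over_tTot(self) -> np.ndarray:
        return self.tI / self.tTot

    def validate(self) -> None:
        m = np.column_stack([self.insp_start, self.exp_start, self.exp_end])
        if not np.all(np.diff(m.ravel()) >= -1e-12):
            raise DataError("ground-truth markers are not increasing/alternating")
        if not np.allclose(self.tI + self.tE, self.tTot):
            raise DataError("tI + tE != tTot")

    def to_dict(self) -> dict:
        return {
            "insp_start": self.insp_start.tolist(),
            "exp_start": self.exp_start.tolist(),
            "exp_end": self.exp_end.tolist(),
            "amplitude": self.amplitude.tolist(),
            "IE50": self.IE50.tolist(),
            "is_artifact": self.is_artifact.astype(int).tolist(),
            "inter_device_offset": self.inter_device_offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            insp_start=np.asarray(d["insp_start"], dtype=float),
            exp_start=np.asarray(d["exp_start"], dtype=float),
            exp_end=np.asarray(d["exp_end"], dtype=float),
            amplitude=np.asarray(d["amplitude"], dtype=float),
            IE50=np.asarray(d["IE50"], dtype=float),
            is_artifact=np.asarray(d["is_artifact"], dtype=bool),
            inter_device_offset=float(d["inter_device_offset"]),
        )


@dataclass
class PairedRecording:
    """One subject's simultaneous PNT and SLP recording plus ground truth."""

    pnt_flow: Trace
    pnt_volume: Trace
    slp_displacement: Trace
    truth: GroundTruth
    config: SimConfig
    subject_id: str = "S00"


# --------------------------------------------------------------------------
# breath-shape mathematics
# --------------------------------------------------------------------------


_BASE_CONC = 2.0  # Beta concentration of the unadjusted limb


def _f(a: float) -> float:
    """Mid-volume flow shape factor: Beta(a, a) density at its median 1/2."""
    return float(0.5 ** (2.0 * a - 2.0) / special.beta(a, a))


def solve_shape_exponents(ie50: float, tI: float, tE: float) -> tuple[float, float]:
    """Beta concentrations (a, b) giving a breath the requested analytic IE50.

    IE50 = (tE/tI) * f(a)/f(b).  One limb keeps the baseline concentration
    2 (f(2) = 1.5) and the other is solved on f's increasing branch, which
    maps (1, inf) onto (1, inf).
    """
    r = ie50 * tI / tE
    if abs(r - 1.0) < 1e-12:
        return _BASE_CONC, _BASE_CONC

    def solve_f(target: float) -> float:
        if target <= 1.0:
            raise ConfigError(f"IE50 target unattainable (f={target})")
        hi = 4.0
        while _f(hi) < target:
            hi *= 2.0
            if hi > 1e4:  # pragma: no cover - unreachable for sane IE50
                raise ConfigError(f"IE50 target unattainable (f={target})")
        return brentq(lambda a: _f(a) - target, 1.0 + 1e-9, hi, xtol=1e-12)

    f0 = _f(_BASE_CONC)
    if r >= 1.0:
        return solve_f(f0 * r), _BASE_CONC
    return _BASE_CONC, solve_f(f0 / r)


def _limb_volume(u: np.ndarray, a: float) -> np.ndarray:
    """Normalised rising-limb volume: regularised incomplete Beta I_u(a, a)."""
    return special.betainc(a, a, np.clip(u, 0.0, 1.0))


def _limb_rate(u: np.ndarray, a: float, duration: float) -> np.ndarray:
    """d/dt of the rising limb; sign is flipped by the caller for expiration."""
    u = np.clip(u, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = u ** (a - 1.0) * (1.0 - u) ** (a - 1.0) / (
            special.beta(a, a) * duration
        )
    return np.where((u > 0) & (u < 1), out, 0.0)


def analytic_volume(t: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Noise-free volume (level) waveform at arbitrary times ``t``."""
    t = np.asarray(t, dtype=float)
    v = np.zeros_like(t)
    for i in range(truth.n_breaths):
        a, b, c = truth.insp_start[i], truth.exp_start[i], truth.exp_end[i]
        amp = truth.amplitude[i]
        p, q = solve_shape_exponents(truth.IE50[i], b - a, c - b)
        sel = (t >= a) & (t < b)
        if sel.any():
            v[sel] = amp * _limb_volume((t[sel] - a) / (b - a), p)
        sel = (t >= b) & (t < c)
        if sel.any():
            v[sel] = amp * (1.0 - _limb_volume((t[sel] - b) / (c - b), q))
    return v


def analytic_flow(t: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """Noise-free flow (rate) waveform, the exact derivative of the volume."""
    t = np.asarray(t, dtype=float)
    f = np.zeros_like(t)
    for i in range(truth.n_breaths):
        a, b, c = truth.insp_start[i], truth.exp_start[i], truth.exp_end[i]
        amp = truth.amplitude[i]
        p, q = solve_shape_exponents(truth.IE50[i], b - a, c - b)
        sel = (t >= a) & (t < b)
        if sel.any():
            f[sel] = amp * _limb_rate((t[sel] - a) / (b - a), p, b - a)
        sel = (t >= b) & (t < c)
        if sel.any():
            f[sel] = -amp * _limb_rate((t[sel] - b) / (c - b), q, c - b)
    return f


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def simulate_breath_train(config: SimConfig, seed: int | None = None) -> GroundTruth:
    """Draw per-breath timings (and artifact insertions) for one recording.

    tI and tE are drawn independently from gamma distributions with the
    configured means and coefficient of variation; markers accumulate from
    t = 0 until the epoch is covered (or ``n_breaths`` reached).
    Deterministic for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    def draw(mean: float) -> float:
        if config.cv_timing == 0:
            return mean
        shape = 1.0 / config.cv_timing**2
        return float(rng.gamma(shape, mean / shape))

    insp, expi, ends, amps, ie50s, art = [], [], [], [], [], []
    t = 0.0
    n_real = 0
    while True:
        tI, tE = draw(config.mean_tI), draw(config.mean_tE)
        mid, end = t + tI, (t + tI) + tE
        insp.append(t)
        expi.append(mid)
        ends.append(end)
        amps.append(config.tidal_amplitude)
        ie50s.append(config.target_IE50)
        art.append(False)
        t = end  # carry the rounded value so junctions match exactly
        n_real += 1
        if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
            # short low-amplitude oscillation (e.g. swallow / glitch)
            insp.append(t)
            expi.append(t + 0.3)
            ends.append(t + 0.6)
            amps.append(0.1 * config.tidal_amplitude)
            ie50s.append(1.0)
            art.append(True)
            t = t + 0.6
        if config.n_breaths is not None:
            if n_real >= config.n_breaths:
                break
        elif t >= config.epoch_length:
            break

    gt = GroundTruth(
        insp_start=np.array(insp),
        exp_start=np.array(expi),
        exp_end=np.array(ends),
        amplitude=np.array(amps),
        IE50=np.array(ie50s),
        is_artifact=np.array(art, dtype=bool),
        inter_device_offset=config.inter_device_offset,
    )
    gt.validate()
    return gt


def _slp_time_warp(
    truth: GroundTruth, sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone piecewise-linear warp knots mapping SLP time -> PNT time.

    Each breath marker is jittered by N(0, sd); the SLP trace then shows the
    breath features at the jittered times.  Jitter is clipped so marker
    ordering (and hence monotonicity of the warp) is preserved.
    """
    knots = np.unique(
        np.concatenate([truth.insp_start, truth.exp_start, truth.exp_end])
    )
    jittered = knots + rng.normal(0.0, sd, size=knots.size)
    gaps = np.diff(knots)
    for i in range(1, jittered.size):  # enforce >= 20 % of the original gap
        min_t = jittered[i - 1] + 0.2 * gaps[i - 1]
        if jittered[i] < min_t:
            jittered[i] = min_t
    return jittered, knots


def render_waveforms(
    truth: GroundTruth, config: SimConfig, seed: int | None = None
) -> PairedRecording:
    """Render the PNT flow/volume and SLP displacement traces for a breath train.

    The PNT flow is the analytic derivative of the breath volume plus white
    noise; the PNT volume is the cumulative-trapezoid integral of that noisy
    flow, exactly as a pneumotachograph acquisition chain produces it.  The
    SLP displacement is ``slp_gain`` times the volume evaluated
    ``inter_device_offset`` seconds earlier (the SLP stream starts late),
    plus sinusoidal baseline drift and independent noise, sampled at the SLP
    rate.
    """
    config.validate()
    truth.validate()
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 0x5EED
    )

    duration = float(truth.exp_end[-1])
    t_pnt = np.arange(0.0, duration, 1.0 / config.fs_pnt)
    flow_clean = analytic_flow(t_pnt, truth)
    flow = flow_clean + rng.normal(0.0, config.noise_sd_pnt, size=t_pnt.size)
    volume = cumulative_trapezoid(flow, dx=1.0 / config.fs_pnt, initial=0.0)

    t_slp = np.arange(0.0, duration, 1.0 / config.fs_slp)
    t_eval = t_slp - config.inter_device_offset
    if config.slp_marker_jitter_sd > 0:
        warped_knots, knots = _slp_time_warp(
            truth, config.slp_marker_jitter_sd, rng
        )
        t_eval = np.interp(t_eval, warped_knots, knots)
    t_eval = np.clip(t_eval, 0.0, duration)
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    slp = (
        config.slp_gain * analytic_volume(t_eval, truth)
        + config.drift_amplitude
        * np.sin(2.0 * np.pi * t_slp / config.drift_period + drift_phase)
        + rng.normal(0.0, config.noise_sd_slp, size=t_slp.size)
    )

    return PairedRecording(
        pnt_flow=Trace(flow, config.fs_pnt, label="pnt_flow", units="L/s"),
        pnt_volume=Trace(volume, config.fs_pnt, label="pnt_volume", units="L"),
        slp_displacement=Trace(slp, config.fs_slp, label="slp_displacement", units="au"),
        truth=truth,
        config=config,
    )


def simulate_recording(config: SimConfig, seed: int | None = None) -> PairedRecording:
    """Convenience: breath train + rendering in one call."""
    truth = simulate_breath_train(config, seed=seed)
    return render_waveforms(truth, config, seed=seed)


def make_cohort(
    n_subjects: int,
    config: SimConfig,
    seed: int | None = None,
    between_subject_cv: float = 0.15,
) -> list[PairedRecording]:
    """Simulate a cohort with between-subject variation around ``config``.

    Each subject's mean timings, IE50, device gain and sync offset are
    jittered around the base configuration; per-subject seeds are spawned
    from the master seed by counter, so cohorts are fully reproducible.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    config.validate()
    master = config.seed if seed is None else seed
    jitter_rng = np.random.default_rng(np.random.SeedSequence([master, 0]))
    out = []
    for i in range(n_subjects):
        z = jitter_rng.normal(size=4)
        off = jitter_rng.normal()
        cv = between_subject_cv
        sub = dataclasses.replace(
            config,
            mean_tI=config.mean_tI * max(0.3, 1.0 + cv * z[0]),
            mean_tE=config.mean_tE * max(0.3, 1.0 + cv * z[1]),
            target_IE50=config.target_IE50 * max(0.3, 1.0 + cv * z[2]),
            slp_gain=config.slp_gain * max(0.3, 1.0 + cv * z[3]),
            inter_device_offset=config.inter_device_offset
            + (0.1 * off if cv > 0 else 0.0),
            seed=int(np.random.SeedSequence([master, 1, i]).generate_state(1)[0] % (2**31)),
        )
        rec = simulate_recording(sub)
        rec.subject_id = f"S{i:02d}"
        out.append(rec)
    return out


# --------------------------------------------------------------------------
# disk round-trip
# --------------------------------------------------------------------------


def write_recording(rec: PairedRecording, directory: str | Path) -> None:
    """Write one recording as three CSV traces plus a JSON sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rec.pnt_flow.to_csv(d / "pnt_flow.csv")
    rec.pnt_volume.to_csv(d / "pnt_volume.csv")
    rec.slp_displacement.to_csv(d / "slp_displacement.csv")
    sidecar = {
        "subject_id": rec.subject_id,
        "config": dataclasses.asdict(rec.config),
        "truth": rec.truth.to_dict(),
    }
    (d / "recording.json").write_text(json.dumps(sidecar, indent=1))


def read_recording(directory: str | Path) -> PairedRecording:
    """Read a recording written by :func:`write_recording`."""
    d = Path(directory)
    sidecar_path = d / "recording.json"
    if not sidecar_path.exists():
        raise DataError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    cfg = SimConfig(**sidecar["config"])
    traces = {}
    for name, units in [
        ("pnt_flow", "L/s"),
        ("pnt_volume", "L"),
        ("slp_displacement", "au"),
    ]:
        path = d / f"{name}.csv"
        if not path.exists():
            raise DataError(f"missing trace file {path}")
        traces[name] = Trace.from_csv(path, label=name, units=units)
    return PairedRecording(
        pnt_flow=traces["pnt_flow"],
        pnt_volume=traces["pnt_volume"],
        slp_displacement=traces["slp_displacement"],
        truth=GroundTruth.from_dict(sidecar["truth"]),
        config=cfg,
        subject_id=sidecar.get("subject_id", "S00"),
    )
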