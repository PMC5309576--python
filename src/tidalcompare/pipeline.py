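"""End-to-end study orchestration: simulate/ingest, preprocess, detect,
compute, compare.

A study mirrors a two-device agreement protocol: one or more measurement
sessions (e.g. ``REST1``, ``REST2``, ``POST_CST``) each record a cohort of
subjects simultaneously with PNT and SLP.  For every subject the pipeline

1. resamples the SLP displacement to the PNT rate (shape-preserving),
2. band-pass filters copies of volume and displacement, estimates the
   inter-device lag from their cross-correlation, and aligns/truncates the
   unfiltered traces,
3. drops a lead-in familiarisation window and keeps the analysis epoch,
4. detects and screens breaths on each device's level trace, pairs them
   one-to-one by inspiratory-start proximity,
5. computes the seven tidal indices per breath and per-subject averages,

and then aggregates breath-level (repeated-measures LOA) and averaged
(simple Bland-Altman) agreement per parameter, plus session comparisons
(REST1 vs REST2 and Combined REST vs POST_CST) with Wald tests of LOA
equality and post-hoc minimum detectable changes.  Identical config + seed
gives identical outputs; a JSON manifest records everything needed to
reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .agreement import (
    DiffSample,
    bland_altman,
    detectable_loa_change,
    distribution_diagnostics,
    loa_repeated,
    percent_diff,
    wald_loa_equality,
)
from .breaths import ScreeningRules, detect_extrema, pair_breaths, screen_breaths
from .errors import ConfigError, DataError
from .parameters import PARAMETERS, average_subject, breath_table, displacement_rate
from .preprocess import (
    align_and_truncate,
    bandpass_zero_phase,
    design_alignment_filter,
    estimate_lag,
    resample_shape_preserving,
)
from .simulate import (
    PairedRecording,
    SimConfig,
    make_cohort,
    read_recording,
)

__all__ = ["SessionSpec", "StudyConfig", "StudyResult", "run_study", "read_cohort",
           "analyze_recording"]


@dataclass
class SessionSpec:
    """One measurement session: a name plus SimConfig field overrides."""

    name: str
    overrides: dict = field(default_factory=dict)


@dataclass
class StudyConfig:
    """Settings for a full simulated (or ingested) agreement study."""

    n_subjects: int = 21
    base_sim: SimConfig = field(default_factory=SimConfig)
    sessions: list[SessionSpec] = field(
        default_factory=lambda: [SessionSpec("REST1"), SessionSpec("REST2")]
    )
    input_directory: str | None = None  # if set, read instead of simulate
    lead_in_s: float = 15.0  # familiarisation window, discarded
    epoch_s: float = 45.0  # analysis epoch
    screening: ScreeningRules = field(default_factory=ScreeningRules)
    derivative_smoothing_s: float = 0.2
    pairing_tolerance_s: float = 0.5
    max_lag_s: float = 5.0
    lag_override_s: float | None = None  # manual synchronisation fallback
    alpha: float = 0.05
    power: float = 0.80
    loa_multiplier: float = 1.96
    between_subject_cv: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if not self.sessions:
            raise ConfigError("at least one session is required")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.epoch_s <= 0 or self.lead_in_s < 0:
            raise ConfigError("epoch_s must be positive, lead_in_s non-negative")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ConfigError("alpha and power must lie in (0, 1)")
        self.base_sim.validate()

    def session_sim(self, spec: SessionSpec, seed: int) -> SimConfig:
        sim = dataclasses.replace(self.base_sim, **spec.overrides)
        # simulate the lead-in too so it can be discarded downstream
        sim = dataclasses.replace(
            sim, epoch_length=self.lead_in_s + self.epoch_s, seed=seed
        )
        return sim


@dataclass
class StudyResult:
    """Tables produced by :func:`run_study`."""

    breath_pairs: pd.DataFrame  # long: one row per paired breath per parameter
    subject_averages: pd.DataFrame  # per subject/session/device parameter means
    agreement_breath: pd.DataFrame  # RM-LOA per parameter per session
    agreement_averaged: pd.DataFrame  # simple BA per parameter per session
    session_comparisons: pd.DataFrame  # Wald + power per parameter per contrast
    subject_log: pd.DataFrame  # lag, breath counts, exclusions per subject
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "breath_pairs",
            "subject_averages",
            "agreement_breath",
            "agreement_averaged",
            "session_comparisons",
            "subject_log",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))


# --------------------------------------------------------------------------


def analyze_recording(
    rec: PairedRecording, config: StudyConfig, session: str = ""
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Process one paired recording into per-breath paired parameter rows.

    Returns the paired-breath table (wide: one row per breath pair with
    both devices' parameters), the per-device breath tables, and a log dict
    (estimated lag, counts, exclusions).
    """
    fs = rec.config.fs_pnt
    slp_rs = resample_shape_preserving(rec.slp_displacement, fs)

    spec = design_alignment_filter(fs)
    vol_f = bandpass_zero_phase(rec.pnt_volume, spec)
    slp_f = bandpass_zero_phase(slp_rs, spec)
    if config.lag_override_s is not None:
        lag, peak, flagged, method = config.lag_override_s, np.nan, False, "manual"
    else:
        ar = estimate_lag(vol_f, slp_f, max_lag=config.max_lag_s)
        lag, peak, flagged, method = ar.lag, ar.peak_correlation, ar.flagged, ar.method

    vol_a, slp_a = align_and_truncate(rec.pnt_volume, slp_rs, lag)
    flow_a, _ = align_and_truncate(rec.pnt_flow, slp_rs, lag)

    t_hi = min(config.lead_in_s + config.epoch_s, vol_a.t0 + vol_a.duration)
    vol_a = vol_a.crop(config.lead_in_s, t_hi)
    slp_a = slp_a.crop(config.lead_in_s, t_hi)
    flow_a = flow_a.crop(config.lead_in_s, t_hi)

    m_pnt = screen_breaths(
        detect_extrema(vol_a, config.derivative_smoothing_s), config.screening
    )
    m_slp = screen_breaths(
        detect_extrema(slp_a, config.derivative_smoothing_s), config.screening
    )
    pairing = pair_breaths(m_pnt, m_slp, tolerance=config.pairing_tolerance_s)

    tables = {}
    if m_pnt.n_breaths:
        tables["PNT"] = breath_table(
            m_pnt, vol_a, flow_a, device="PNT",
            subject=rec.subject_id, session=session,
        )
    if m_slp.n_breaths:
        tables["SLP"] = breath_table(
            m_slp, slp_a, displacement_rate(slp_a), device="SLP",
            subject=rec.subject_id, session=session,
        )

    rows = []
    for ia, ib in pairing.pairs:
        row = {"subject": rec.subject_id, "session": session, "pair_id": len(rows)}
        for par in PARAMETERS:
            row[f"{par}_PNT"] = tables["PNT"].iloc[ia][par]
            row[f"{par}_SLP"] = tables["SLP"].iloc[ib][par]
        rows.append(row)
    paired = pd.DataFrame(rows)

    log = {
        "subject": rec.subject_id,
        "session": session,
        "lag_s": float(lag),
        "peak_correlation": float(peak) if np.isfinite(peak) else np.nan,
        "alignment_method": method,
        "alignment_flagged": bool(flagged),
        "n_breaths_pnt": int(m_pnt.n_breaths),
        "n_breaths_slp": int(m_slp.n_breaths),
        "n_paired": pairing.n_pairs,
        "n_unpaired_pnt": len(pairing.unpaired_a),
        "n_unpaired_slp": len(pairing.unpaired_b),
        "exclusions_pnt": "; ".join(r for _, r in m_pnt.exclusions),
        "exclusions_slp": "; ".join(r for _, r in m_slp.exclusions),
    }
    return paired, tables, log


def _diff_sample(paired: pd.DataFrame, par: str, session: str) -> DiffSample:
    sel = paired if not session else paired[paired["session"].isin(session.split("+"))]
    ref = sel[f"{par}_PNT"].to_numpy()
    test = sel[f"{par}_SLP"].to_numpy()
    subj = sel["subject"].to_numpy()
    ds = DiffSample(ref, test, subj, parameter=par, session=session)
    return ds.dropna_pairs()


def _averaged_sample(
    averages: pd.DataFrame, par: str, session: str
) -> DiffSample:
    sel = averages[averages["session"].isin(session.split("+"))]
    wide = sel.pivot_table(
        index=["subject", "session"], columns="device", values=par
    ).dropna()
    return DiffSample(
        wide["PNT"].to_numpy(), wide["SLP"].to_numpy(),
        parameter=par, session=session,
    )


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full study and return its result tables."""
    config.validate()

    all_paired, all_avg, logs = [], [], []
    session_names = [s.name for s in config.sessions]
    for si, spec in enumerate(config.sessions):
        if config.input_directory is not None:
            cohort = read_cohort(Path(config.input_directory) / spec.name)
        else:
            seed = int(
                np.random.SeedSequence([config.seed, 7, si]).generate_state(1)[0]
                % (2**31)
            )
            sim = config.session_sim(spec, seed)
            cohort = make_cohort(
                config.n_subjects, sim, seed=seed,
                between_subject_cv=config.between_subject_cv,
            )
        for rec in cohort:
            paired, tables, log = analyze_recording(rec, config, session=spec.name)
            if not paired.empty:
                all_paired.append(paired)
            for tb in tables.values():
                if not tb.empty:
                    all_avg.append(average_subject(tb))
            logs.append(log)

    breath_pairs = (
        pd.concat(all_paired, ignore_index=True) if all_paired else pd.DataFrame()
    )
    subject_averages = (
        pd.concat(all_avg, ignore_index=True) if all_avg else pd.DataFrame()
    )
    subject_log = pd.DataFrame(logs)

    # ---------------- per-session agreement tables
    rows_b, rows_a = [], []
    fits_b, fits_a = {}, {}
    contrasts = _contrasts(session_names)
    fit_sessions = list(session_names) + [
        c for pair in contrasts for c in pair if "+" in c
    ]
    for sess in dict.fromkeys(fit_sessions):
        for par in PARAMETERS:
            ds = _diff_sample(breath_pairs, par, sess)
            if ds.n >= 2:
                rm = loa_repeated(ds, config.loa_multiplier)
                fits_b[(sess, par)] = rm
                _, pct = percent_diff(ds, config.loa_multiplier)
                diag = distribution_diagnostics(ds) if ds.n >= 4 else None
                rows_b.append(
                    {
                        "session": sess, "parameter": par, "n_breaths": rm.n_total,
                        "n_subjects": rm.n_subjects, "bias": rm.bias,
                        "loa_lower": rm.loa_lower, "loa_upper": rm.loa_upper,
                        "sd_total": rm.sd_total,
                        "sigma2_between": rm.sigma2_between,
                        "sigma2_within": rm.sigma2_within,
                        "pct_bias": pct.bias, "pct_loa_lower": pct.loa_lower,
                        "pct_loa_upper": pct.loa_upper,
                        "kurtosis": diag.kurtosis if diag else np.nan,
                    }
                )
            ds_a = _averaged_sample(subject_averages, par, sess)
            if ds_a.n >= 2:
                ba = bland_altman(ds_a, config.loa_multiplier)
                fits_a[(sess, par)] = ba
                _, pct = percent_diff(ds_a, config.loa_multiplier)
                rows_a.append(
                    {
                        "session": sess, "parameter": par, "n_subjects": ba.n,
                        "bias": ba.bias, "loa_lower": ba.loa_lower,
                        "loa_upper": ba.loa_upper, "sd": ba.sd,
                        "pearson_r": ba.pearson_r,
                        "pct_bias": pct.bias, "pct_loa_lower": pct.loa_lower,
                        "pct_loa_upper": pct.loa_upper,
                    }
                )

    # ---------------- session contrasts (Wald + power)
    rows_c = []
    for g1name, g2name in contrasts:
        for par in PARAMETERS:
            for level, fits in (("breath", fits_b), ("averaged", fits_a)):
                f1, f2 = fits.get((g1name, par)), fits.get((g2name, par))
                if f1 is None or f2 is None:
                    continue
                w = wald_loa_equality(f1, f2, alpha=config.alpha)
                pw = detectable_loa_change(f1, f2, config.power, config.alpha)
                rows_c.append(
                    {
                        "contrast": f"{g1name} vs {g2name}", "level": level,
                        "parameter": par,
                        "p_lower": w.p_lower, "p_upper": w.p_upper,
                        "p_joint": w.p_joint,
                        "detectable_loa_change": pw.delta_min,
                    }
                )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "sessions": session_names,
        "n_subjects": config.n_subjects,
        "config_hash": _config_hash(config),
        "loa_multiplier": config.loa_multiplier,
        "alpha": config.alpha,
        "power": config.power,
    }
    return StudyResult(
        breath_pairs=breath_pairs,
        subject_averages=subject_averages,
        agreement_breath=pd.DataFrame(rows_b),
        agreement_averaged=pd.DataFrame(rows_a),
        session_comparisons=pd.DataFrame(rows_c),
        subject_log=subject_log,
        manifest=manifest,
    )


def _contrasts(session_names: list[str]) -> list[tuple[str, str]]:
    """Standard contrasts: REST1 vs REST2; Combined REST vs POST_CST."""
    out = []
    if "REST1" in session_names and "REST2" in session_names:
        out.append(("REST1", "REST2"))
        if "POST_CST" in session_names:
            out.append(("REST1+REST2", "POST_CST"))
    elif len(session_names) == 2:
        out.append((session_names[0], session_names[1]))
    return out


def _config_hash(config: StudyConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_cohort(directory: str | Path) -> list[PairedRecording]:
    """Read every per-subject recording directory under ``directory``."""
    d = Path(directory)
    if not d.is_dir():
        raise DataError(f"cohort directory {d} does not exist")
    subdirs = sorted(p for p in d.iterdir() if p.is_dir())
    if not subdirs:
        raise DataError(f"no subject directories under {d}")
    return [read_recording(p) for p in subdirs]
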