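"""Bland-Altman agreement statistics for two-device method comparison.

The reference device (PNT) plays the gold standard: differences are
``d = x_SLP - x_PNT`` and Bland-Altman plots put the PNT value on the
x-axis rather than the pair mean.  Three layers of inference are provided:

* simple Bland-Altman bias and 95 % limits of agreement (LOA),
  ``bias +/- 1.96 * SD`` of the differences, for subject-averaged data;
* a repeated-measures variant for breath-level data, where a one-way
  random-subject-effects decomposition splits the difference variance into
  between-subject and within-subject components and the LOA use the total
  SD ``sqrt(sigma2_b + sigma2_w)``;
* Wald tests of LOA equality between sessions, a post-hoc minimum
  detectable LOA change at given power, and distribution diagnostics
  (Pearson kurtosis, normality, optional log-transform retest).

Standard errors of a fitted limit ``L = bias +/- z * SD`` use the delta
method, ``Var(L) = Var(bias) + z^2 * Var(SD)`` with the normal-theory
approximation ``Var(SD) = sigma^2 / (2 m)``; ``m`` is the subject count for
averaged data and a variance-component-adjusted effective size for
breath-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "LOA_MULTIPLIER",
    "DiffSample",
    "BAResult",
    "RMResult",
    "WaldResult",
    "PowerResult",
    "Diagnostics",
    "bland_altman",
    "percent_diff",
    "loa_repeated",
    "wald_loa_equality",
    "detectable_loa_change",
    "distribution_diagnostics",
    "bland_altman_plot",
]

LOA_MULTIPLIER = 1.96  # 95 % limits of agreement


@dataclass
class DiffSample:
    """Paired reference/test values and their differences.

    One element per unit — a breath (with a ``subject`` grouping key) or a
    subject (averaged data, no grouping).
    """

    reference: np.ndarray  # x_PNT
    test: np.ndarray  # x_SLP
    subject: np.ndarray | None = None
    parameter: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if self.reference.shape != self.test.shape:
            raise DataError("reference and test must have matching lengths")
        if self.subject is not None:
            self.subject = np.asarray(self.subject)
            if self.subject.shape != self.reference.shape:
                raise DataError("subject labels must match the sample length")
        # missing values (e.g. undefined IE50) are allowed at construction;
        # dropna_pairs() removes them and the estimators reject any leftovers

    @property
    def differences(self) -> np.ndarray:
        """d = test - reference (SLP - PNT)."""
        return self.test - self.reference

    @property
    def n(self) -> int:
        return self.reference.size

    def dropna_pairs(self) -> "DiffSample":
        """Remove units where either value is missing (e.g. undefined IE50)."""
        ok = np.isfinite(self.reference) & np.isfinite(self.test)
        return DiffSample(
            self.reference[ok],
            self.test[ok],
            None if self.subject is None else self.subject[ok],
            self.parameter,
            self.session,
        )


@dataclass
class BAResult:
    """Simple Bland-Altman bias and limits of agreement."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float
    n: int
    pearson_r: float
    se_bias: float
    se_limit: float
    multiplier: float = LOA_MULTIPLIER

    @property
    def limit_covariance(self) -> float:
        """Cov(lower, upper) under the delta method."""
        var_sd = self.se_bias**2 / 2.0  # Var(SD) = sigma^2/(2m) = Var(bias)/2
        return self.se_bias**2 - self.multiplier**2 * var_sd


@dataclass
class RMResult:
    """Repeated-measures (random subject effect) bias and LOA."""

    bias: float
    sigma2_between: float
    sigma2_within: float
    sd_total: float
    loa_lower: float
    loa_upper: float
    n_subjects: int
    n_total: int
    se_bias: float
    se_limit: float
    multiplier: float = LOA_MULTIPLIER
    fallback_simple: bool = False

    @property
    def limit_covariance(self) -> float:
        var_sd = self.se_bias**2 / 2.0
        return self.se_bias**2 - self.multiplier**2 * var_sd


@dataclass
class WaldResult:
    """Per-limit (and joint) Wald tests of LOA equality between two groups."""

    z_lower: float
    z_upper: float
    p_lower: float
    p_upper: float
    p_joint: float
    alpha: float = 0.05

    @property
    def reject_lower(self) -> bool:
        return self.p_lower < self.alpha

    @property
    def reject_upper(self) -> bool:
        return self.p_upper < self.alpha


@dataclass
class PowerResult:
    """Minimum detectable change in a limit of agreement."""

    delta_min: float
    power: float
    alpha: float


@dataclass
class Diagnostics:
    """Distribution diagnostics for a difference sample."""

    kurtosis: float  # Pearson convention: normal = 3
    qq_rms: float  # RMS deviation of standardized sample from normal quantiles
    shapiro_p: float
    log_retested: bool
    log_kurtosis: float = np.nan
    log_qq_rms: float = np.nan
    log_skip_reason: str = ""


# --------------------------------------------------------------------------


def _se_limit(se_bias: float, multiplier: float) -> float:
    # Var(L) = Var(bias) + z^2 Var(SD), Var(SD) = sigma^2/(2m) = Var(bias)/2
    return float(se_bias * np.sqrt(1.0 + multiplier**2 / 2.0))


def bland_altman(
    sample: DiffSample, multiplier: float = LOA_MULTIPLIER
) -> BAResult:
    """Bias, 95 % LOA and Pearson r for a paired sample.

    The SD uses the n-1 denominator.  Pearson r between reference and test
    is NaN-safe for constant inputs.
    """
    d = sample.differences
    if d.size < 2:
        raise DataError("Bland-Altman needs at least two paired observations")
    if not np.all(np.isfinite(d)):
        raise DataError("differences contain non-finite values; drop missing pairs first")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.ptp(sample.reference) == 0 or np.ptp(sample.test) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(sample.reference, sample.test)[0, 1])
    se_bias = sd / np.sqrt(d.size)
    return BAResult(
        bias=bias,
        sd=sd,
        loa_lower=bias - multiplier * sd,
        loa_upper=bias + multiplier * sd,
        n=int(d.size),
        pearson_r=r,
        se_bias=float(se_bias),
        se_limit=_se_limit(se_bias, multiplier),
        multiplier=multiplier,
    )


def percent_diff(
    sample: DiffSample, multiplier: float = LOA_MULTIPLIER
) -> tuple[np.ndarray, BAResult]:
    """Per-unit percentage differences 100 * (test - ref) / ref and their LOA.

    Raises for any zero reference value (the percentage is undefined there).
    """
    if np.any(sample.reference == 0):
        raise DataError("percentage difference undefined for zero reference values")
    pct = 100.0 * sample.differences / sample.reference
    pct_sample = DiffSample(
        reference=np.zeros_like(pct),
        test=pct,
        subject=sample.subject,
        parameter=sample.parameter + " (%)",
        session=sample.session,
    )
    res = bland_altman(pct_sample, multiplier)
    # Pearson r of the raw pair is the meaningful correlation to report
    with np.errstate(invalid="ignore"):
        if np.ptp(sample.reference) and np.ptp(sample.test):
            res.pearson_r = float(
                np.corrcoef(sample.reference, sample.test)[0, 1]
            )
        else:
            res.pearson_r = np.nan
    return pct, res


def loa_repeated(
    sample: DiffSample, multiplier: float = LOA_MULTIPLIER
) -> RMResult:
    """Random-subject-effects bias and LOA for breath-level differences.

    The variance of d is split into between-subject (sigma2_b) and
    within-subject (sigma2_w) components with the one-way random-effects
    ANOVA (method-of-moments) estimator, unbalanced-aware; a negative
    between-subject estimate is truncated to zero.  LOA are
    ``bias +/- multiplier * sqrt(sigma2_b + sigma2_w)``.  With a single
    subject the simple Bland-Altman result is returned with a flag.
    """
    if sample.subject is None:
        raise DataError("loa_repeated needs subject grouping labels")
    d = sample.differences
    subjects, counts = np.unique(sample.subject, return_counts=True)
    k, N = subjects.size, d.size
    if k < 2 or N == k:
        # single subject (or one breath each): fall back to pooled BA
        ba = bland_altman(sample, multiplier)
        return RMResult(
            bias=ba.bias,
            sigma2_between=0.0,
            sigma2_within=ba.sd**2,
            sd_total=ba.sd,
            loa_lower=ba.loa_lower,
            loa_upper=ba.loa_upper,
            n_subjects=k,
            n_total=N,
            se_bias=ba.se_bias,
            se_limit=ba.se_limit,
            multiplier=multiplier,
            fallback_simple=True,
        )

    grand = float(d.mean())
    group_means = np.array([d[sample.subject == s].mean() for s in subjects])
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(
        sum(
            np.sum((d[sample.subject == s] - gm) ** 2)
            for s, gm in zip(subjects, group_means)
        )
    )
    msw = ss_within / (N - k)
    msb = ss_between / (k - 1)
    n0 = (N - np.sum(counts**2) / N) / (k - 1)  # effective per-subject count
    sigma2_w = msw
    sigma2_b = max(0.0, (msb - msw) / n0)
    sd_total = float(np.sqrt(sigma2_b + sigma2_w))

    var_bias = sigma2_b / k + sigma2_w / N
    se_bias = float(np.sqrt(var_bias))
    return RMResult(
        bias=grand,
        sigma2_between=sigma2_b,
        sigma2_within=sigma2_w,
        sd_total=sd_total,
        loa_lower=grand - multiplier * sd_total,
        loa_upper=grand + multiplier * sd_total,
        n_subjects=int(k),
        n_total=int(N),
        se_bias=se_bias,
        se_limit=_se_limit(se_bias, multiplier),
        multiplier=multiplier,
    )


def wald_loa_equality(
    g1: BAResult | RMResult, g2: BAResult | RMResult, alpha: float = 0.05
) -> WaldResult:
    """Wald z-tests of lower- and upper-LOA equality between two groups.

    Per-limit two-sided p-values are reported (as a ``[lower, upper]``
    pair), plus a joint 2-df chi-square p-value accounting for the
    within-group covariance of the two limits.
    """
    se2 = g1.se_limit**2 + g2.se_limit**2
    if se2 == 0:
        raise DataError("degenerate zero-variance groups; Wald test undefined")
    dl = g1.loa_lower - g2.loa_lower
    du = g1.loa_upper - g2.loa_upper
    se = np.sqrt(se2)
    z_lower = float(dl / se)
    z_upper = float(du / se)
    p_lower = float(2.0 * stats.norm.sf(abs(z_lower)))
    p_upper = float(2.0 * stats.norm.sf(abs(z_upper)))

    cov = g1.limit_covariance + g2.limit_covariance
    sigma = np.array([[se2, cov], [cov, se2]])
    delta = np.array([dl, du])
    try:
        chi2 = float(delta @ np.linalg.solve(sigma, delta))
        p_joint = float(stats.chi2.sf(chi2, df=2))
    except np.linalg.LinAlgError:  # pragma: no cover - singular only if se2==cov
        p_joint = np.nan
    return WaldResult(
        z_lower=z_lower,
        z_upper=z_upper,
        p_lower=p_lower,
        p_upper=p_upper,
        p_joint=p_joint,
        alpha=alpha,
    )


def detectable_loa_change(
    g1: BAResult | RMResult,
    g2: BAResult | RMResult,
    power: float = 0.80,
    alpha: float = 0.05,
) -> PowerResult:
    """Minimum LOA shift detectable between two fitted groups.

    Post-hoc power analysis: with limit standard errors SE1, SE2, a true
    shift of ``(z_{1-alpha/2} + z_power) * sqrt(SE1^2 + SE2^2)`` in either
    limit is detected by the Wald test with the requested probability.
    """
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise DataError("power and alpha must lie in (0, 1)")
    se = np.sqrt(g1.se_limit**2 + g2.se_limit**2)
    delta = float((stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)) * se)
    return PowerResult(delta_min=delta, power=power, alpha=alpha)


def distribution_diagnostics(
    sample: DiffSample, log_retest: bool = True
) -> Diagnostics:
    """Kurtosis and normality summaries of the differences.

    Kurtosis follows the Pearson convention (normal = 3).  The QQ summary is
    the RMS deviation of the sorted standardized differences from normal
    plotting-position quantiles.  When requested and all paired values are
    positive, the diagnostics are recomputed on differences of logs.
    """
    d = sample.differences
    if d.size < 4:
        raise DataError("need at least 4 observations for diagnostics")
    if np.ptp(d) == 0:
        raise DataError("constant sample; diagnostics undefined")

    def _qq_rms(x: np.ndarray) -> float:
        z = (np.sort(x) - x.mean()) / x.std(ddof=1)
        q = stats.norm.ppf((np.arange(1, x.size + 1) - 0.5) / x.size)
        return float(np.sqrt(np.mean((z - q) ** 2)))

    kurt = float(stats.kurtosis(d, fisher=False, bias=False))
    shapiro_p = float(stats.shapiro(d).pvalue) if d.size <= 5000 else float(
        stats.shapiro(np.random.default_rng(0).choice(d, 5000, replace=False)).pvalue
    )
    diag = Diagnostics(
        kurtosis=kurt,
        qq_rms=_qq_rms(d),
        shapiro_p=shapiro_p,
        log_retested=False,
    )
    if log_retest:
        if np.all(sample.reference > 0) and np.all(sample.test > 0):
            dl = np.log(sample.test) - np.log(sample.reference)
            if np.ptp(dl) > 0:
                diag.log_retested = True
                diag.log_kurtosis = float(stats.kurtosis(dl, fisher=False, bias=False))
                diag.log_qq_rms = _qq_rms(dl)
            else:
                diag.log_skip_reason = "log-differences constant"
        else:
            diag.log_skip_reason = "non-positive values; log transform skipped"
    return diag


def bland_altman_plot(
    sample: DiffSample, result: BAResult | RMResult, path: str | None = None
):
    """Bland-Altman chart with the reference (PNT) value on the x-axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(sample.reference, sample.differences, s=12, alpha=0.7)
    for y, style, lab in [
        (result.bias, "-", f"m = {result.bias:.3g}"),
        (result.loa_lower, "--", f"LOA {result.loa_lower:.3g}"),
        (result.loa_upper, "--", f"LOA {result.loa_upper:.3g}"),
    ]:
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.annotate(lab, (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel(f"{sample.parameter} (PNT)")
    ax.set_ylabel("SLP - PNT")
    ax.set_title(sample.parameter or "difference")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
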