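"""Reliability and agreement between pharmacy and ward consumption series.

Two complementary views of method agreement:

* the intraclass correlation coefficient (ICC) from a two-way ANOVA with
  subjects (ward x agent x interval cells) random and method fixed —
  ICC = sigma_s^2 / (sigma_s^2 + sigma_e^2), the share of total variance
  attributable to real between-cell differences rather than method
  disagreement; 0.7 is the conventional threshold of sufficient reliability;

* Bland-Altman limits of agreement — mean and standard deviation of the
  per-cell differences (pharmacy - ward), with limits mean +/- 1.96 sd, and
  a conversion of those per-registration limits into a DDD use range around
  the mean interval-total use.

The default ICC variant is two-way mixed-effects, consistency, single
measures (ICC(3,1) in the Shrout-Fleiss taxonomy): systematic level shifts
between the two methods are the object of the separate Bland-Altman
analysis, so they are excluded from the reliability ratio.  An
absolute-agreement variant (ICC(2,1)) is available behind a switch.
Confidence intervals use exact F-distribution bounds transformed through the
ICC formula (Shrout & Fleiss for consistency; McGraw & Wong for absolute
agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .accounting import ConsumptionSeries, retained_weeks
from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

RELIABILITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Mean squares of the two-way (subjects x methods) layout, k = 2."""

    ms_subjects: float
    ms_error: float
    ms_methods: float
    n_subjects: int
    k: int = 2
    degenerate: bool = False


@dataclass(frozen=True)
class ICCResult:
    icc: float | None
    ci_low: float | None
    ci_high: float | None
    n_subjects: int
    sigma_s2: float | None
    sigma_e2: float | None
    ms_subjects: float
    ms_error: float
    variant: str = "consistency"
    reason: str | None = None  # set when icc is undefined

    @property
    def defined(self) -> bool:
        return self.icc is not None


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_low: float
    loa_high: float
    n_pairs: int
    mean_of_means: float


@dataclass(frozen=True)
class UseRangeResult:
    mean_interval_use: float
    range_low: float
    range_high: float
    percent_low: float
    percent_high: float


def _pair_matrix(pairs) -> np.ndarray:
    """Accept a PairedRegistration frame or an (n, 2) array-like."""
    if isinstance(pairs, pd.DataFrame):
        x = pairs[["pharmacy_ddd", "ward_ddd"]].to_numpy(dtype=float)
    else:
        x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValidationError(
            f"expected paired (n, 2) measurements, got shape {x.shape}"
        )
    if not np.isfinite(x).all():
        raise ValidationError("paired registrations contain non-finite values")
    return x


def anova_mean_squares(pairs) -> AnovaMeanSquares:
    """Two-way ANOVA mean squares for n subjects x 2 methods.

    Subjects are the paired registrations; the two methods (pharmacy, ward)
    are the repeated measurements.  Computed from explicit sums of squares:

        SS_subjects = k * sum_i (s_i - m)^2          df = n - 1
        SS_methods  = n * sum_j (m_j - m)^2          df = k - 1
        SS_error    = SS_total - SS_subjects - SS_methods
                                                     df = (n-1)(k-1)
    """
    x = _pair_matrix(pairs)
    n, k = x.shape
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 paired registrations, got {n}"
        )
    grand = x.mean()
    subj_means = x.mean(axis=1)
    meth_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())
    ss_methods = float(n * ((meth_means - grand) ** 2).sum())
    ss_error = max(ss_total - ss_subjects - ss_methods, 0.0)
    return AnovaMeanSquares(
        ms_subjects=ss_subjects / (n - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        ms_methods=ss_methods / (k - 1),
        n_subjects=n,
        k=k,
        degenerate=(ss_total == 0.0),
    )


def icc_from_anova(
    ms: AnovaMeanSquares,
    variant: str = "consistency",
    confidence: float = 0.95,
) -> ICCResult:
    """Single-measures ICC with exact-F confidence bounds.

    Consistency (default): ICC(3,1) = (MSs - MSe) / (MSs + (k-1) MSe).
    Absolute agreement:    ICC(2,1) = (MSs - MSe) /
                           (MSs + (k-1) MSe + k (MSm - MSe) / n).
    """
    if variant not in ("consistency", "absolute"):
        raise ValidationError(f"unknown ICC variant {variant!r}")
    n, k = ms.n_subjects, ms.k
    if ms.degenerate:
        return ICCResult(
            icc=None, ci_low=None, ci_high=None, n_subjects=n,
            sigma_s2=None, sigma_e2=None,
            ms_subjects=ms.ms_subjects, ms_error=ms.ms_error,
            variant=variant, reason="zero total variance",
        )
    alpha = 1.0 - confidence
    sigma_e2 = ms.ms_error
    sigma_s2 = max((ms.ms_subjects - ms.ms_error) / k, 0.0)

    if variant == "consistency":
        if ms.ms_error == 0.0:
            # perfect within-subject consistency
            icc, ci = 1.0, (1.0, 1.0)
        else:
            icc = (ms.ms_subjects - ms.ms_error) / (
                ms.ms_subjects + (k - 1) * ms.ms_error
            )
            f_obs = ms.ms_subjects / ms.ms_error
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        denom = (
            ms.ms_subjects
            + (k - 1) * ms.ms_error
            + k * (ms.ms_methods - ms.ms_error) / n
        )
        if denom == 0.0:
            icc, ci = 1.0, (1.0, 1.0)
        else:
            icc = (ms.ms_subjects - ms.ms_error) / denom
            ci = _absolute_ci(ms, icc, alpha)

    return ICCResult(
        icc=float(icc),
        ci_low=float(min(ci)),
        ci_high=float(max(ci)),
        n_subjects=n,
        sigma_s2=float(sigma_s2),
        sigma_e2=float(sigma_e2),
        ms_subjects=ms.ms_subjects,
        ms_error=ms.ms_error,
        variant=variant,
    )


def _absolute_ci(ms: AnovaMeanSquares, icc: float,
                 alpha: float) -> tuple[float, float]:
    """McGraw & Wong F bounds with Satterthwaite df for ICC(2,1)."""
    n, k = ms.n_subjects, ms.k
    if ms.ms_error == 0.0 and ms.ms_methods == 0.0:
        return (1.0, 1.0)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
    if not math.isfinite(a):
        return (1.0, 1.0)
    num = (a * ms.ms_methods + b * ms.ms_error) ** 2
    den = (
        (a * ms.ms_methods) ** 2 / (k - 1)
        + (b * ms.ms_error) ** 2 / ((n - 1) * (k - 1))
    )
    v = num / den if den > 0 else 1.0
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n * (ms.ms_subjects - f_low * ms.ms_error)
        / (
            f_low * (k * ms.ms_methods + (k * n - k - n) * ms.ms_error)
            + n * ms.ms_subjects
        )
    )
    upper = (
        n * (f_up * ms.ms_subjects - ms.ms_error)
        / (
            k * ms.ms_methods
            + (k * n - k - n) * ms.ms_error
            + n * f_up * ms.ms_subjects
        )
    )
    return (lower, upper)


def icc(pairs, variant: str = "consistency",
        confidence: float = 0.95) -> ICCResult:
    """Convenience wrapper: ANOVA mean squares then :func:`icc_from_anova`."""
    return icc_from_anova(anova_mean_squares(pairs), variant=variant,
                          confidence=confidence)


def bland_altman(pairs) -> BlandAltmanResult:
    """Mean difference (pharmacy - ward) and 1.96-sd limits of agreement.

    The sd uses the n-1 denominator; 1.96 is used verbatim, not a t
    quantile, per the Bland-Altman convention.
    """
    x = _pair_matrix(pairs)
    n = x.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {n}")
    d = x[:, 0] - x[:, 1]
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_low=mean_d - 1.96 * sd_d,
        loa_high=mean_d + 1.96 * sd_d,
        n_pairs=n,
        mean_of_means=float(x.mean(axis=1).mean()),
    )


def bland_altman_plot_data(pairs) -> pd.DataFrame:
    """Per-pair averages and differences for a Bland-Altman plot."""
    x = _pair_matrix(pairs)
    return pd.DataFrame(
        {"average": x.mean(axis=1), "difference": x[:, 0] - x[:, 1]}
    )


def mean_interval_use_from_totals(
    pharmacy_total: float,
    ward_total: float,
    n_intervals: int,
) -> float:
    """Average of the two methods' grand totals, per registration interval."""
    if n_intervals <= 0:
        raise ConfigurationError(
            f"number of intervals must be positive, got {n_intervals}"
        )
    return ((pharmacy_total + ward_total) / 2.0) / n_intervals


def mean_interval_use(
    pharm: ConsumptionSeries,
    ward: ConsumptionSeries,
    k: int,
    omit_weeks: Iterable[int] = (),
) -> float:
    """Mean DDD use per k-week interval, averaged over the two methods."""
    weeks = retained_weeks(pharm.n_weeks, omit_weeks)
    if len(weeks) % k != 0:
        raise ConfigurationError(
            f"{len(weeks)} retained weeks not divisible by k={k}"
        )
    n_intervals = len(weeks) // k
    p_total = float(pharm.data[pharm.data["week"].isin(weeks)]["ddd"].sum())
    w_total = float(ward.data[ward.data["week"].isin(weeks)]["ddd"].sum())
    return mean_interval_use_from_totals(p_total, w_total, n_intervals)


def loa_to_use_range(
    ba: BlandAltmanResult,
    n_cells_per_interval: int,
    mean_interval_use: float,
) -> UseRangeResult:
    """Convert per-registration limits of agreement to an interval-level DDD
    use range around the mean interval use.

    The per-pair limits scale linearly with the number of ward x agent cells
    summed into one interval total.
    """
    if n_cells_per_interval < 1:
        raise ValidationError(
            f"n_cells_per_interval must be >= 1, got {n_cells_per_interval}"
        )
    if not mean_interval_use > 0:
        raise ValidationError(
            f"mean_interval_use must be > 0, got {mean_interval_use}"
        )
    lo = mean_interval_use + n_cells_per_interval * ba.loa_low
    hi = mean_interval_use + n_cells_per_interval * ba.loa_high
    return UseRangeResult(
        mean_interval_use=mean_interval_use,
        range_low=lo,
        range_high=hi,
        percent_low=100.0 * abs(lo - mean_interval_use) / mean_interval_use,
        percent_high=100.0 * abs(hi - mean_interval_use) / mean_interval_use,
    )


def reliability_verdict(
    result: ICCResult,
    threshold: float = RELIABILITY_THRESHOLD,
) -> tuple[bool | None, str]:
    """Sufficient reliability iff ICC >= threshold (inclusive).

    Returns (verdict, label); verdict is None and the label reads
    "indeterminate" when the ICC is undefined.
    """
    if not result.defined:
        return None, f"indeterminate ({result.reason})"
    verdict = result.icc >= threshold
    word = "sufficient" if verdict else "insufficient"
    return verdict, (
        f"{word} (ICC {result.icc:.2f}, 95% CI "
        f"{result.ci_low:.2f}-{result.ci_high:.2f}, threshold {threshold})"
    )
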