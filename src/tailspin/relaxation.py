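"""Estimation of R1, R2, hnNOE, and R2/R1 with errors from peak tables.

Decay series are fit to a single-exponential without offset, I(t) =
I0*exp(-R*t), by unweighted nonlinear least squares.  Parameter errors come
from the covariance matrix scaled by the residual variance (n-2 denominator);
a jackknife (leave-one-point-out) error is available as a robustness
cross-check.  hnNOE is the saturated/reference peak-height ratio with the
spectral noise propagated; R2/R1 propagates the two fit errors in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .sequence import DEFAULT_RULES, ObservabilityRules, TAIL_LENGTH


class AnalysisError(ValueError):
    """Invalid analysis input."""


class EmptyRegionError(AnalysisError):
    """A residue span contains no observed values."""


@dataclass(frozen=True)
class RelaxationSeries:
    """One residue/peak's (delay, intensity) measurements for one experiment."""

    residue: int
    peak_id: int
    delays: np.ndarray
    intensities: np.ndarray
    noise: float = 0.0

    def __post_init__(self) -> None:
        if len(self.delays) != len(self.intensities):
            raise AnalysisError("delays and intensities differ in length")


@dataclass(frozen=True)
class RateFit:
    """Result of a single-exponential decay fit."""

    rate: float
    rate_error: float
    amplitude: float
    amplitude_error: float
    n_points: int
    rss: float
    ok: bool = True
    reason: str = ""

    @classmethod
    def failed(cls, reason: str, n_points: int = 0) -> "RateFit":
        return cls(math.nan, math.nan, math.nan, math.nan, n_points, math.nan, False, reason)


@dataclass(frozen=True)
class NOEValue:
    value: float
    error: float


def _decay(t, i0, r):
    return i0 * np.exp(-r * t)


def _log_linear_start(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form start values from log-linear regression on positive points."""
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        rate = max(-slope, 1e-6)
        return float(np.exp(intercept)), float(rate)
    scale = float(np.max(np.abs(y))) or 1.0
    return scale, 1.0 / float(np.ptp(t) or 1.0)


def fit_exponential(series: RelaxationSeries, scale_covariance: bool = True) -> RateFit:
    """Unweighted least-squares fit of I(t) = I0*exp(-R*t).

    ``scale_covariance=True`` (default) scales the parameter covariance by the
    residual variance with an n-2 denominator; ``False`` uses the per-spectrum
    noise figure instead.  Fit failure (non-convergence, or a non-positive
    rate at the optimum) is flagged, never raised.
    """
    t = np.asarray(series.delays, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    order = np.argsort(t, kind="stable")  # make row order irrelevant
    t, y = t[order], y[order]
    n = len(t)
    if n < 3:
        raise AnalysisError(f"need >=3 points to fit, got {n}")
    p0 = _log_linear_start(t, y)
    try:
        if scale_covariance or series.noise <= 0:
            popt, pcov = curve_fit(_decay, t, y, p0=p0, maxfev=10000)
        else:
            sigma = np.full(n, series.noise)
            popt, pcov = curve_fit(
                _decay, t, y, p0=p0, sigma=sigma, absolute_sigma=True, maxfev=10000
            )
    except RuntimeError:
        return RateFit.failed("no convergence", n)
    i0, rate = popt
    if not np.isfinite(rate) or rate <= 0:
        return RateFit.failed("non-positive rate at optimum", n)
    errs = np.sqrt(np.diag(pcov))
    rss = float(np.sum((y - _decay(t, *popt)) ** 2))
    return RateFit(float(rate), float(errs[1]), float(i0), float(errs[0]), n, rss)


def jackknife_rate_error(series: RelaxationSeries) -> float:
    """Leave-one-point-out rate error: sqrt(((n-1)/n) * sum (R_i - Rbar)^2)."""
    t = np.asarray(series.delays, dtype=float)
    y = np.asarray(series.intensities, dtype=float)
    n = len(t)
    if n < 4:
        raise AnalysisError(f"need >=4 points for jackknife, got {n}")
    rates = []
    for i in range(n):
        sub = RelaxationSeries(
            series.residue,
            series.peak_id,
            np.delete(t, i),
            np.delete(y, i),
            series.noise,
        )
        fit = fit_exponential(sub)
        if not fit.ok:
            raise AnalysisError(f"jackknife refit failed: {fit.reason}")
        rates.append(fit.rate)
    rates = np.asarray(rates)
    return float(np.sqrt((n - 1) / n * np.sum((rates - rates.mean()) ** 2)))


def compute_hnnoe(
    saturated: float, reference: float, noise_sat: float, noise_ref: float
) -> NOEValue:
    """hnNOE = saturated/reference with the spectral noise propagated.

    error = |value| * sqrt((noise_sat/saturated)^2 + (noise_ref/reference)^2),
    with the limit form noise_sat/|reference| when the saturated peak is zero.
    """
    if reference == 0:
        raise AnalysisError("reference intensity is zero; hnNOE undefined")
    if noise_sat < 0 or noise_ref < 0:
        raise AnalysisError("noise figures must be non-negative")
    value = saturated / reference
    if saturated == 0:
        error = noise_sat / abs(reference)
    else:
        error = abs(value) * math.sqrt(
            (noise_sat / saturated) ** 2 + (noise_ref / reference) ** 2
        )
    return NOEValue(value, error)


def compute_r2_over_r1(r1: RateFit, r2: RateFit) -> tuple[float, float]:
    """R2/R1 with the two fit errors propagated in quadrature."""
    if not (r1.ok and r2.ok):
        raise AnalysisError("both fits must have succeeded")
    value = r2.rate / r1.rate
    error = value * math.sqrt(
        (r2.rate_error / r2.rate) ** 2 + (r1.rate_error / r1.rate) ** 2
    )
    return value, error


# --- per-residue profiles ---------------------------------------------------


@dataclass(frozen=True)
class PeakValue:
    peak_id: int
    value: float
    error: float


@dataclass
class ResidueProfile:
    """Per-residue observable values with missing-residue bookkeeping.

    Every position 1..36 is accounted for either in ``values`` (one entry per
    peak; two for doublets) or in ``missing`` with a reason (invisible,
    omitted, not observed, not fit).
    """

    construct: str
    salt_mM: int
    kind: str  # hnNOE | R1 | R2 | R2R1
    values: dict[int, list[PeakValue]] = field(default_factory=dict)
    missing: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos in range(1, TAIL_LENGTH + 1):
            if pos not in self.values and pos not in self.missing:
                self.missing[pos] = "not observed"

    @property
    def positions(self) -> list[int]:
        return sorted(self.values)

    def residue_mean(self, position: int) -> float:
        """Single number per residue: the mean over its peak values."""
        vals = self.values[position]
        return float(np.mean([v.value for v in vals]))

    def residue_error(self, position: int) -> float:
        vals = self.values[position]
        return float(np.sqrt(np.sum([v.error**2 for v in vals])) / len(vals))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in range(1, TAIL_LENGTH + 1):
            if pos in self.values:
                for pv in self.values[pos]:
                    rows.append(
                        dict(
                            residue=pos,
                            peak_id=pv.peak_id,
                            observable=self.kind,
                            value=pv.value,
                            error=pv.error,
                            status="ok",
                        )
                    )
            else:
                rows.append(
                    dict(
                        residue=pos,
                        peak_id=0,
                        observable=self.kind,
                        value=np.nan,
                        error=np.nan,
                        status=self.missing[pos],
                    )
                )
        return pd.DataFrame(rows)


def _base_missing(
    construct: str, salt_mM: int, rules: ObservabilityRules
) -> dict[int, str]:
    missing = {pos: "invisible" for pos in rules.never_visible}
    for pos in rules.omitted(construct, salt_mM):
        missing[pos] = "omitted"
    return missing


def _series_from_table(table: pd.DataFrame, experiment: str):
    sub = table[table["experiment"] == experiment]
    for (pos, peak_id), grp in sub.groupby(["residue", "peak_id"]):
        yield RelaxationSeries(
            int(pos),
            int(peak_id),
            grp["delay_s"].to_numpy(),
            grp["intensity"].to_numpy(),
            float(grp["noise"].iloc[0]),
        )


def rate_profile(
    table: pd.DataFrame,
    experiment: str,
    construct: str | None = None,
    salt_mM: int | None = None,
    rules: ObservabilityRules = DEFAULT_RULES,
    scale_covariance: bool = True,
) -> ResidueProfile:
    """Fit every residue/peak decay series in a peak table into a profile."""
    if experiment not in ("R1", "R2"):
        raise AnalysisError(f"experiment must be R1 or R2, got {experiment!r}")
    construct = construct or str(table["construct"].iloc[0])
    salt_mM = int(table["salt_mM"].iloc[0]) if salt_mM is None else salt_mM
    values: dict[int, list[PeakValue]] = {}
    missing = _base_missing(construct, salt_mM, rules)
    for series in _series_from_table(table, experiment):
        fit = fit_exponential(series, scale_covariance=scale_covariance)
        if fit.ok:
            values.setdefault(series.residue, []).append(
                PeakValue(series.peak_id, fit.rate, fit.rate_error)
            )
        else:
            missing[series.residue] = "not fit"
    for pos in values:
        missing.pop(pos, None)
    return ResidueProfile(construct, salt_mM, experiment, values, missing)


def noe_profile(
    table: pd.DataFrame,
    construct: str | None = None,
    salt_mM: int | None = None,
    rules: ObservabilityRules = DEFAULT_RULES,
) -> ResidueProfile:
    """Compute hnNOE per residue/peak from interleaved sat/ref rows."""
    construct = construct or str(table["construct"].iloc[0])
    salt_mM = int(table["salt_mM"].iloc[0]) if salt_mM is None else salt_mM
    sat = table[table["experiment"] == "hnNOE-sat"].set_index(["residue", "peak_id"])
    ref = table[table["experiment"] == "hnNOE-ref"].set_index(["residue", "peak_id"])
    values: dict[int, list[PeakValue]] = {}
    missing = _base_missing(construct, salt_mM, rules)
    for key in sat.index.intersection(ref.index):
        pos, peak_id = int(key[0]), int(key[1])
        noe = compute_hnnoe(
            float(sat.loc[key, "intensity"]),
            float(ref.loc[key, "intensity"]),
            float(sat.loc[key, "noise"]),
            float(ref.loc[key, "noise"]),
        )
        values.setdefault(pos, []).append(PeakValue(peak_id, noe.value, noe.error))
    for pos in values:
        values[pos].sort(key=lambda pv: pv.peak_id)
        missing.pop(pos, None)
    return ResidueProfile(construct, salt_mM, "hnNOE", values, missing)


def r2r1_profile(r1: ResidueProfile, r2: ResidueProfile) -> ResidueProfile:
    """Combine matching R1 and R2 profiles into an R2/R1 profile.

    Peaks are matched by peak id; a residue missing in either input is missing
    in the output.
    """
    if (r1.kind, r2.kind) != ("R1", "R2"):
        raise AnalysisError("inputs must be R1 and R2 profiles in that order")
    if (r1.construct, r1.salt_mM) != (r2.construct, r2.salt_mM):
        raise AnalysisError("profiles come from different samples")
    values: dict[int, list[PeakValue]] = {}
    missing: dict[int, str] = {}
    for pos in range(1, TAIL_LENGTH + 1):
        if pos in r1.values and pos in r2.values:
            p1 = {pv.peak_id: pv for pv in r1.values[pos]}
            p2 = {pv.peak_id: pv for pv in r2.values[pos]}
            shared = sorted(set(p1) & set(p2))
            if not shared:
                missing[pos] = "not fit"
                continue
            for pid in shared:
                v = p2[pid].value / p1[pid].value
                e = abs(v) * math.sqrt(
                    (p2[pid].error / p2[pid].value) ** 2
                    + (p1[pid].error / p1[pid].value) ** 2
                )
                values.setdefault(pos, []).append(PeakValue(pid, v, e))
        else:
            missing[pos] = r1.missing.get(pos) or r2.missing.get(pos) or "not observed"
    return ResidueProfile(r1.construct, r1.salt_mM, "R2R1", values, missing)


def region_average(profile: ResidueProfile, start, end) -> tuple[float, float, int]:
    """Unweighted mean and sample SD over observed values in a residue span.

    Doublet residues contribute the mean of their two peak values as a single
    observation; missing residues are excluded from n.
    """
    s = start.position if hasattr(start, "position") else int(start)
    e = end.position if hasattr(end, "position") else int(end)
    if s > e:
        raise AnalysisError(f"range start {s} after end {e}")
    vals = [profile.residue_mean(p) for p in range(s, e + 1) if p in profile.values]
    if not vals:
        raise EmptyRegionError(f"no observed residues in span {s}-{e}")
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr)
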