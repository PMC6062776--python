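"""Phosphorescence-lifetime oximetry.

Mono-exponential fitting of averaged phosphorescence decays,
I(t) = A + B exp(-t/tau), and conversion between lifetime and absolute
oxygen tension through a Stern-Volmer calibration,

    1/tau = 1/tau0 + kq * pO2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "DecayTrace",
    "LifetimeFit",
    "SternVolmerCalibration",
    "OxygenTension",
    "DEFAULT_CALIBRATION",
    "average_decays",
    "apply_instrument_offset",
    "fit_decay",
    "pO2_from_tau",
    "tau_from_pO2",
    "roi_pO2_timecourse",
]

DEFAULT_INSTRUMENT_OFFSET_S = 2e-6
TAU_BOUNDS_S = (0.5e-6, 1e-3)
REL_SE_TAU_GATE = 0.20


@dataclass
class DecayTrace:
    """A (possibly averaged) sampled phosphorescence decay."""

    t: np.ndarray
    signal: np.ndarray
    n_averaged: int = 1
    sample_rate: float | None = None
    offset_applied: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.t.ndim != 1 or self.t.shape != self.signal.shape:
            raise ParameterError("t and signal must be 1-D vectors of equal length")
        if self.t.size < 2:
            raise ParameterError("a decay trace needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ParameterError("t must be strictly increasing")
        if self.n_averaged < 1:
            raise ParameterError("n_averaged must be >= 1")
        if self.sample_rate is None:
            self.sample_rate = 1.0 / float(np.median(dt))
        else:
            if not self.sample_rate > 0:
                raise ParameterError("sample_rate must be positive")
            if abs(self.sample_rate * float(np.median(dt)) - 1.0) > 1e-6:
                raise ParameterError(
                    "sample_rate inconsistent with the time axis spacing (>1e-6 relative)"
                )

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class LifetimeFit:
    """Result of a mono-exponential decay fit."""

    A: float
    B: float
    tau: float
    rss: float
    converged: bool
    rel_se_tau: float
    message: str = ""


@dataclass
class SternVolmerCalibration:
    """Lifetime <-> pO2 calibration.

    ``kq`` in mmHg^-1 s^-1 and ``tau0`` (unquenched lifetime) in seconds
    define the Stern-Volmer branch; ``sv_regime_tau`` is the lifetime below
    which that branch is asserted valid. An optional ``table`` of
    (tau_s, pO2_mmHg) pairs, strictly decreasing in pO2 as tau grows,
    overrides the analytic branch via monotone piecewise-cubic interpolation.
    """

    kq: float = 291.014
    tau0: float = 47e-6
    sv_regime_tau: float = 16e-6
    table: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.kq > 0:
            raise ParameterError("kq must be positive")
        if not self.tau0 > self.sv_regime_tau > 0:
            raise ParameterError("require tau0 > sv_regime_tau > 0")
        if self.table is not None:
            tbl = np.asarray(self.table, dtype=np.float64)
            if tbl.ndim != 2 or tbl.shape[1] != 2 or tbl.shape[0] < 2:
                raise ParameterError("table must be an (n >= 2, 2) array of (tau_s, pO2)")
            order = np.argsort(tbl[:, 0])
            tbl = tbl[order]
            if np.any(np.diff(tbl[:, 0]) <= 0) or np.any(np.diff(tbl[:, 1]) >= 0):
                raise ParameterError("table must have unique tau and strictly decreasing pO2")
            self.table = tbl


DEFAULT_CALIBRATION = SternVolmerCalibration()


@dataclass
class OxygenTension:
    """Absolute oxygen tension, mmHg; ``clamped`` marks a negative->0 clamp."""

    pO2: float
    clamped: bool = False
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.pO2 < 0:
            raise ParameterError("pO2 must be non-negative")


def average_decays(traces: Sequence[DecayTrace]) -> DecayTrace:
    """Pointwise mean of decays sharing one time base; n_averaged adds up."""
    traces = list(traces)
    if not traces:
        raise ParameterError("cannot average an empty sequence of decays")
    t0 = traces[0].t
    for tr in traces[1:]:
        if tr.t.shape != t0.shape or not np.allclose(tr.t, t0, rtol=0, atol=1e-12):
            raise ParameterError("decay traces do not share a time base")
        if tr.offset_applied != traces[0].offset_applied:
            raise ParameterError("cannot mix offset-applied and raw traces")
    mean = np.mean(np.stack([tr.signal for tr in traces]), axis=0)
    return DecayTrace(
        t=t0.copy(),
        signal=mean,
        n_averaged=sum(tr.n_averaged for tr in traces),
        sample_rate=traces[0].sample_rate,
        offset_applied=traces[0].offset_applied,
    )


def apply_instrument_offset(
    trace: DecayTrace, offset: float = DEFAULT_INSTRUMENT_OFFSET_S
) -> DecayTrace:
    """Discard the instrument-contaminated start of a trace and re-zero time.

    Samples with t < offset (relative to the first sample) are removed and
    the time axis shifted so the first retained sample sits at t = 0.
    """
    if trace.offset_applied:
        raise ParameterError("instrument offset already applied to this trace")
    if offset < 0:
        raise ParameterError("offset must be non-negative")
    if offset >= trace.duration:
        raise ParameterError(
            f"offset {offset} s >= trace duration {trace.duration} s"
        )
    keep = trace.t - trace.t[0] >= offset
    t = trace.t[keep]
    return DecayTrace(
        t=t - t[0],
        signal=trace.signal[keep].copy(),
        n_averaged=trace.n_averaged,
        sample_rate=trace.sample_rate,
        offset_applied=True,
    )


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n_tail = max(1, y.size // 10)
    A0 = float(np.mean(y[-n_tail:]))
    half = slice(0, y.size // 2)
    resid = y[half] - A0
    pos = resid > 0
    if np.count_nonzero(pos) >= 5:
        slope, intercept = np.polyfit(t[half][pos], np.log(resid[pos]), 1)
        if slope < 0:
            tau0 = float(np.clip(-1.0 / slope, *TAU_BOUNDS_S))
            return A0, float(np.exp(intercept)), tau0
    # fallback: crude scale guesses
    B0 = max(float(y[0] - A0), 1e-12)
    return A0, B0, float(np.clip(t[-1] / 5.0, *TAU_BOUNDS_S))


def fit_decay(trace: DecayTrace) -> LifetimeFit:
    """Nonlinear least-squares fit of I(t) = A + B exp(-t/tau).

    Requires the instrument offset to have been applied and >= 50 samples.
    ``converged`` demands a successful solve, B > 0 and a relative standard
    error on tau below 20%. Failures return diagnostics, never raise
    (except for a constant signal, which carries no decay information).
    """
    if not trace.offset_applied:
        raise ParameterError("apply the instrument offset before fitting")
    t, y = trace.t, trace.signal
    if t.size < 50:
        raise ParameterError(f"need >= 50 samples to fit, got {t.size}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("signal is constant; no decay to fit")

    A0, B0, tau0 = _initial_guess(t, y)

    def model(tt, A, B, tau):
        return A + B * np.exp(-tt / tau)

    lo = [-np.inf, 0.0, TAU_BOUNDS_S[0]]
    hi = [np.inf, np.inf, TAU_BOUNDS_S[1]]
    p0 = [A0, max(B0, 1e-12), tau0]
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return LifetimeFit(
            A=np.nan, B=np.nan, tau=np.nan, rss=np.nan,
            converged=False, rel_se_tau=np.inf, message=f"solver failure: {exc}",
        )
    A, B, tau = (float(v) for v in popt)
    rss = float(np.sum((y - model(t, *popt)) ** 2))
    se_tau = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    rel_se = se_tau / tau if tau > 0 else np.inf
    converged = bool(B > 0 and np.isfinite(rel_se) and rel_se < REL_SE_TAU_GATE)
    msg = "" if converged else (
        "no decaying component (B <= 0)" if B <= 0 else
        f"relative SE of tau {rel_se:.3g} exceeds the {REL_SE_TAU_GATE:.0%} gate"
    )
    return LifetimeFit(A=A, B=B, tau=tau, rss=rss, converged=converged,
                       rel_se_tau=rel_se, message=msg)


def pO2_from_tau(tau: float, cal: SternVolmerCalibration = DEFAULT_CALIBRATION) -> OxygenTension:
    """Convert a lifetime to absolute oxygen tension.

    Without a table, the Stern-Volmer branch pO2 = (1/tau - 1/tau0)/kq is
    applied over the full lifetime range; a warning is attached for
    tau >= sv_regime_tau, where the analytic branch is extrapolated beyond
    its asserted regime. tau > tau0 clamps to 0 (flagged). With a table,
    monotone piecewise-cubic interpolation of the table is used instead.
    """
    if not tau > 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    warning = None
    if cal.table is not None:
        interp = PchipInterpolator(cal.table[:, 0], cal.table[:, 1], extrapolate=True)
        p = float(interp(tau))
    else:
        p = (1.0 / tau - 1.0 / cal.tau0) / cal.kq
        if tau >= cal.sv_regime_tau:
            warning = (
                f"tau = {tau:.3g} s >= Stern-Volmer regime bound "
                f"{cal.sv_regime_tau:.3g} s; analytic branch extrapolated"
            )
    if p < 0:
        return OxygenTension(pO2=0.0, clamped=True, warning=warning)
    return OxygenTension(pO2=p, clamped=False, warning=warning)


def tau_from_pO2(pO2: float, cal: SternVolmerCalibration = DEFAULT_CALIBRATION) -> float:
    """Exact inverse of the Stern-Volmer branch: tau = 1/(1/tau0 + kq pO2)."""
    if pO2 < 0:
        raise ParameterError(f"pO2 must be non-negative, got {pO2}")
    return 1.0 / (1.0 / cal.tau0 + cal.kq * pO2)


def roi_pO2_timecourse(
    decays: Sequence[tuple[str, DecayTrace]],
    cal: SternVolmerCalibration = DEFAULT_CALIBRATION,
    pattern_rate: float | None = None,
    offset: float = DEFAULT_INSTRUMENT_OFFSET_S,
) -> pd.DataFrame:
    """Fit a sequence of per-ROI decays and convert to pO2 timecourses.

    ``decays`` is ordered by acquisition; each entry k is timestamped at the
    midpoint of its pattern slot, (k + 1/2) / pattern_rate (the bare index
    when no rate is given). Raw traces get the instrument offset applied
    internally. Non-converged fits yield NaN pO2 with the reason recorded.

    Returns a DataFrame with columns
    roi_id, time_s, A, B, tau_s, pO2_mmhg, clamped, converged, note.
    """
    decays = list(decays)
    if not decays:
        raise ParameterError("empty decay sequence")
    rows = []
    for k, (roi_id, trace) in enumerate(decays):
        time_s = (k + 0.5) / pattern_rate if pattern_rate else float(k)
        if not trace.offset_applied:
            trace = apply_instrument_offset(trace, offset)
        try:
            fit = fit_decay(trace)
        except DegenerateInputError as exc:
            rows.append(dict(roi_id=roi_id, time_s=time_s, A=np.nan, B=np.nan,
                             tau_s=np.nan, pO2_mmhg=np.nan, clamped=False,
                             converged=False, note=str(exc)))
            continue
        if fit.converged:
            ox = pO2_from_tau(fit.tau, cal)
            rows.append(dict(roi_id=roi_id, time_s=time_s, A=fit.A, B=fit.B,
                             tau_s=fit.tau, pO2_mmhg=ox.pO2, clamped=ox.clamped,
                             converged=True, note=ox.warning or ""))
        else:
            rows.append(dict(roi_id=roi_id, time_s=time_s, A=fit.A, B=fit.B,
                             tau_s=fit.tau, pO2_mmhg=np.nan, clamped=False,
                             converged=False, note=fit.message))
    return pd.DataFrame(rows)
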