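"""Per-pulse response statistics for pulsed vesicles.

Turns per-frame geometry plus pulse metadata into the quantities the
response curves are built from:

* the normalised area A_norm = A_f / A_i of each pulse, where A_i averages
  the pre-pulse window and A_f the last quartile of the post-pulse window
  (the "final" state, reached minutes after the pulse),
* the final form factor,
* a contrast-loss class per vesicle — ``none``, ``gradual`` (slow cumulative
  decline over many pulses) or ``complete`` (the interior/exterior contrast
  collapses within a single post-pulse window),
* field-binned means +/- sample standard deviations (30 V/mm bins by
  convention) and a 4-parameter logistic least-squares fit of the response
  versus applied field,
* a smooth exponential fit of the post-pulse area decay whose analytic
  derivative feeds the efflux and pore-radius estimates.

Responses are plotted and fitted against the *applied field* E (V/mm), not
the induced transmembrane voltage, because vesicles become non-spherical
after repeated pulses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.optimize import OptimizeWarning, curve_fit

from .errors import (
    FitError,
    InsufficientDataError,
    InvalidFieldError,
    WindowEmptyError,
)
from .segmentation import FrameGeometry

__all__ = [
    "PulseEvent",
    "GUVResponse",
    "BinnedResponse",
    "SigmoidFit",
    "AreaDecayFit",
    "SplineDecayFit",
    "compute_response",
    "classify_contrast_loss",
    "bin_and_average",
    "fit_sigmoid",
    "fit_area_decay",
]


def _curve_fit(*args, **kwargs):
    # the covariance estimate is discarded everywhere here; silence its warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        return curve_fit(*args, **kwargs)


@dataclass(frozen=True)
class PulseEvent:
    """One applied pulse and its frame windows.

    ``field_strength`` in V/mm, ``duration_us`` in microseconds.
    ``pre_window``/``post_window`` are half-open frame ranges (start, stop);
    the pre window lies entirely before ``pulse_frame`` and the post window
    entirely after it.
    """

    field_strength: float
    duration_us: float
    pulse_frame: int
    pre_window: tuple[int, int]
    post_window: tuple[int, int]
    pulse_id: int = 0

    def __post_init__(self):
        if self.field_strength < 0:
            raise InvalidFieldError(f"negative field strength {self.field_strength}")
        if self.duration_us <= 0:
            raise ValueError("pulse duration must be positive")
        pre_lo, pre_hi = self.pre_window
        post_lo, post_hi = self.post_window
        if not (pre_lo < pre_hi <= self.pulse_frame):
            raise ValueError("pre_window must lie entirely before pulse_frame")
        if not (self.pulse_frame < post_lo < post_hi):
            raise ValueError("post_window must lie entirely after pulse_frame")


@dataclass(frozen=True)
class GUVResponse:
    """Derived per-pulse quantities; A_norm = A_f / A_i exactly."""

    pulse: PulseEvent
    a_i_um2: float
    a_f_um2: float
    a_norm: float
    ff_final: float
    contrast_class: str = "none"
    contrast_drop_fraction: float = math.nan


@dataclass(frozen=True)
class BinnedResponse:
    """Mean +/- sample sd of a response within one electric-field bin."""

    bin_lower: float
    bin_upper: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class SigmoidFit:
    """4-parameter logistic y(E) = u - (u - l) / (1 + exp(-(E - e50)/width)).

    ``upper`` is the low-field plateau, ``lower`` the high-field one,
    ``e50`` the midpoint field and ``width`` (> 0) the transition scale.
    """

    upper: float
    lower: float
    e50: float
    width: float
    residual_ss: float

    def predict(self, e_field):
        return _logistic(np.asarray(e_field, dtype=float), self.upper, self.lower, self.e50, self.width)


def _window_values(
    frames: Sequence[FrameGeometry | None], window: tuple[int, int], attr: str
) -> np.ndarray:
    lo, hi = window
    vals = [
        getattr(frames[i], attr)
        for i in range(lo, min(hi, len(frames)))
        if frames[i] is not None
    ]
    return np.asarray(vals, dtype=float)


def compute_response(
    frames: Sequence[FrameGeometry | None], pulse: PulseEvent
) -> GUVResponse:
    """Normalised area and final form factor of one pulse.

    A_i is the mean area over the pre-pulse window; A_f and FF_final average
    the last quartile of the post-pulse window (its most "final" part),
    falling back to all non-gap post frames if that quartile is all gaps.
    Contrast classification is a per-vesicle operation and is attached
    separately (see :func:`classify_contrast_loss`).

    Raises
    ------
    WindowEmptyError
        If either window contains only gap frames.
    """
    pre = _window_values(frames, pulse.pre_window, "area_um2")
    if pre.size == 0:
        raise WindowEmptyError(f"pulse {pulse.pulse_id}: pre-window has no usable frames")
    lo, hi = pulse.post_window
    hi = min(hi, len(frames))
    quartile = (max(lo, hi - max(1, (hi - lo) // 4)), hi)
    a_f_vals = _window_values(frames, quartile, "area_um2")
    ff_vals = _window_values(frames, quartile, "form_factor")
    if a_f_vals.size == 0:
        a_f_vals = _window_values(frames, (lo, hi), "area_um2")
        ff_vals = _window_values(frames, (lo, hi), "form_factor")
    if a_f_vals.size == 0:
        raise WindowEmptyError(f"pulse {pulse.pulse_id}: post-window has no usable frames")
    a_i = float(pre.mean())
    a_f = float(a_f_vals.mean())
    return GUVResponse(
        pulse=pulse,
        a_i_um2=a_i,
        a_f_um2=a_f,
        a_norm=a_f / a_i,
        ff_final=float(ff_vals.mean()),
    )


def classify_contrast_loss(
    contrast: Sequence[float],
    pulses: Sequence[PulseEvent],
    frac_complete: float = 0.10,
    frac_gradual: float = 0.25,
) -> tuple[str, float]:
    """Classify the contrast trace of one vesicle over its whole pulse train.

    * ``complete`` — within at least one post-pulse window the contrast falls
      below ``frac_complete`` of the pre-experiment baseline;
    * ``gradual`` — no single-window collapse, but the cumulative decline by
      the end of the trace exceeds ``frac_gradual`` of the baseline;
    * ``none`` — otherwise.

    Returns ``(class, overall_drop_fraction)``. Gap frames may be NaN.

    Raises
    ------
    InsufficientDataError
        With fewer than 2 finite contrast samples, or no pulses.
    """
    trace = np.asarray(contrast, dtype=float)
    finite = np.isfinite(trace)
    if finite.sum() < 2 or len(pulses) == 0:
        raise InsufficientDataError("need at least 2 contrast samples and one pulse")

    first = pulses[0]
    lo, hi = first.pre_window
    baseline_vals = trace[lo:hi][np.isfinite(trace[lo:hi])]
    if baseline_vals.size == 0:
        baseline_vals = trace[finite][:1]
    baseline = float(baseline_vals.mean())
    if baseline <= 0:
        return "none", 0.0

    complete = False
    for pulse in pulses:
        plo, phi = pulse.post_window
        window = trace[plo : min(phi, len(trace))]
        window = window[np.isfinite(window)]
        if window.size and window.min() < frac_complete * baseline:
            complete = True
            break

    final_vals = trace[finite][-3:]
    drop = (baseline - float(final_vals.mean())) / baseline
    if complete:
        return "complete", drop
    if drop >= frac_gradual:
        return "gradual", drop
    return "none", drop


def attach_contrast_class(
    responses: Sequence[GUVResponse], contrast_class: str, drop_fraction: float
) -> list[GUVResponse]:
    """Stamp one vesicle's contrast class onto all of its pulse responses."""
    return [
        replace(r, contrast_class=contrast_class, contrast_drop_fraction=drop_fraction)
        for r in responses
    ]


def bin_and_average(
    fields: Sequence[float], values: Sequence[float], bin_width: float = 30.0
) -> list[BinnedResponse]:
    """Average a response over electric-field bins [k*w, (k+1)*w).

    Bins with no samples are omitted; the spread is the sample standard
    deviation (ddof=1), reported as 0 for singleton bins.

    Raises
    ------
    InvalidFieldError
        If any field strength is negative.
    """
    e = np.asarray(fields, dtype=float)
    y = np.asarray(values, dtype=float)
    if e.size == 0 or e.size != y.size:
        raise ValueError("fields and values must be non-empty and the same length")
    if np.any(e < 0):
        raise InvalidFieldError("negative electric field in responses")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    out = []
    for k in np.unique(np.floor(e / bin_width).astype(int)):
        sel = (e >= k * bin_width) & (e < (k + 1) * bin_width)
        vals = y[sel]
        out.append(
            BinnedResponse(
                bin_lower=k * bin_width,
                bin_upper=(k + 1) * bin_width,
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                n=int(vals.size),
            )
        )
    return out


def _logistic(e, upper, lower, e50, width):
    z = np.clip(-(e - e50) / width, -500.0, 500.0)  # avoid spurious exp overflow
    return upper - (upper - lower) / (1.0 + np.exp(z))


def fit_sigmoid(fields: Sequence[float], values: Sequence[float]) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of a response versus field.

    Runs a small grid of starting points (midpoint at the field quartiles,
    width at several fractions of the field span) and keeps the converged
    fit with the lowest residual sum of squares. A fit that lands on a
    negative width is folded back to the equivalent parameterisation with
    width > 0 and the plateaus swapped.

    Raises
    ------
    ValueError
        With fewer than 4 distinct field values.
    FitError
        If no starting point converges (carries the best attempt).
    """
    e = np.asarray(fields, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(e).size < 4:
        raise ValueError("need at least 4 distinct field values for a 4-parameter fit")

    if np.ptp(y) < 1e-12:
        level = float(y[0])
        return SigmoidFit(level, level, float(np.median(e)), max(np.ptp(e) / 4.0, 1.0), 0.0)

    span = float(np.ptp(e)) or 1.0
    order = np.argsort(e)
    n_edge = max(1, e.size // 4)
    u0 = float(y[order][:n_edge].mean())
    l0 = float(y[order][-n_edge:].mean())
    best, best_ss = None, np.inf
    last_err: Exception | None = None
    for e50_0 in np.quantile(e, [0.25, 0.5, 0.75]):
        for w0 in (span / 20.0, span / 8.0, span / 3.0):
            try:
                popt, _ = _curve_fit(
                    _logistic, e, y, p0=[u0, l0, float(e50_0), w0], maxfev=20000
                )
            except RuntimeError as err:
                last_err = err
                continue
            ss = float(np.sum((_logistic(e, *popt) - y) ** 2))
            if ss < best_ss:
                best, best_ss = popt, ss
    if best is None:
        raise FitError(f"sigmoid fit failed from every start: {last_err}", best=None)
    upper, lower, e50, width = (float(v) for v in best)
    if width < 0:
        upper, lower, width = lower, upper, -width
    return SigmoidFit(upper, lower, e50, width, best_ss)


@dataclass(frozen=True)
class AreaDecayFit:
    """Exponential post-pulse area model A(t) = a_inf + delta_a exp(-(t-t0)/tau).

    ``tau_at_bound`` flags a time constant pinned at the optimiser bound
    (the decay is then indistinguishable from linear over the window, but
    the initial slope -delta_a/tau remains well determined).
    """

    a_inf: float
    delta_a: float
    tau: float
    t0: float
    residual_ss: float
    tau_at_bound: bool = False

    def value(self, t):
        t = np.asarray(t, dtype=float)
        return self.a_inf + self.delta_a * np.exp(-(t - self.t0) / self.tau)

    def derivative(self, t):
        """Analytic dA/dt, used by the efflux estimate."""
        t = np.asarray(t, dtype=float)
        return -self.delta_a / self.tau * np.exp(-(t - self.t0) / self.tau)


@dataclass(frozen=True)
class SplineDecayFit:
    """Smoothing-spline alternative with a numeric derivative (sensitivity check)."""

    spline: UnivariateSpline
    t0: float
    residual_ss: float

    def value(self, t):
        return self.spline(np.asarray(t, dtype=float))

    def derivative(self, t):
        return self.spline.derivative()(np.asarray(t, dtype=float))


def fit_area_decay(
    times: Sequence[float],
    areas: Sequence[float],
    method: str = "exponential",
) -> AreaDecayFit | SplineDecayFit:
    """Fit a smooth decaying model to a post-pulse area time series.

    The default single-exponential model has an analytic derivative for the
    efflux estimate; ``method="spline"`` fits a smoothing spline instead and
    differentiates it numerically. Non-decaying input is not an error: the
    exponential fit returns delta_a ~ 0.

    Raises
    ------
    ValueError
        With fewer than 5 samples or non-increasing times.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(areas, dtype=float)
    keep = np.isfinite(t) & np.isfinite(a)
    t, a = t[keep], a[keep]
    if t.size < 5:
        raise ValueError("need at least 5 non-gap samples spanning the decay")
    order = np.argsort(t)
    t, a = t[order], a[order]
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("times must span a positive interval")

    if method == "spline":
        resid_scale = max(float(np.std(np.diff(a))) / math.sqrt(2.0), 1e-12)
        spline = UnivariateSpline(t, a, k=3, s=t.size * resid_scale**2)
        ss = float(np.sum((spline(t) - a) ** 2))
        return SplineDecayFit(spline=spline, t0=float(t[0]), residual_ss=ss)
    if method != "exponential":
        raise ValueError(f"unknown decay model {method!r}")

    slope = float(np.polyfit(t, a, 1)[0])
    if slope >= 0 or np.ptp(a) < 1e-12:
        a_inf = float(a.mean())
        ss = float(np.sum((a - a_inf) ** 2))
        return AreaDecayFit(a_inf=a_inf, delta_a=0.0, tau=span, t0=float(t[0]),
                            residual_ss=ss, tau_at_bound=False)

    ts = t - t[0]
    tau_hi = 50.0 * span
    p0 = [float(a[-1]), float(a[0] - a[-1]), span / 3.0]

    def model(tt, a_inf, delta_a, tau):
        return a_inf + delta_a * np.exp(-tt / tau)

    try:
        popt, _ = _curve_fit(
            model,
            ts,
            a,
            p0=p0,
            bounds=([-np.inf, 0.0, 1e-9 * span], [np.inf, np.inf, tau_hi]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
    except RuntimeError as err:
        raise FitError(f"area-decay fit failed: {err}") from err
    a_inf, delta_a, tau = (float(v) for v in popt)
    ss = float(np.sum((model(ts, *popt) - a) ** 2))
    return AreaDecayFit(
        a_inf=a_inf,
        delta_a=delta_a,
        tau=tau,
        t0=float(t[0]),
        residual_ss=ss,
        tau_at_bound=tau > 0.95 * tau_hi,
    )
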