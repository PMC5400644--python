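"""Biodistribution kinetics: %IA/g curves, kinetic fits, cumulated activity.

Turns gamma-counter records into time-activity curves, fits them with a
mono-exponential (most organs) or a polynomial-uptake/exponential-tail hybrid
(tumor and spleen), integrates the curves into cumulated activities, and
extrapolates the biological kinetics measured with an imaging surrogate
nuclide to therapeutic nuclides.

Kinetic conventions
-------------------
A fitted curve carries a ``decay_corrected`` flag.  If False (default), the
values include physical decay and the fitted rate is the effective constant
``lambda_eff = lambda_bio + lambda_phys``; if True, the values are
biology-only and ``lambda_eff = lambda_bio``.  Surrogate-nuclide
extrapolation always returns a fit in the non-decay-corrected convention of
the target nuclide, which is what cumulated-activity integration needs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .nuclides import Radionuclide, decay_factor

__all__ = [
    "BiodistSample",
    "TimeActivityCurve",
    "KineticFit",
    "MonoExpFit",
    "HybridFit",
    "DecayShiftedFit",
    "CumulatedActivity",
    "InsufficientDataError",
    "FitFailureError",
    "percent_ia_per_gram",
    "samples_to_frame",
    "aggregate_curve",
    "fit_monoexp",
    "fit_hybrid",
    "cumulated_activity",
    "extrapolate_to_nuclide",
]

logger = logging.getLogger(__name__)

#: hours -> seconds
H_TO_S = 3600.0


class InsufficientDataError(ValueError):
    """Too few usable points for the requested fit."""


class FitFailureError(RuntimeError):
    """The optimizer could not produce a physically valid fit."""


@dataclass(frozen=True)
class BiodistSample:
    """One gamma-counted organ sample from one animal."""

    mouse_id: str
    organ: str
    time_h: float
    mass_g: float
    counts_cpm: float
    counter_eff_cpm_per_mbq: float
    injected_mbq: float
    count_offset_h: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError(
                f"mouse {self.mouse_id} organ {self.organ}: mass must be > 0"
            )
        if self.counts_cpm < 0:
            raise ValueError(
                f"mouse {self.mouse_id} organ {self.organ}: negative counts"
            )
        if self.injected_mbq <= 0:
            raise ValueError(
                f"mouse {self.mouse_id}: injected activity must be > 0"
            )
        if self.time_h < 0:
            raise ValueError(f"mouse {self.mouse_id}: negative time point")


def percent_ia_per_gram(
    sample: BiodistSample,
    nuclide: Radionuclide | None = None,
    decay_correct: bool = False,
) -> tuple[str, float, float, float]:
    """Convert one counting record to (%IA/g, %IA) at sacrifice time.

    Measured activity is ``counts / efficiency``; with ``decay_correct`` the
    physical decay between sacrifice and counting (``count_offset_h``) is
    undone, which requires the counting nuclide.

    Returns ``(organ, time_h, pia_per_g, pia)``.
    """
    if sample.counter_eff_cpm_per_mbq <= 0:
        raise ValueError("counter efficiency must be > 0")
    activity_mbq = sample.counts_cpm / sample.counter_eff_cpm_per_mbq
    if decay_correct and sample.count_offset_h != 0.0:
        if nuclide is None:
            raise ValueError("decay correction requires the counting nuclide")
        activity_mbq /= decay_factor(nuclide, sample.count_offset_h)
    pia = 100.0 * activity_mbq / sample.injected_mbq
    pia_g = pia / sample.mass_g
    return sample.organ, sample.time_h, pia_g, pia


def samples_to_frame(
    samples: list[BiodistSample],
    nuclide: Radionuclide | None = None,
    decay_correct: bool = False,
) -> pd.DataFrame:
    """Tabulate %IA/g and %IA for a list of samples."""
    rows = []
    for s in samples:
        organ, t, pia_g, pia = percent_ia_per_gram(s, nuclide, decay_correct)
        rows.append(
            {
                "mouse_id": s.mouse_id,
                "organ": organ,
                "time_h": t,
                "mass_g": s.mass_g,
                "pia_g": pia_g,
                "pia": pia,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-organ mean +- SEM time-activity points (%IA/g or %IA)."""

    organ: str
    times_h: np.ndarray
    values: np.ndarray
    sems: np.ndarray
    n_per_point: np.ndarray
    nuclide: Radionuclide | None = None
    decay_corrected: bool = False
    unit: str = "pia_g"

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        s = np.asarray(self.sems, dtype=float)
        n = np.asarray(self.n_per_point, dtype=int)
        if np.any(np.diff(t) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("curve values must be nonnegative")
        if np.any(n < 1):
            raise ValueError("n_per_point must be >= 1")
        for name, arr in (("times_h", t), ("values", v), ("sems", s), ("n_per_point", n)):
            object.__setattr__(self, name, arr)


def aggregate_curve(
    samples: list[BiodistSample],
    organ: str,
    nuclide: Radionuclide | None = None,
    decay_correct_offset: bool = False,
    decay_corrected: bool = False,
    unit: str = "pia_g",
) -> TimeActivityCurve:
    """Mean and SEM of %IA/g (or %IA) across mice at each time point.

    ``decay_correct_offset`` undoes sacrifice-to-counting decay;
    ``decay_corrected`` records whether the resulting values are
    biology-only (counts corrected back to injection time upstream).
    """
    frame = samples_to_frame(
        [s for s in samples if s.organ == organ], nuclide, decay_correct_offset
    )
    if frame.empty:
        raise ValueError(f"no samples for organ {organ!r}")
    col = "pia_g" if unit == "pia_g" else "pia"
    grouped = frame.groupby("time_h")[col]
    mean = grouped.mean()
    sem = grouped.sem(ddof=1).fillna(0.0)
    n = grouped.count()
    return TimeActivityCurve(
        organ=organ,
        times_h=mean.index.to_numpy(dtype=float),
        values=mean.to_numpy(),
        sems=sem.to_numpy(),
        n_per_point=n.to_numpy(),
        nuclide=nuclide,
        decay_corrected=decay_corrected,
        unit=unit,
    )


class KineticFit:
    """Base class for fitted time-activity models.

    Subclasses provide ``predict(t)`` [same unit as the fitted curve],
    ``lambda_eff`` [1/h] governing the terminal exponential, the organ name,
    the fitted nuclide and the decay-correction convention of the data.
    """

    organ: str = ""
    nuclide: Radionuclide | None = None
    decay_corrected: bool = False
    residual_rms: float = 0.0
    t_last: float = 0.0

    @property
    def lambda_eff(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, t_h):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class MonoExpFit(KineticFit):
    """A(t) = A0 exp(-lambda_eff t)."""

    a0: float
    _lambda_eff: float
    organ: str = ""
    nuclide: Radionuclide | None = None
    decay_corrected: bool = False
    residual_rms: float = 0.0
    t_last: float = 0.0

    def __post_init__(self) -> None:
        if self._lambda_eff <= 0:
            raise FitFailureError(
                f"{self.organ}: non-decaying fit (lambda_eff <= 0); "
                "consider the hybrid uptake model"
            )

    @property
    def lambda_eff(self) -> float:
        return self._lambda_eff

    def predict(self, t_h):
        t = np.asarray(t_h, dtype=float)
        out = self.a0 * np.exp(-self._lambda_eff * t)
        return float(out) if out.ndim == 0 else out


@dataclass
class HybridFit(KineticFit):
    """Polynomial uptake on [0, t_peak], mono-exponential tail beyond.

    The rising piece is parameterized as
    ``A(t) = A(t_peak) + sum_k c_k (t - t_peak)^k`` so continuity at the
    junction is exact by construction.  Predictions are clipped at zero.
    """

    tail: MonoExpFit
    t_peak: float
    poly_coeffs: np.ndarray  # c_1..c_deg of (t - t_peak)^k; empty = degenerate
    organ: str = ""
    nuclide: Radionuclide | None = None
    decay_corrected: bool = False
    residual_rms: float = 0.0
    t_last: float = 0.0

    @property
    def lambda_eff(self) -> float:
        return self.tail.lambda_eff

    @property
    def a0(self) -> float:
        return self.tail.a0

    def predict(self, t_h):
        scalar = np.ndim(t_h) == 0
        t = np.atleast_1d(np.asarray(t_h, dtype=float))
        out = self.tail.predict(t)
        if len(self.poly_coeffs):
            rising = t < self.t_peak
            if np.any(rising):
                dt = t[rising] - self.t_peak
                val = np.full(dt.shape, self.tail.predict(self.t_peak))
                for k, c in enumerate(self.poly_coeffs, start=1):
                    val += c * dt**k
                out[rising] = val
        out = np.maximum(out, 0.0)
        return float(out[0]) if scalar else out


@dataclass
class DecayShiftedFit(KineticFit):
    """A fitted curve with its physical decay constant swapped.

    ``predict(t) = base_predict(t) * exp(-delta_lambda * t)``; used to carry
    hybrid fits across the surrogate-nuclide extrapolation.
    """

    base: KineticFit
    delta_lambda: float
    organ: str = ""
    nuclide: Radionuclide | None = None
    decay_corrected: bool = False
    residual_rms: float = 0.0
    t_last: float = 0.0

    @property
    def lambda_eff(self) -> float:
        return self.base.lambda_eff + self.delta_lambda

    @property
    def t_peak(self) -> float:
        return getattr(self.base, "t_peak", 0.0)

    def predict(self, t_h):
        scalar = np.ndim(t_h) == 0
        t = np.atleast_1d(np.asarray(t_h, dtype=float))
        out = self.base.predict(t) * np.exp(-self.delta_lambda * t)
        return float(out[0]) if scalar else out


def _monoexp_seed(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Log-linear seed for the nonlinear fit (positive values only)."""
    slope, intercept = np.polyfit(t, np.log(v), 1)
    lam = max(-slope, 1e-6)
    return math.exp(intercept), lam


def fit_monoexp(curve: TimeActivityCurve, weighting: str = "relative") -> MonoExpFit:
    """Nonlinear least squares of A0 exp(-lambda t) on the original scale.

    ``weighting="relative"`` (default) minimizes relative residuals
    (proportional-error model, matching the constant-CV noise of gamma
    counting across two orders of magnitude of activity); ``"none"`` gives
    plain unweighted least squares.  Either way the fit stays on the
    original (not log) scale and lambda is bounded positive.
    """
    mask = curve.values > 0
    t, v = curve.times_h[mask], curve.values[mask]
    if t.size < 3:
        raise InsufficientDataError(
            f"{curve.organ}: mono-exponential fit needs >= 3 positive points, "
            f"got {t.size}"
        )
    a0_seed, lam_seed = _monoexp_seed(t, v)
    if np.polyfit(t, np.log(v), 1)[0] >= 0:
        raise FitFailureError(
            f"{curve.organ}: data do not decay (best lambda_eff <= 0); "
            "use the hybrid uptake model"
        )
    popt, _ = optimize.curve_fit(
        lambda tt, a0, lam: a0 * np.exp(-lam * tt),
        t,
        v,
        p0=(a0_seed, lam_seed),
        sigma=v if weighting == "relative" else None,
        absolute_sigma=False,
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    a0, lam = popt
    rms = float(np.sqrt(np.mean((a0 * np.exp(-lam * t) - v) ** 2)))
    return MonoExpFit(
        a0=float(a0),
        _lambda_eff=float(lam),
        organ=curve.organ,
        nuclide=curve.nuclide,
        decay_corrected=curve.decay_corrected,
        residual_rms=rms,
        t_last=float(curve.times_h[-1]),
    )


def _fit_tail(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Mono-exponential tail fit; exact solve when only two points."""
    if t.size == 2:
        if v[0] <= 0 or v[1] <= 0 or v[1] >= v[0]:
            raise FitFailureError("tail points do not decay")
        lam = math.log(v[0] / v[1]) / (t[1] - t[0])
        a0 = v[0] * math.exp(lam * t[0])
        return a0, lam
    a0_seed, lam_seed = _monoexp_seed(t, v)
    popt, _ = optimize.curve_fit(
        lambda tt, a0, lam: a0 * np.exp(-lam * tt),
        t,
        v,
        p0=(a0_seed, lam_seed),
        sigma=v,
        absolute_sigma=False,
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


def fit_hybrid(curve: TimeActivityCurve, poly_degree: int = 2) -> HybridFit:
    """Piecewise uptake/clearance fit for organs with an uptake phase.

    The junction ``t_peak`` is the time of the maximum observed value
    (earliest on ties); the tail is mono-exponential on points at or after
    the peak, and the rising piece is a degree-``poly_degree`` polynomial
    constrained to meet the tail at ``t_peak``.  Monotone-decreasing data
    degenerate to the plain mono-exponential fit.
    """
    if poly_degree not in (1, 2, 3):
        raise ValueError("poly_degree must be 1, 2 or 3")
    if curve.times_h.size < 4:
        raise InsufficientDataError(
            f"{curve.organ}: hybrid fit needs >= 4 points, got {curve.times_h.size}"
        )
    i_peak = int(np.argmax(curve.values))
    t_peak = float(curve.times_h[i_peak])
    if i_peak == curve.times_h.size - 1:
        raise FitFailureError(
            f"{curve.organ}: peak at the last time point, no tail to fit; "
            "use fit_monoexp instead"
        )
    tail_t = curve.times_h[i_peak:]
    tail_v = curve.values[i_peak:]
    mask = tail_v > 0
    if mask.sum() < 2:
        raise InsufficientDataError(f"{curve.organ}: tail has < 2 positive points")
    a0, lam = _fit_tail(tail_t[mask], tail_v[mask])
    tail = MonoExpFit(
        a0=a0,
        _lambda_eff=lam,
        organ=curve.organ,
        nuclide=curve.nuclide,
        decay_corrected=curve.decay_corrected,
        t_last=float(curve.times_h[-1]),
    )
    if i_peak == 0:
        coeffs = np.empty(0)
    else:
        rise_t = curve.times_h[: i_peak + 1]
        rise_v = curve.values[: i_peak + 1]
        dt = rise_t - t_peak
        a_peak = tail.predict(t_peak)
        design = np.column_stack([dt**k for k in range(1, poly_degree + 1)])
        coeffs, *_ = np.linalg.lstsq(design, rise_v - a_peak, rcond=None)
    fit = HybridFit(
        tail=tail,
        t_peak=t_peak,
        poly_coeffs=np.asarray(coeffs, dtype=float),
        organ=curve.organ,
        nuclide=curve.nuclide,
        decay_corrected=curve.decay_corrected,
        t_last=float(curve.times_h[-1]),
    )
    pred = fit.predict(curve.times_h)
    fit.residual_rms = float(np.sqrt(np.mean((pred - curve.values) ** 2)))
    return fit


@dataclass(frozen=True)
class CumulatedActivity:
    """Time integral of an activity curve.

    ``value_s`` is in "fraction-seconds": Bq·s in the organ per Bq injected
    when the fitted curve is the injected-activity *fraction*; for curves in
    %IA the integrand is divided by 100 first.
    """

    organ: str
    nuclide: Radionuclide | None
    value_s: float
    t_lo_h: float
    t_hi_h: float
    method: str

    def __post_init__(self) -> None:
        if self.value_s < 0:
            raise ValueError("cumulated activity must be nonnegative")


def cumulated_activity(
    fit: KineticFit,
    t_lo_h: float = 0.0,
    t_hi_h: float = math.inf,
    curve_unit: str = "fraction",
    flat_back_from_h: float | None = None,
) -> CumulatedActivity:
    """Adaptive-quadrature integral of a fitted curve, with analytic tail.

    For ``t_hi = inf`` the exponential tail beyond the last finite node is
    added in closed form as ``A(t_node)/lambda_eff``.  ``flat_back_from_h``
    implements the early-time convention A(t < t0) := A(t0) for organs whose
    uptake phase was not sampled.  ``curve_unit`` is ``"fraction"`` (values
    are injected-activity fractions) or ``"percent"`` (values are %IA).
    """
    if not t_lo_h < t_hi_h:
        raise ValueError("need t_lo < t_hi")
    if t_lo_h < 0:
        raise ValueError("t_lo must be >= 0")
    scale = 1.0 if curve_unit == "fraction" else 0.01
    total_h = 0.0
    lo = t_lo_h
    if flat_back_from_h is not None and lo < flat_back_from_h:
        flat_hi = min(flat_back_from_h, t_hi_h)
        total_h += float(fit.predict(flat_back_from_h)) * (flat_hi - lo)
        lo = flat_hi
    if lo < t_hi_h:
        node = max(fit.t_last, getattr(fit, "t_peak", 0.0), lo)
        breaks = sorted({lo, *(p for p in (getattr(fit, "t_peak", None),) if p)})
        if math.isinf(t_hi_h):
            finite_hi = node
        else:
            finite_hi = min(t_hi_h, math.inf)
        if finite_hi > lo:
            interior = [b for b in breaks if lo < b < finite_hi]
            val, _ = integrate.quad(
                lambda tt: float(fit.predict(tt)),
                lo,
                finite_hi,
                points=interior or None,
                epsabs=0.0,
                epsrel=1e-10,
                limit=200,
            )
            total_h += val
        if math.isinf(t_hi_h):
            total_h += float(fit.predict(finite_hi)) / fit.lambda_eff
    return CumulatedActivity(
        organ=fit.organ,
        nuclide=fit.nuclide,
        value_s=total_h * H_TO_S * scale,
        t_lo_h=t_lo_h,
        t_hi_h=t_hi_h,
        method="adaptive quadrature + analytic exponential tail",
    )


def extrapolate_to_nuclide(fit: KineticFit, target: Radionuclide) -> KineticFit:
    """Swap the physical decay of a fitted curve for another nuclide.

    The biological clearance rate is ``lambda_bio = lambda_eff -
    lambda_phys(source)`` when the fit was made on non-decay-corrected data
    (or ``lambda_eff`` itself on corrected data); the returned fit carries
    the target nuclide's physical decay on top of the same biology and is
    always expressed in the non-decay-corrected convention.  Negative
    ``lambda_bio`` is clamped to zero with a warning.
    """
    if fit.nuclide is None:
        raise ValueError("fit has no source nuclide")
    lam_src = fit.nuclide.decay_constant if not fit.decay_corrected else 0.0
    lam_bio = fit.lambda_eff - lam_src
    clamp = 0.0
    if lam_bio < 0:
        warnings.warn(
            f"{fit.organ}: biological rate {lam_bio:.3e}/h < 0; clamped to 0",
            stacklevel=2,
        )
        logger.warning("%s: lambda_bio clamped from %.3e to 0", fit.organ, lam_bio)
        clamp = -lam_bio
        lam_bio = 0.0
    delta = (target.decay_constant - lam_src) + clamp
    if isinstance(fit, MonoExpFit):
        out: KineticFit = MonoExpFit(
            a0=fit.a0,
            _lambda_eff=lam_bio + target.decay_constant,
            organ=fit.organ,
            nuclide=target,
            decay_corrected=False,
            residual_rms=fit.residual_rms,
            t_last=fit.t_last,
        )
        return out
    return DecayShiftedFit(
        base=fit,
        delta_lambda=delta,
        organ=fit.organ,
        nuclide=target,
        decay_corrected=False,
        residual_rms=fit.residual_rms,
        t_last=fit.t_last,
    )
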