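"""Isotopic exchange kinetics and the 1-minute exchangeable P value.

After carrier-free tracer is injected into a soil suspension at
steady state, the fraction of radioactivity remaining in solution
declines as

    r(t)/R = m * [t + m**(1/n)]**(-n) + ratio * c_p / pi_total

where ``m`` approximates the fraction remaining after one minute,
``n`` the rate of disappearance, and the additive term is the
equilibrium floor set by the solution-to-total inorganic P ratio.
The exchangeable pool within one minute is

    E1min = ratio * c_p * R / r(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateSeriesError,
    FitFailureError,
    InvalidParameterError,
)

__all__ = [
    "KineticsSeries",
    "KineticsFit",
    "predict_r_ratio",
    "fit_kinetics",
    "e_value_1min",
    "e_value_from_fit",
]

#: box constraints used by the nonlinear fit
M_BOUNDS = (1e-6, 1.0)
N_BOUNDS = (1e-6, 0.999)

#: relative slack allowed for non-monotone noise in an observed series
MONOTONE_RTOL = 0.10


@dataclass(frozen=True)
class KineticsSeries:
    """Observed decline of solution radioactivity after tracer injection.

    Parameters
    ----------
    times : array
        Sampling times in minutes, strictly increasing, all > 0.
    r_t : array
        Remaining solution activity at each time (Bq per mL filtrate).
    r_injected : float
        Introduced activity R (Bq per mL suspension).
    c_p : float
        Solution P concentration (mg P per L), measured after the last
        sampling.
    pi_total : float
        Total inorganic P basis (mg P per kg soil): soil total P minus
        organic P plus the applied fertilizer dose.
    ratio : float
        Solution-to-soil ratio (L per kg), default 10.
    """

    sample_id: str
    times: np.ndarray
    r_t: np.ndarray
    r_injected: float
    c_p: float
    pi_total: float
    ratio: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "r_t", np.asarray(self.r_t, dtype=float))
        t, r = self.times, self.r_t
        if t.size != r.size:
            raise InvalidParameterError("times and r_t must have equal length")
        if t.size and (np.any(t <= 0) or np.any(np.diff(t) <= 0)):
            raise InvalidParameterError("times must be strictly increasing and > 0")
        if np.any(r <= 0) or np.any(r > self.r_injected):
            raise InvalidParameterError("r_t must satisfy 0 < r_t <= r_injected")
        if self.pi_total <= 0:
            raise InvalidParameterError("pi_total must be > 0")
        if self.c_p < 0:
            raise InvalidParameterError("c_p must be >= 0")
        rises = np.diff(r) > MONOTONE_RTOL * r[:-1] if r.size > 1 else np.array([])
        if np.any(rises):
            raise InvalidParameterError(
                "r_t must be non-increasing in time within measurement tolerance"
            )

    @property
    def r_ratio(self) -> np.ndarray:
        return self.r_t / self.r_injected

    @property
    def floor(self) -> float:
        return self.ratio * self.c_p / self.pi_total


@dataclass(frozen=True)
class KineticsFit:
    m: float
    n: float
    e1min: float
    rss: float
    converged: bool
    n_iter: int
    residuals: np.ndarray = field(default=None, repr=False, compare=False)


def _check_params(m, n):
    if not (M_BOUNDS[0] < m <= M_BOUNDS[1]):
        raise InvalidParameterError(f"m must lie in ({M_BOUNDS[0]}, {M_BOUNDS[1]}], got {m}")
    if not (N_BOUNDS[0] < n < 1.0):
        raise InvalidParameterError(f"n must lie in ({N_BOUNDS[0]}, 1), got {n}")


def predict_r_ratio(t, m, n, c_p, pi_total, ratio=10.0):
    """Modeled fraction of injected activity remaining in solution."""
    _check_params(m, n)
    if pi_total <= 0:
        raise InvalidParameterError(f"pi_total must be > 0, got {pi_total}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    out = m * (t + m ** (1.0 / n)) ** (-n) + ratio * c_p / pi_total
    return out if out.ndim else float(out)


def _initial_guess(series: KineticsSeries):
    y = series.r_ratio - series.floor
    m0 = float(np.clip(y[0], 0.01, 0.99))
    n0 = 0.4
    if series.times.size >= 3 and np.all(y[:3] > 0):
        slope, _ = np.polyfit(np.log(series.times[:3]), np.log(y[:3]), 1)
        n0 = float(np.clip(-slope, 0.05, 0.95))
    if not np.isfinite(m0) or not np.isfinite(n0):
        m0, n0 = 0.3, 0.4
    return m0, n0


def fit_kinetics(series: KineticsSeries, init=None, max_iter: int = 500) -> KineticsFit:
    """Least-squares estimate of (m, n) with c_p and pi_total held fixed.

    Raises
    ------
    DegenerateSeriesError
        If the observed series carries no decline (constant r_t).
    FitFailureError
        If the optimiser fails to converge within ``max_iter`` function
        evaluations.
    """
    if series.times.size < 3:
        raise InvalidParameterError("need >= 3 time points to fit kinetics")
    obs = series.r_ratio
    if np.ptp(obs) == 0:
        raise DegenerateSeriesError("all r_t identical; no kinetics signal")

    m0, n0 = init if init is not None else _initial_guess(series)

    def resid(p):
        m, n = p
        return m * (series.times + m ** (1.0 / n)) ** (-n) + series.floor - obs

    sol = least_squares(
        resid,
        x0=[m0, n0],
        bounds=([M_BOUNDS[0], N_BOUNDS[0]], [M_BOUNDS[1], N_BOUNDS[1]]),
        xtol=1e-12,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_iter,
    )
    if not sol.success:
        raise FitFailureError(f"kinetics fit did not converge: {sol.message}")
    m, n = float(sol.x[0]), float(sol.x[1])
    r1_ratio = predict_r_ratio(1.0, m, n, series.c_p, series.pi_total, series.ratio)
    e1 = e_value_1min(series.c_p, 1.0, r1_ratio, series.ratio)
    return KineticsFit(
        m=m,
        n=n,
        e1min=e1,
        rss=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        residuals=sol.fun,
    )


def e_value_1min(c_p: float, R: float, r1: float, ratio: float = 10.0) -> float:
    """Isotopically exchangeable P within one minute (mg P per kg soil)."""
    if r1 <= 0:
        raise InvalidParameterError(f"r1 must be > 0, got {r1}")
    if r1 > R:
        raise InvalidParameterError(f"r1 ({r1}) cannot exceed R ({R})")
    if c_p < 0:
        raise InvalidParameterError(f"c_p must be >= 0, got {c_p}")
    return ratio * c_p * R / r1


def e_value_from_fit(fit: KineticsFit, series: KineticsSeries, source: str = "fitted") -> float:
    """E1min from a fitted series.

    ``source='fitted'`` evaluates the smoothed model at t = 1 min;
    ``source='raw'`` uses the observed r(1) when the first sampling is
    at one minute.
    """
    if not fit.converged:
        raise FitFailureError("cannot compute E1min from a non-converged fit")
    if source == "fitted":
        r1_ratio = predict_r_ratio(1.0, fit.m, fit.n, series.c_p, series.pi_total, series.ratio)
        return e_value_1min(series.c_p, 1.0, r1_ratio, series.ratio)
    if source == "raw":
        if not np.isclose(series.times[0], 1.0):
            warnings.warn(
                f"first sampling at t={series.times[0]} min used as r(1)", stacklevel=2
            )
        return e_value_1min(series.c_p, series.r_injected, float(series.r_t[0]), series.ratio)
    raise InvalidParameterError(f"unknown e_value source {source!r}")
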