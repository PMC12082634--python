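"""Forward model and fitting for fluorescence scrambling assays.

Dithionite assay: a membrane-impermeant reductant converts outer-leaflet
NBD-labelled lipids to a non-fluorescent form.  Without scrambling only the
outer half of the labels is lost (plateau 0.50); a scramblase ferries inner
labels outward until fluorescence is gone.  BSA back-extraction assay: BSA
quenches at most 50% of accessible NBD fluorescence, so the plateaus are
0.75 (no scrambling) and 0.50 (complete scrambling).

The forward model is a two-compartment kinetic scheme for the label
fractions N_out, N_in and the quenched pool Q:

    dN_out/dt = k_scr (N_in - N_out) - k_q N_out
    dN_in/dt  = k_scr (N_out - N_in)
    dQ/dt     = k_q N_out

with fluorescence F = N_out + N_in + c Q, where c = 0 (dithionite, reacted
labels dark) or c = 0.5 (BSA, bound labels half-quenched).  Quenching acts
only after the quencher addition time.  Measured decays are fitted with the
constrained double exponential F(t) = F_s exp(-t/tau_s) + F_f exp(-t/tau_f),
F_s + F_f = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit

logger = logging.getLogger("scramblekit")

__all__ = [
    "AssayModel",
    "AssayCurve",
    "DoubleExpFit",
    "simulate_assay",
    "normalize_and_trim",
    "fit_double_exponential",
    "expected_plateau",
]

_QUENCHED_FLUORESCENCE = {"dithionite": 0.0, "bsa": 0.5}


@dataclass
class AssayModel:
    """Parameters of the two-compartment scrambling-assay model.

    Rates are in 1/s.  ``nonscrambling_fraction`` models vesicles without a
    reconstituted scramblase (their labels follow the k_scr = 0 kinetics).
    """

    mode: str = "dithionite"
    k_scr: float = 0.0
    k_q: float = 0.1
    outer_fraction: float = 0.5
    addition_time_s: float = 0.0
    nonscrambling_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.mode = self.mode.lower()
        if self.mode not in _QUENCHED_FLUORESCENCE:
            raise ValueError("mode must be 'dithionite' or 'bsa'")
        if self.k_scr < 0 or self.k_q < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.outer_fraction <= 1.0:
            raise ValueError("outer fraction must lie in [0, 1]")
        if not 0.0 <= self.nonscrambling_fraction <= 1.0:
            raise ValueError("non-scrambling fraction must lie in [0, 1]")


@dataclass
class AssayCurve:
    """Normalized fluorescence decay: F = 1 before quencher addition."""

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.times) != len(self.fluorescence):
            raise ValueError("times and fluorescence lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")


def _population_curve(k_scr: float, k_q: float, out0: float, t: np.ndarray, c: float) -> np.ndarray:
    """F(t) for one vesicle population, quenching active from t = 0."""
    a = np.array([[-(k_scr + k_q), k_scr], [k_scr, -k_scr]])
    y0 = np.array([out0, 1.0 - out0])
    f = np.empty(len(t))
    for i, ti in enumerate(t):
        y = expm(a * ti) @ y0
        unquenched = y.sum()
        f[i] = unquenched + c * (1.0 - unquenched)
    return f


def simulate_assay(model: AssayModel, times: np.ndarray) -> AssayCurve:
    """Solve the forward model at the given times (s).

    Total label is conserved exactly (unquenched + quenched = 1); F is 1
    before the quencher addition time and monotone non-increasing after.
    """
    t = np.asarray(times, dtype=float)
    c = _QUENCHED_FLUORESCENCE[model.mode]
    f = np.ones(len(t))
    after = t >= model.addition_time_s
    trel = t[after] - model.addition_time_s
    f_scr = _population_curve(model.k_scr, model.k_q, model.outer_fraction, trel, c)
    if model.nonscrambling_fraction > 0:
        f_ns = _population_curve(0.0, model.k_q, model.outer_fraction, trel, c)
        w = model.nonscrambling_fraction
        f[after] = (1 - w) * f_scr + w * f_ns
    else:
        f[after] = f_scr
    return AssayCurve(times=t, fluorescence=f)


def normalize_and_trim(
    times: np.ndarray, intensity: np.ndarray, addition_time: float
) -> AssayCurve:
    """Divide by the pre-addition mean, drop pre-addition points, and shift
    the time origin to the addition, so the decay starts at (0, ~1)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensity, dtype=float)
    pre = t < addition_time
    if not pre.any():
        raise ValueError("no data points before the quencher addition time")
    baseline = y[pre].mean()
    if baseline <= 0:
        raise ValueError("non-positive pre-addition baseline")
    post = ~pre
    return AssayCurve(times=t[post] - addition_time, fluorescence=y[post] / baseline)


@dataclass
class DoubleExpFit:
    """Constrained double-exponential fit, F_s + F_f = 1, tau_s >= tau_f."""

    f_slow: float
    f_fast: float
    tau_slow: float
    tau_fast: float
    covariance: np.ndarray = field(default_factory=lambda: np.full((3, 3), np.nan))
    residual_norm: float = np.nan
    degenerate: bool = False

    def __post_init__(self) -> None:
        if abs(self.f_slow + self.f_fast - 1.0) > 1e-9:
            raise ValueError("prefactors must sum to 1")
        if not (self.tau_slow >= self.tau_fast > 0):
            raise ValueError("need tau_slow >= tau_fast > 0")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f_slow * np.exp(-t / self.tau_slow) + self.f_fast * np.exp(
            -t / self.tau_fast
        )


def _model(t: np.ndarray, fs: float, tau_a: float, tau_b: float) -> np.ndarray:
    return fs * np.exp(-t / tau_a) + (1.0 - fs) * np.exp(-t / tau_b)


def fit_double_exponential(curve: AssayCurve) -> DoubleExpFit:
    """Nonlinear least squares with the sum-to-one constraint built into the
    parameterization; multi-start over five log-spaced tau initializations.

    Fits where the two time constants collapse (pure single exponential) are
    returned with ``degenerate=True`` rather than rejected.
    """
    t = curve.times
    y = curve.fluorescence
    if len(t) < 8:
        raise ValueError("need at least 8 points to fit a double exponential")
    span = max(t[-1] - t[0], 1e-12)
    taus = np.logspace(np.log10(span / 100.0), np.log10(span), 5)
    best = None
    best_ssr = np.inf
    for tau0 in taus:
        p0 = [0.5, tau0, tau0 / 10.0]
        try:
            popt, pcov = curve_fit(
                _model,
                t,
                y,
                p0=p0,
                bounds=([0.0, 1e-12, 1e-12], [1.0, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        ssr = float(((y - _model(t, *popt)) ** 2).sum())
        if ssr < best_ssr:
            best, best_ssr = (popt, pcov), ssr
    if best is None:
        raise RuntimeError(
            "double-exponential fit failed to converge from all starts; "
            f"data range [{y.min():.3g}, {y.max():.3g}] over {len(t)} points"
        )
    (fs, tau_a, tau_b), pcov = best
    if tau_a >= tau_b:
        f_slow, tau_slow, tau_fast = fs, tau_a, tau_b
    else:
        f_slow, tau_slow, tau_fast = 1.0 - fs, tau_b, tau_a
    degenerate = (
        tau_slow / tau_fast < 1.2 or f_slow < 1e-3 or f_slow > 1.0 - 1e-3
    )
    if degenerate:
        logger.info("double-exponential fit is degenerate (single-exponential family)")
    return DoubleExpFit(
        f_slow=float(f_slow),
        f_fast=float(1.0 - f_slow),
        tau_slow=float(tau_slow),
        tau_fast=float(tau_fast),
        covariance=pcov,
        residual_norm=float(np.sqrt(best_ssr)),
        degenerate=degenerate,
    )


def expected_plateau(mode: str, scrambling: str) -> float:
    """Closed-form long-time fluorescence plateaus of the two assays."""
    table = {
        ("dithionite", "none"): 0.50,
        ("dithionite", "complete"): 0.0,
        ("bsa", "none"): 0.75,
        ("bsa", "complete"): 0.50,
    }
    key = (mode.lower(), scrambling.lower())
    if key not in table:
        raise ValueError(f"unknown combination {key}")
    return table[key]
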