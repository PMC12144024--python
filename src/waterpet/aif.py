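"""Arterial input function (AIF) handling.

The arterial blood activity curve C_A(t) drives the one-tissue-compartment
model.  A measured curve differs from the input the brain actually sees by a
transit-time *delay* and by *dispersion* — smearing in the sampling line,
modelled as convolution with a monoexponential kernel (1/tau) exp(-t/tau).

This module provides:

* a gamma-variate bolus generator (:func:`make_aif`) standing in for online
  arterial sampling,
* calibration against discrete blood samples,
* the delay and dispersion operators and their inverses,
* joint delay/dispersion estimation by fitting the kinetic model to the
  whole-brain time-activity curve over a grid of dispersion constants, with
  delay as a continuous fit parameter; the grid point with the lowest
  residual sum of squares wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._conv import dispersion_conv

__all__ = [
    "InputFunction",
    "DelayDispersionFit",
    "make_aif",
    "calibrate_input",
    "apply_dispersion",
    "correct_dispersion",
    "apply_delay",
    "estimate_delay_dispersion",
    "read_aif_csv",
    "write_aif_csv",
]


@dataclass(frozen=True)
class InputFunction:
    """Finely sampled arterial activity curve with its correction state.

    Attributes
    ----------
    times : array, s — strictly increasing fine grid starting at 0.
    activity : array, kBq/mL.
    delay : s — accumulated delay shift applied to this curve.
    dispersion_tau : s — accumulated dispersion applied (>= 0).
    calibration_factor : unitless scale applied by calibration.
    """

    times: np.ndarray
    activity: np.ndarray
    delay: float = 0.0
    dispersion_tau: float = 0.0
    calibration_factor: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.ndim != 1 or t.shape != a.shape:
            raise ValueError("times and activity must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("activity must be finite")
        if self.dispersion_tau < 0:
            raise ValueError("dispersion_tau must be >= 0")
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "activity", a)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation; 0 outside the support."""
        return np.interp(t, self.times, self.activity, left=0.0, right=0.0)


@dataclass(frozen=True)
class DelayDispersionFit:
    """Result of the grid search over dispersion time constants."""

    tau: float
    delay: float
    rss: float
    per_tau_rss: pd.DataFrame  # columns: tau_s, delay_s, rss
    params: object = None  # kinetic parameters at the optimum

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tau_s": self.tau,
            "delay_s": self.delay,
            "rss": self.rss,
            "per_tau": self.per_tau_rss.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_aif(
    dose_scale: float = 50.0,
    shape_params: dict | None = None,
    grid: np.ndarray | None = None,
) -> InputFunction:
    """Generate a bolus-shaped arterial input curve.

    The curve is a gamma-variate first pass plus a slowly decaying
    recirculation plateau:

        g(t) = dose_scale * ((t-t0)/(alpha*beta))^alpha * exp(alpha - (t-t0)/beta)
        r(t) = recirc_frac * dose_scale * (1 - exp(-(t-t0)/recirc_rise))
                 * exp(-(t-t0)/recirc_decay)

    for t > t0, both zero before the onset t0.  The gamma-variate peaks at
    t0 + alpha*beta with value ``dose_scale`` (kBq/mL).

    Parameters
    ----------
    dose_scale : peak first-pass activity, kBq/mL (>= 0).
    shape_params : overrides for {t0, alpha, beta, recirc_frac, recirc_rise,
        recirc_decay}.
    grid : fine time grid, s; strictly increasing, starting at 0.
        Default 0–400 s at 0.5 s spacing.
    """
    if dose_scale < 0:
        raise ValueError("dose_scale must be >= 0")
    p = {
        "t0": 15.0,
        "alpha": 3.0,
        "beta": 5.0,
        "recirc_frac": 0.12,
        "recirc_rise": 25.0,
        "recirc_decay": 600.0,
    }
    if shape_params:
        p.update(shape_params)
    if grid is None:
        grid = np.arange(0.0, 400.0 + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if grid[0] != 0.0:
        raise ValueError("grid must start at 0")

    s = np.clip(grid - p["t0"], 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        bolus = np.where(
            s > 0,
            (s / (p["alpha"] * p["beta"])) ** p["alpha"] * np.exp(p["alpha"] - s / p["beta"]),
            0.0,
        )
    recirc = np.where(
        s > 0,
        p["recirc_frac"] * (1.0 - np.exp(-s / p["recirc_rise"])) * np.exp(-s / p["recirc_decay"]),
        0.0,
    )
    activity = dose_scale * (bolus + recirc)
    return InputFunction(grid, activity)


def calibrate_input(
    curve: InputFunction, samples: list[tuple[float, float]]
) -> InputFunction:
    """Scale the curve to discrete well-counter blood samples.

    The factor is the mean over samples of (sample activity / curve activity
    interpolated at the sample time).
    """
    if not samples:
        raise ValueError("at least one calibration sample is required")
    ratios = []
    for t_s, a_s in samples:
        if t_s < curve.times[0] or t_s > curve.times[-1]:
            raise ValueError(f"sample time {t_s} s outside curve support")
        c = float(curve(t_s))
        if c <= 0:
            raise ValueError(f"curve activity non-positive at sample time {t_s} s")
        ratios.append(a_s / c)
    factor = float(np.mean(ratios))
    return replace(
        curve,
        activity=curve.activity * factor,
        calibration_factor=curve.calibration_factor * factor,
    )


def apply_dispersion(curve: InputFunction, tau: float) -> InputFunction:
    """Convolve the curve with the kernel (1/tau) exp(-t/tau)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return curve
    dispersed = dispersion_conv(curve.times, curve.activity, tau)
    return replace(curve, activity=dispersed, dispersion_tau=curve.dispersion_tau + tau)


def correct_dispersion(
    curve: InputFunction, tau: float, smooth_window: int = 3
) -> InputFunction:
    """Undo monoexponential dispersion via C_true = C_meas + tau * dC_meas/dt.

    A moving-average pre-smoothing (default 3 points) tames the numerical
    derivative on measured curves; pass ``smooth_window=0`` to disable.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return curve
    a = curve.activity
    if smooth_window and smooth_window > 1:
        pad = smooth_window // 2
        kernel = np.ones(smooth_window) / smooth_window
        a = np.convolve(np.pad(a, pad, mode="edge"), kernel, mode="valid")[: a.size]
    deriv = np.gradient(a, curve.times)
    corrected = a + tau * deriv
    return replace(
        curve, activity=corrected, dispersion_tau=max(curve.dispersion_tau - tau, 0.0)
    )


def apply_delay(curve: InputFunction, delta: float) -> InputFunction:
    """Shift the curve later in time by ``delta`` s (earlier if negative).

    The shifted activity is ``a(t - delta)`` by linear interpolation; regions
    shifted in from outside the support are filled with 0.
    """
    shifted = np.interp(curve.times - delta, curve.times, curve.activity, left=0.0, right=0.0)
    return replace(curve, activity=shifted, delay=curve.delay + delta)


def estimate_delay_dispersion(
    wb_tac,
    curve: InputFunction,
    tau_grid: np.ndarray | None = None,
    delay_bounds: tuple[float, float] = (-15.0, 15.0),
) -> DelayDispersionFit:
    """Estimate dispersion tau and delay from the whole-brain TAC.

    For each tau on the grid the curve is dispersed (forward modelling — no
    deconvolution of measured data) and the one-tissue model is fitted to the
    whole-brain TAC with K1, k2, VA and delay free.  The tau with the lowest
    residual sum of squares is returned together with its fitted delay and
    the full RSS-vs-tau table.

    Parameters
    ----------
    wb_tac : TimeActivityCurve on the acquisition schedule.
    curve : the (calibrated) measured input function.
    tau_grid : dispersion constants to search, s; default 0–20 s step 1 s.
    """
    from .kinetics import fit_regional  # deferred to avoid an import cycle

    if tau_grid is None:
        tau_grid = np.arange(0.0, 21.0, 1.0)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("tau_grid must be non-empty")
    if np.any(tau_grid < 0):
        raise ValueError("tau_grid values must be >= 0")

    rows = []
    fits: dict[float, object] = {}
    for tau in tau_grid:
        dispersed = apply_dispersion(curve, float(tau))
        try:
            params = fit_regional(
                wb_tac, dispersed, fit_delay=True, delay_bounds=delay_bounds
            )
        except RuntimeError:
            rows.append({"tau_s": float(tau), "delay_s": np.nan, "rss": np.nan})
            continue
        fits[float(tau)] = params
        rows.append({"tau_s": float(tau), "delay_s": params.delay, "rss": params.rss})
    table = pd.DataFrame(rows)
    if table["rss"].isna().all():
        raise RuntimeError("kinetic fit failed at every tau on the grid")
    best = table.loc[table["rss"].idxmin()]
    best_params = fits[float(best["tau_s"])]
    return DelayDispersionFit(
        tau=float(best["tau_s"]),
        delay=float(best["delay_s"]),
        rss=float(best["rss"]),
        per_tau_rss=table,
        params=best_params,
    )


# -- CSV round trip --------------------------------------------------------

def write_aif_csv(curve: InputFunction, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": curve.times, "activity_kBq_per_mL": curve.activity}
    ).to_csv(path, index=False)


def read_aif_csv(path: str | Path) -> InputFunction:
    df = pd.read_csv(path)
    return InputFunction(
        df["time_s"].to_numpy(float), df["activity_kBq_per_mL"].to_numpy(float)
    )
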