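"""Exponential convolution on a fine time grid.

Both the tissue impulse response (``exp(-k2 t)``) and the sampling-line
dispersion kernel (``(1/tau) exp(-t/tau)``) reduce to the same primitive:
convolution of a sampled curve with a decaying exponential.  The input is
treated as piecewise linear between grid points and the convolution integral
is evaluated exactly on each interval, which gives a stable one-pass
recursion that degrades gracefully for kernels much narrower than the grid
step (tau -> 0 recovers the identity).
"""

from __future__ import annotations

import numpy as np

__all__ = ["expconv", "dispersion_conv"]


def expconv(times: np.ndarray, values: np.ndarray, rate: float) -> np.ndarray:
    """Return ``y(t) = \\int_0^t values(s) * exp(-rate * (t - s)) ds``.

    ``rate`` is in 1/s on the same time axis as ``times``.  For ``rate == 0``
    this is the running integral of the curve.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if rate < 0:
        raise ValueError("rate must be non-negative")

    dt = np.diff(t)
    y = np.empty_like(c)
    y[0] = 0.0
    if rate == 0.0:
        np.cumsum(0.5 * dt * (c[1:] + c[:-1]), out=y[1:])
        return y

    u = rate * dt
    e = np.exp(-u)
    # Exact integral of a linear segment against exp(-rate (t_i - s)):
    #   contribution = c[i-1] * (j0 - j1) + c[i] * j1, all divided by rate.
    j0 = 1.0 - e
    j1 = 1.0 - (1.0 - e) / u
    w_prev = (j0 - j1) / rate
    w_curr = j1 / rate
    b = c[:-1] * w_prev + c[1:] * w_curr
    if np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
        # Uniform grid: the recursion y_i = E y_{i-1} + b_i is an IIR filter.
        from scipy.signal import lfilter

        y[1:] = lfilter([1.0], [1.0, -e[0]], b)
    else:
        for i in range(1, t.size):
            y[i] = e[i - 1] * y[i - 1] + b[i - 1]
    return y


def dispersion_conv(times: np.ndarray, values: np.ndarray, tau: float) -> np.ndarray:
    """Convolve with the normalized kernel ``(1/tau) exp(-t/tau)``.

    ``tau == 0`` returns the input unchanged (delta kernel).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if tau == 0.0:
        return np.asarray(values, dtype=float).copy()
    return expconv(times, values, 1.0 / tau) / tau
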