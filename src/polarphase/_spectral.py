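"""Shared utilities for periodic fields on a uniform angular grid.

All fields live on the grid ``theta_m = 2*pi*m/n`` and are treated as
trigonometric interpolants, so differentiation, rotation and off-grid
evaluation are spectrally accurate.
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap(angle):
    """Wrap angles to the interval (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    w = (a + np.pi) % TWO_PI - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def circular_grid(n: int) -> np.ndarray:
    """Uniform periodic grid theta_m = 2*pi*m/n, m = 0..n-1."""
    return TWO_PI * np.arange(n) / n


def wavenumbers(n: int) -> np.ndarray:
    """Integer wavenumbers matching numpy's FFT ordering."""
    return np.fft.fftfreq(n, d=1.0 / n)


def spectral_derivative(values: np.ndarray, order: int = 1) -> np.ndarray:
    """Derivative along the last axis of periodic grid samples."""
    n = values.shape[-1]
    k = np.fft.rfftfreq(n, d=1.0 / n)
    factor = (1j * k) ** order
    if order % 2 == 1 and n % 2 == 0:
        factor[-1] = 0.0  # odd derivative of the Nyquist mode vanishes
    return np.fft.irfft(np.fft.rfft(values, axis=-1) * factor, n=n, axis=-1)


def rotate(values: np.ndarray, shift: float) -> np.ndarray:
    """Samples of ``f(theta - shift)`` given samples of ``f`` (last axis)."""
    n = values.shape[-1]
    k = np.fft.rfftfreq(n, d=1.0 / n)
    return np.fft.irfft(np.fft.rfft(values, axis=-1) * np.exp(-1j * k * shift), n=n, axis=-1)


def trig_eval(values: np.ndarray, x) -> np.ndarray:
    """Evaluate the trigonometric interpolant of grid samples at angles x.

    ``values`` is 1-D (length n); ``x`` may have any shape.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[-1]
    xs = np.asarray(x, dtype=float)
    flat = xs.ravel()
    c = np.fft.rfft(v)
    k = np.arange(1, (n + 1) // 2)
    kx = np.outer(k, flat)
    out = np.full(flat.shape, c[0].real)
    out += 2.0 * (np.cos(kx).T @ c[1 : k.size + 1].real - np.sin(kx).T @ c[1 : k.size + 1].imag)
    if n % 2 == 0:
        out += c[n // 2].real * np.cos(0.5 * n * flat)
    out /= n
    out = out.reshape(xs.shape)
    if np.ndim(x) == 0:
        return float(out)
    return out


def trig_interp_matrix(n: int, x: np.ndarray) -> np.ndarray:
    """Matrix M with (M @ v)[p] = trig_eval(v, x[p]) for grid samples v."""
    x = np.asarray(x, dtype=float)
    theta = circular_grid(n)
    delta = x[:, None] - theta[None, :]
    k = np.arange(1, (n + 1) // 2)
    kernel = np.ones_like(delta)
    kernel += 2.0 * np.sum(np.cos(k[:, None, None] * delta[None, :, :]), axis=0)
    if n % 2 == 0:
        kernel += np.cos(0.5 * n * delta)
    return kernel / n


def second_derivative_matrix(n: int) -> np.ndarray:
    """Dense circulant matrix of the spectral second derivative."""
    k = wavenumbers(n)
    first_col = np.fft.ifft(-(k**2)).real
    idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
    return first_col[idx]


def cosine_coefficient(values: np.ndarray, k: int) -> float:
    """(1/2pi) * integral of values * cos(k theta), by periodic trapezoid."""
    n = values.shape[-1]
    return float(np.mean(values * np.cos(k * circular_grid(n))))


def sine_coefficient(values: np.ndarray, k: int) -> float:
    """(1/2pi) * integral of values * sin(k theta), by periodic trapezoid."""
    n = values.shape[-1]
    return float(np.mean(values * np.sin(k * circular_grid(n))))


def periodic_integral(values: np.ndarray) -> float:
    """Integral over [0, 2pi) of a periodic grid function (trapezoid rule)."""
    n = values.shape[-1]
    return float(np.sum(values) * TWO_PI / n)
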