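"""Apparent and molecular brightness, the detector S-factor, and
brightness-based corrections.

An analog confocal detector adds shot noise whose variance grows
linearly with the mean signal; the slope is the S-factor.  The apparent
brightness of the fluorescent particles,

    B = (sigma^2 - sigma0^2) / I,

mixes molecular fluctuations with that shot noise.  Subtracting the
molecular part (the ACF amplitude times I^2) from the pixel variance
isolates the shot noise, whose regression against intensity yields S;
the molecular brightness Q = (B - S)/S is then gain- and
concentration-independent.  If Q rises (brighter particles, e.g. hubs),
the measured ACF amplitude and immobile fraction are inflated by the
normalized brightness q = Q/Q_min, and are corrected by dividing by q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BrightnessRecord:
    time_s: float
    intensity: float  # mean nuclear intensity (counts)
    variance: float  # nuclear pixel variance (counts^2)
    variance0: float  # zero-intensity (background) variance
    b_app: float = float("nan")
    shot: float = float("nan")
    q_mol: float = float("nan")  # molecular brightness Q
    q_norm: float = float("nan")  # q(t) = Q/Q_min, floored at 1
    corrected: bool = False
    flags: str = ""


def apparent_brightness(intensity: float, variance: float, variance0: float) -> float:
    """B = (sigma^2 - sigma0^2) / I; requires I > 0."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    return (variance - variance0) / intensity


def shot_noise(variance: float, amplitude: float, intensity: float) -> float:
    """Shot-noise variance: pixel variance minus the molecular part A I^2."""
    return variance - amplitude * intensity**2


def estimate_s_factor(shot: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    """Slope and intercept of the line shot = S * I + b.

    Ordinary least squares over the time course; the intercept b is a
    free parameter kept for robustness.  Needs >= 10 points spanning at
    least a 2-fold intensity range.
    """
    shot = np.asarray(shot, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    ok = np.isfinite(shot) & np.isfinite(intensity)
    shot, intensity = shot[ok], intensity[ok]
    if len(shot) < 10:
        raise ValueError("need at least 10 usable time points")
    if intensity.min() <= 0 or intensity.max() / intensity.min() < 2.0:
        raise ValueError("intensity range must span at least 2-fold")
    s, b = np.polyfit(intensity, shot, 1)
    return float(s), float(b)


def molecular_brightness(b_app: float, s_factor: float) -> float:
    """Q = (B - S)/S for an analog detector, clipped at 0."""
    if s_factor <= 0:
        raise ValueError("S must be positive")
    return max((b_app - s_factor) / s_factor, 0.0)


def normalized_q(q_mol: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """q(t) = Q(t)/Q_min with values below 1 set to 1.

    ``reference`` is a boolean window over the time course (the analogue
    of "within nc 14"): Q_min is the maximum Q inside it, so points in
    the window get q = 1 (no correction) and only excursions above the
    reference band are corrected.
    """
    q_mol = np.asarray(q_mol, dtype=float)
    reference = np.asarray(reference, dtype=bool)
    if reference.shape != q_mol.shape:
        raise ValueError("reference window must match the Q series shape")
    if not reference.any():
        raise ValueError("reference window is empty")
    q_min = float(np.nanmax(q_mol[reference]))
    if q_min <= 0:
        return np.ones_like(q_mol)
    return np.maximum(q_mol / q_min, 1.0)


def brightness_correction(q: float, a_old: float, phi_old: float) -> tuple[float, float]:
    """Corrected amplitude and immobile fraction: A/q and phi/q.

    q = 1 is the identity; larger q never increases either value.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    return a_old / q, phi_old / q


def nuclear_moments(frame: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """(mean, variance) of the nuclear pixels of one frame."""
    vals = np.asarray(frame, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("mask is empty")
    return float(vals.mean()), float(vals.var())


def background_variance(frame: np.ndarray, mask: np.ndarray, quantile: float = 0.05) -> float:
    """Variance of the lowest-intensity pixels (zero-intensity variance).

    Uses pixels outside the nuclear mask below the given intensity
    quantile of that region.
    """
    frame = np.asarray(frame, dtype=float)
    outside = frame[~np.asarray(mask, dtype=bool)]
    if outside.size < 100:
        outside = np.sort(frame.ravel())[: max(frame.size // 20, 100)]
    cut = np.quantile(outside, max(quantile, 0.01) * 10)
    low = outside[outside <= cut]
    return float(low.var())
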