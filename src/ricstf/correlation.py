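"""2D spatial auto- and cross-correlation of masked image regions.

The RICS correlation surface is

    G(dx, dy) = < dI_a(x, y) dI_b(x+dx, y+dy) > / (<I_a> <I_b>)

where the averages run only over pixel pairs whose *both* members lie
inside the (nuclear) mask and dI = I - <I>_mask.  The masked estimator
is computed with zero-padded FFTs of the masked fluctuation images,
normalized per lag by the autocorrelation of the mask itself (the count
of valid pixel pairs), which makes it exactly equal to the direct
double-sum definition for arbitrary mask shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lag bins supported by fewer pixel pairs than this are unreliable
MIN_PAIRS = 100

DEFAULT_MAX_LAG = 32


@dataclass
class CorrelationSurface:
    """Correlation values on a lag grid.

    ``values[j, i]`` is G at lag (dx = x_lags[i], dy = y_lags[j]).
    For auto pairs the dy range is [0, L] (negative dy is redundant by
    symmetry); for the cross pair the full [-L, L] range is kept because
    a channel-registration displacement breaks the symmetry.
    """

    values: np.ndarray
    x_lags: np.ndarray
    y_lags: np.ndarray
    pair: str = "gg"  # gg, rr, or gc (cross)
    n_frames: int = 1

    @property
    def is_cross(self) -> bool:
        return self.pair == "gc"

    def at(self, dx: int, dy: int) -> float:
        i = int(np.flatnonzero(self.x_lags == dx)[0])
        j = int(np.flatnonzero(self.y_lags == dy)[0])
        return float(self.values[j, i])

    def fast_axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(dx, G(dx, 0)) cut along the fast scanning axis."""
        j = int(np.flatnonzero(self.y_lags == 0)[0])
        return self.x_lags.copy(), self.values[j].copy()


def _lag_grids(max_lag: int, cross: bool):
    x_lags = np.arange(-max_lag, max_lag + 1)
    y_lags = np.arange(-max_lag if cross else 0, max_lag + 1)
    return x_lags, y_lags


def masked_correlation_2d(
    frame_a: np.ndarray,
    frame_b: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    pair: str = "gg",
    min_pairs: int = MIN_PAIRS,
) -> CorrelationSurface:
    """FFT masked correlation of one frame (pair).

    ``frame_b=None`` computes the autocorrelation of ``frame_a``.  Lags
    with fewer than ``min_pairs`` valid pairs are set to NaN.
    """
    a = np.asarray(frame_a, dtype=float)
    b = a if frame_b is None else np.asarray(frame_b, dtype=float)
    if b.shape != a.shape:
        raise ValueError("frames must share shape")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask must share the frame shape")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("mask is empty")
    mean_a = a[mask].mean()
    mean_b = b[mask].mean()
    da = np.where(mask, a - mean_a, 0.0)
    db = np.where(mask, b - mean_b, 0.0)

    h, w = a.shape
    ph, pw = 2 * h, 2 * w
    fa = np.fft.rfft2(da, s=(ph, pw))
    fb = np.fft.rfft2(db, s=(ph, pw))
    fm = np.fft.rfft2(mask.astype(float), s=(ph, pw))
    # sum_x a(x) b(x + lag)  at index `lag` (negative lags wrap)
    num = np.fft.irfft2(np.conj(fa) * fb, s=(ph, pw))
    cnt = np.fft.irfft2(np.conj(fm) * fm, s=(ph, pw))

    x_lags, y_lags = _lag_grids(max_lag, pair == "gc")
    vals = np.empty((len(y_lags), len(x_lags)))
    ii = np.mod(x_lags, pw)
    jj = np.mod(y_lags, ph)
    num_l = num[np.ix_(jj, ii)]
    cnt_l = np.round(cnt[np.ix_(jj, ii)])
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num_l / cnt_l / (mean_a * mean_b)
    vals[cnt_l < min_pairs] = np.nan
    return CorrelationSurface(vals, x_lags, y_lags, pair=pair)


def direct_correlation_oracle(
    frame_a: np.ndarray,
    frame_b: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    pair: str = "gg",
    min_pairs: int = MIN_PAIRS,
) -> CorrelationSurface:
    """Literal double-sum masked correlation (test oracle, small images).

    Loops over every lag and sums over the pixel pairs with both members
    in the mask; independent of the FFT path.
    """
    a = np.asarray(frame_a, dtype=float)
    b = a if frame_b is None else np.asarray(frame_b, dtype=float)
    if a.shape[0] > 64 or a.shape[1] > 64:
        raise ValueError("oracle is for small images (<= 64 x 64)")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    mean_a = a[mask].mean()
    mean_b = b[mask].mean()
    da = a - mean_a
    db = b - mean_b
    h, w = a.shape
    x_lags, y_lags = _lag_grids(max_lag, pair == "gc")
    vals = np.full((len(y_lags), len(x_lags)), np.nan)
    for j, dy in enumerate(y_lags):
        for i, dx in enumerate(x_lags):
            # overlap windows of (x, y) and (x+dx, y+dy) inside the image
            y0, y1 = max(0, -dy), min(h, h - dy)
            x0, x1 = max(0, -dx), min(w, w - dx)
            if y1 <= y0 or x1 <= x0:
                continue
            m = mask[y0:y1, x0:x1] & mask[y0 + dy : y1 + dy, x0 + dx : x1 + dx]
            count = int(m.sum())
            if count < min_pairs:
                continue
            total = float(
                (da[y0:y1, x0:x1] * db[y0 + dy : y1 + dy, x0 + dx : x1 + dx])[m].sum()
            )
            vals[j, i] = total / count / (mean_a * mean_b)
    return CorrelationSurface(vals, x_lags, y_lags, pair=pair)


def average_surfaces(surfaces: list[CorrelationSurface]) -> CorrelationSurface:
    """Pointwise mean of per-frame surfaces; NaN bins propagate via
    nanmean (a bin missing in every member stays missing)."""
    if not surfaces:
        raise ValueError("no surfaces to average")
    ref = surfaces[0]
    stack = np.stack([s.values for s in surfaces])
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmean(stack, axis=0)
    return CorrelationSurface(
        vals, ref.x_lags.copy(), ref.y_lags.copy(), pair=ref.pair, n_frames=len(surfaces)
    )


def average_group_correlation(
    frames_a: np.ndarray,
    frames_b: np.ndarray | None,
    mask: np.ndarray,
    pair: str = "gg",
    max_lag: int = DEFAULT_MAX_LAG,
) -> CorrelationSurface:
    """Mean correlation surface over the member frames of one group."""
    n = frames_a.shape[0]
    surfaces = []
    for f in range(n):
        fb = None if frames_b is None else frames_b[f]
        surfaces.append(
            masked_correlation_2d(frames_a[f], fb, mask, max_lag=max_lag, pair=pair)
        )
    return average_surfaces(surfaces)
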