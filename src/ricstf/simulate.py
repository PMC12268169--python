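"""Synthetic two-channel raster-scan movies with known ground truth.

The generator emulates the statistical structure that RICS analysis
assumes: fluorescent particles inside disk-shaped nuclei, imaged by a
raster-scanning 3D Gaussian point spread function with realistic pixel
and line timing, and read out by an analog detector whose shot-noise
variance is proportional to the mean signal.

Particle species
----------------
free
    Brownian diffusion with diffusivity ``D`` (default 2 um^2/s).
quasi-immobile (binders)
    A two-state Markov process: bound (strictly immobile) with mean
    dwell 1/k_off, unbound (diffusing with ``D``) with mean dwell
    1/k_on.  The default k_off of 1/frame_time makes binders immobile
    across the correlation lag window (~ max_lag line times) while
    successive frames sample nearly independent binding configurations,
    so the moving-average detrend of the analysis removes the bound pool
    no more than the free pool — mimicking the quasi-immobile chromatin
    binding the method is built to measure.
cobound
    Binders rendered in both channels (green TF co-bound to the
    red-labelled chromatin structure), with the red image displaced by a
    fixed inter-channel registration offset.

Positions are advanced once per scan line: at ~2 um^2/s a particle moves
well under a pixel during one line's worth of pixel dwells, so the fast
axis of the correlation is PSF-dominated, while line-to-line motion
carries the diffusion signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry import ScanGeometry, PSFModel, molecules, concentration_nM

# rendering cutoffs (in units of w0 / wz); contributions below ~1e-4 of
# the peak are dropped
_LATERAL_CUT = 2.2
_AXIAL_CUT = 2.2


@dataclass(frozen=True)
class NucleiLayout:
    """Disk-shaped nuclei on the image plane.

    centers_px are (row, col) pixel coordinates; all nuclei share one
    radius.  Particles live in cylinders: the disk extruded over
    ``[-z_half_um, z_half_um]`` in z.
    """

    centers_px: tuple = ((64.0, 64.0), (64.0, 192.0), (192.0, 64.0), (192.0, 192.0))
    radius_px: float = 60.0
    z_half_um: float = 2.5

    def __post_init__(self):
        if self.radius_px <= 0 or self.z_half_um <= 0:
            raise ValueError("radius and z extent must be positive")
        if len(self.centers_px) < 1:
            raise ValueError("need at least one nucleus")
        c = np.asarray(self.centers_px, dtype=float)
        if len(c) > 1:
            d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if (d < 2 * self.radius_px).any():
                raise ValueError("overlapping nuclei")

    @property
    def n_nuclei(self) -> int:
        return len(self.centers_px)

    def volume_um3(self, pixel_size_um: float) -> float:
        """Total particle-accessible volume across all nuclei (um^3)."""
        area = math.pi * (self.radius_px * pixel_size_um) ** 2
        return self.n_nuclei * area * 2 * self.z_half_um

    def mask(self, shape: tuple) -> np.ndarray:
        """Boolean truth mask of the nuclear disks."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        out = np.zeros(shape, dtype=bool)
        for r0, c0 in self.centers_px:
            out |= (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_px**2
        return out

    def labeled_mask(self, shape: tuple) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        out = np.zeros(shape, dtype=np.int32)
        for i, (r0, c0) in enumerate(self.centers_px, start=1):
            out[(rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius_px**2] = i
        return out


@dataclass
class SimTruth:
    """Ground truth attached to every synthetic movie.

    Counts are totals over all nuclei.  Brightness is the mean detector
    counts contributed by one particle sitting at the PSF centre during
    one pixel dwell.  ``offset_nm`` displaces the red image of cobound
    particles (channel registration error), (dx, dy, dz).
    """

    n_free_green: int = 0
    n_bound_green: int = 0
    n_cobound: int = 0
    n_free_red: int = 0
    n_bound_red: int = 0
    d_free_um2_s: float = 2.0
    brightness_green: float = 1500.0
    brightness_red: float = 1500.0
    offset_nm: tuple = (0.0, 0.0, 0.0)
    k_on_s: float | None = None
    k_off_s: float | None = None
    s_true: float = 400.0
    read_noise_var: float = 100.0
    background: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_free_green", "n_bound_green", "n_cobound", "n_free_red", "n_bound_red"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d_free_um2_s <= 0:
            raise ValueError("d_free_um2_s must be positive")
        for name in ("k_on_s", "k_off_s"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_green(self) -> int:
        return self.n_free_green + self.n_bound_green + self.n_cobound

    @property
    def n_red(self) -> int:
        return self.n_free_red + self.n_bound_red + self.n_cobound

    @property
    def phi_green(self) -> float:
        """True immobile (bound) fraction of the green channel."""
        return (self.n_bound_green + self.n_cobound) / self.n_green if self.n_green else 0.0

    @property
    def psi_green(self) -> float:
        """True red-correlated fraction of the green channel."""
        return self.n_cobound / self.n_green if self.n_green else 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def truth_from_concentrations(
    c_green_nM: float,
    phi: float,
    psi: float,
    layout: NucleiLayout,
    geometry: ScanGeometry,
    c_red_nM: float = 25.0,
    seed: int = 0,
    **kwargs,
) -> SimTruth:
    """Build a :class:`SimTruth` from target concentrations and fractions.

    ``phi`` is the bound (quasi-immobile) fraction of the green channel,
    ``psi`` the fraction co-bound with the red channel; psi <= phi.
    Red-channel particles are all binders (chromatin-like) except the
    cobound ones which are shared with the green channel.
    """
    if not 0 <= psi <= phi <= 1:
        raise ValueError("need 0 <= psi <= phi <= 1")
    vol = layout.volume_um3(geometry.pixel_size_um)
    n_green = molecules(c_green_nM, vol)
    n_red = molecules(c_red_nM, vol)
    n_cobound = int(round(psi * n_green))
    n_bound_green = int(round((phi - psi) * n_green))
    n_free_green = int(round((1 - phi) * n_green))
    n_bound_red = max(int(round(n_red)) - n_cobound, 0)
    return SimTruth(
        n_free_green=n_free_green,
        n_bound_green=n_bound_green,
        n_cobound=n_cobound,
        n_free_red=0,
        n_bound_red=n_bound_red,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# particle dynamics
# ---------------------------------------------------------------------------


class ParticleEnsemble:
    """Mutable particle state stepped at line-time resolution.

    Coordinates are um: x along the fast (column) axis, y along the slow
    (row) axis, z along the optical axis.  Bound particles are strictly
    immobile; unbound ones take Brownian steps and are reflected at the
    nuclear boundary (radially in the disk, specularly in z).
    """

    def __init__(self, truth: SimTruth, layout: NucleiLayout, geometry: ScanGeometry, rng: np.random.Generator):
        self.layout = layout
        self.geometry = geometry
        self.rng = rng
        px = geometry.pixel_size_um
        if truth.k_off_s is None:
            # bound dwell of one frame period: immobile across the
            # correlation lag window (~ max_lag * line_time), yet nearly
            # independent between frames so the group-average detrend
            # removes the bound pool no more than the free pool
            k_off = 1.0 / geometry.frame_time_s
        else:
            k_off = truth.k_off_s
        k_on = 19.0 * k_off if truth.k_on_s is None else truth.k_on_s

        counts = [truth.n_free_green, truth.n_bound_green, truth.n_cobound, truth.n_free_red, truth.n_bound_red]
        n = sum(counts)
        self.n = n
        self.bright_g = np.zeros(n)
        self.bright_r = np.zeros(n)
        self.is_binder = np.zeros(n, dtype=bool)
        edges = np.cumsum([0] + counts)
        fg, bg, cb, fr, br = (slice(edges[i], edges[i + 1]) for i in range(5))
        self.bright_g[fg] = truth.brightness_green
        self.bright_g[bg] = truth.brightness_green
        self.bright_g[cb] = truth.brightness_green
        self.bright_r[cb] = truth.brightness_red
        self.bright_r[fr] = truth.brightness_red
        self.bright_r[br] = truth.brightness_red
        self.is_binder[bg] = True
        self.is_binder[cb] = True
        self.is_binder[br] = True

        self.k_on = k_on
        self.k_off = k_off
        self.d_free = truth.d_free_um2_s
        # binders start bound (stationary distribution is reached quickly
        # relative to a movie; duty cycle k_on/(k_on+k_off) ~ 0.95)
        self.bound = self.is_binder.copy()

        # uniform positions inside the nuclear cylinders
        self.nucleus = rng.integers(0, layout.n_nuclei, size=n)
        centers = np.asarray(layout.centers_px, dtype=float) * px
        r = layout.radius_px * px * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * math.pi
        self.pos = np.empty((n, 3))
        self.pos[:, 0] = centers[self.nucleus, 1] + r * np.cos(th)  # x = col
        self.pos[:, 1] = centers[self.nucleus, 0] + r * np.sin(th)  # y = row
        self.pos[:, 2] = rng.uniform(-layout.z_half_um, layout.z_half_um, size=n)
        self._centers = centers
        self._radius = layout.radius_px * px

    def step(self, dt: float) -> None:
        if dt <= 0:
            return
        mobile = ~self.bound
        nm = int(mobile.sum())
        if nm:
            sigma = math.sqrt(2 * self.d_free * dt)
            self.pos[mobile] += self.rng.normal(0.0, sigma, size=(nm, 3))
            self._confine(mobile)
        # two-state exchange for binders
        if self.is_binder.any() and (self.k_off > 0 or self.k_on > 0):
            u = self.rng.random(self.n)
            release = self.bound & self.is_binder & (u < -np.expm1(-self.k_off * dt))
            capture = (~self.bound) & self.is_binder & (u < -np.expm1(-self.k_on * dt))
            self.bound[release] = False
            self.bound[capture] = True

    def _confine(self, sel: np.ndarray) -> None:
        p = self.pos[sel]
        c = self._centers[self.nucleus[sel]]
        dx = p[:, 0] - c[:, 1]
        dy = p[:, 1] - c[:, 0]
        r = np.hypot(dx, dy)
        out = r > self._radius
        if out.any():
            # radial reflection at the disk boundary
            r_new = np.clip(2 * self._radius - r[out], 0.0, self._radius)
            scale = np.where(r[out] > 0, r_new / r[out], 0.0)
            p[out, 0] = c[out, 1] + dx[out] * scale
            p[out, 1] = c[out, 0] + dy[out] * scale
        zh = self.layout.z_half_um
        z = p[:, 2]
        # specular reflection into [-zh, zh] (triangle wave, period 4 zh)
        p[:, 2] = zh - np.abs(np.mod(z + zh, 4 * zh) - 2 * zh)
        self.pos[sel] = p


def simulate_particle_paths(
    truth: SimTruth,
    geometry: ScanGeometry,
    n_frames: int,
    layout: NucleiLayout | None = None,
) -> tuple:
    """Per-line particle trajectories for a short movie.

    Returns ``(positions, bound)`` with ``positions`` of shape
    ``(n_frames * n_rows, n_particles, 3)`` (um, sampled at the start of
    each scan line) and ``bound`` the matching boolean mobility state.
    Intended for inspection and tests; :func:`simulate_timeseries` steps
    the same dynamics incrementally without storing trajectories.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    layout = layout or NucleiLayout()
    _check_box(layout, geometry)
    rng = np.random.default_rng(truth.seed)
    ens = ParticleEnsemble(truth, layout, geometry, rng)
    n_lines = n_frames * geometry.n_rows
    pos = np.empty((n_lines, ens.n, 3))
    bound = np.empty((n_lines, ens.n), dtype=bool)
    retrace = geometry.frame_time_s - geometry.n_rows * geometry.line_time_s
    for t in range(n_lines):
        pos[t] = ens.pos
        bound[t] = ens.bound
        ens.step(geometry.line_time_s)
        if (t + 1) % geometry.n_rows == 0 and retrace > 0:
            ens.step(retrace)
    return pos, bound


def _check_box(layout: NucleiLayout, geometry: ScanGeometry, psf: PSFModel | None = None):
    psf = psf or PSFModel()
    if 2 * layout.radius_px * geometry.pixel_size_um <= 2 * psf.w0_um:
        raise ValueError("nuclei smaller than the PSF")
    if 2 * layout.z_half_um <= psf.wz_um:
        raise ValueError("z extent smaller than the PSF axial radius")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_line(row: np.ndarray, x: np.ndarray, wy: np.ndarray, w0_px: float, n_cols: int):
    """Add Gaussian x-profiles of particles (positions in px) into one row."""
    half = int(math.ceil(_LATERAL_CUT * w0_px))
    base = np.round(x).astype(np.int64)
    cols = base[:, None] + np.arange(-half, half + 1)[None, :]
    vals = wy[:, None] * np.exp(-2.0 * ((cols - x[:, None]) / w0_px) ** 2)
    ok = (cols >= 0) & (cols < n_cols)
    np.add.at(row, cols[ok], vals[ok])


def render_raster_frame(
    positions: np.ndarray,
    brightness: np.ndarray,
    geometry: ScanGeometry,
    psf: PSFModel,
    background: float = 0.0,
    s_true: float = 0.0,
    read_noise_var: float = 0.0,
    rng: np.random.Generator | None = None,
    offset_um: tuple = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Render one raster-scanned frame.

    ``positions`` is either ``(n, 3)`` (static during the frame) or
    ``(n_rows, n, 3)`` (one snapshot per scan line).  Pixel (i, j)
    integrates the PSF-weighted brightness of every particle at its
    position during line i; analog detector noise with variance
    ``read_noise_var + s_true * signal`` is then added and the result is
    rounded to non-negative integers.
    """
    h, w = geometry.n_rows, geometry.n_cols
    px = geometry.pixel_size_um
    w0_px = psf.w0_um / px
    img = np.zeros((h, w))
    pos = np.asarray(positions, dtype=float)
    per_line = pos.ndim == 3
    bright = np.asarray(brightness, dtype=float)
    ox, oy, oz = offset_um
    for i in range(h):
        p = pos[i] if per_line else pos
        if p.size == 0:
            continue
        lit = bright > 0
        if not lit.any():
            continue
        y = (p[lit, 1] + oy) / px
        z = p[lit, 2] + oz
        dy = y - i
        near = (np.abs(dy) < _LATERAL_CUT * w0_px) & (np.abs(z) < _AXIAL_CUT * psf.wz_um)
        if not near.any():
            continue
        wy = (
            bright[lit][near]
            * np.exp(-2.0 * (dy[near] / w0_px) ** 2)
            * np.exp(-2.0 * (z[near] / psf.wz_um) ** 2)
        )
        x = (p[lit, 0][near] + ox) / px
        _render_line(img[i], x, wy, w0_px, w)
    signal = img
    img = img + background
    if s_true > 0 or read_noise_var > 0:
        if rng is None:
            rng = np.random.default_rng()
        img = img + rng.normal(0.0, np.sqrt(read_noise_var + s_true * signal))
    return np.clip(np.round(img), 0, None)


@dataclass
class Movie:
    """A simulated two-channel raster-scan time series."""

    green: np.ndarray  # (n_frames, h, w)
    red: np.ndarray
    truth: SimTruth
    layout: NucleiLayout
    geometry: ScanGeometry
    psf_green: PSFModel
    psf_red: PSFModel

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def truth_mask(self) -> np.ndarray:
        return self.layout.mask(self.green.shape[1:])

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.geometry.frame_time_s


def simulate_timeseries(
    truth: SimTruth,
    geometry: ScanGeometry,
    n_frames: int,
    layout: NucleiLayout | None = None,
    psf_green: PSFModel | None = None,
    psf_red: PSFModel | None = None,
) -> Movie:
    """Simulate a two-channel movie with ground truth attached.

    Cobound particles appear in both channels; their red image is
    displaced by ``truth.offset_nm``.  Detector noise and background are
    applied per channel.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    layout = layout or NucleiLayout()
    psf_green = psf_green or PSFModel()
    psf_red = psf_red or PSFModel()
    _check_box(layout, geometry, psf_green)
    rng = np.random.default_rng(truth.seed)
    ens = ParticleEnsemble(truth, layout, geometry, rng)
    h, w = geometry.n_rows, geometry.n_cols
    green = np.empty((n_frames, h, w))
    red = np.empty((n_frames, h, w))
    off_um = tuple(v * 1e-3 for v in truth.offset_nm)
    retrace = geometry.frame_time_s - h * geometry.line_time_s
    px = geometry.pixel_size_um
    w0g_px = psf_green.w0_um / px
    w0r_px = psf_red.w0_um / px
    has_red = (ens.bright_r > 0).any()
    for f in range(n_frames):
        sig_g = np.zeros((h, w))
        sig_r = np.zeros((h, w))
        for i in range(h):
            p = ens.pos
            _accumulate_line(sig_g[i], p, ens.bright_g, i, px, w0g_px, psf_green.wz_um, w, (0.0, 0.0, 0.0))
            if has_red:
                _accumulate_line(sig_r[i], p, ens.bright_r, i, px, w0r_px, psf_red.wz_um, w, off_um)
            ens.step(geometry.line_time_s)
        if retrace > 0:
            ens.step(retrace)
        green[f] = _detect(sig_g, truth, rng)
        red[f] = _detect(sig_r, truth, rng)
    return Movie(green, red, truth, layout, geometry, psf_green, psf_red)


def _accumulate_line(row, pos, bright, i, px, w0_px, wz_um, n_cols, offset_um):
    lit = bright > 0
    if not lit.any():
        return
    ox, oy, oz = offset_um
    dy = (pos[lit, 1] + oy) / px - i
    z = pos[lit, 2] + oz
    near = (np.abs(dy) < _LATERAL_CUT * w0_px) & (np.abs(z) < _AXIAL_CUT * wz_um)
    if not near.any():
        return
    wy = bright[lit][near] * np.exp(-2.0 * (dy[near] / w0_px) ** 2 - 2.0 * (z[near] / wz_um) ** 2)
    x = (pos[lit, 0][near] + ox) / px
    _render_line(row, x, wy, w0_px, n_cols)


def _detect(signal: np.ndarray, truth: SimTruth, rng: np.random.Generator) -> np.ndarray:
    img = signal + truth.background
    if truth.s_true > 0 or truth.read_noise_var > 0:
        img = img + rng.normal(0.0, np.sqrt(truth.read_noise_var + truth.s_true * signal))
    return np.clip(np.round(img), 0, None)


# ---------------------------------------------------------------------------
# bead stacks for channel registration
# ---------------------------------------------------------------------------


@dataclass
class BeadStack:
    green: np.ndarray  # (nz, h, w)
    red: np.ndarray
    z_um: np.ndarray
    centers_um: np.ndarray  # (n_beads, 3) true green-channel centers (x, y, z)
    offsets_um: tuple  # true red-channel displacement (dx, dy, dz)
    pixel_size_um: float
    psf_green: PSFModel
    psf_red: PSFModel


def simulate_bead_stack(
    offsets_nm: tuple = (60.0, 30.0, 100.0),
    psf_green: PSFModel | None = None,
    psf_red: PSFModel | None = None,
    z_step_um: float = 0.05,
    n_beads: int = 5,
    shape: tuple = (128, 128),
    pixel_size_nm: float = 31.95,
    z_range_um: float | None = None,
    brightness: float = 2000.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> BeadStack:
    """Two-channel z-stack of sub-diffraction beads.

    Each bead images as the 3D Gaussian PSF of its channel; the red
    channel is displaced by ``offsets_nm``.  Beads are placed with
    pairwise separation of at least 3 w0 so that per-bead fits do not
    confound each other.
    """
    psf_green = psf_green or PSFModel()
    psf_red = psf_red or PSFModel()
    z_range_um = z_range_um or 4.5 * max(psf_green.wz_um, psf_red.wz_um)
    if z_range_um < 4 * max(psf_green.wz_um, psf_red.wz_um):
        raise ValueError("z range must cover at least 4 x wz")
    rng = np.random.default_rng(seed)
    px = pixel_size_nm * 1e-3
    h, w = shape
    min_sep = 3 * max(psf_green.w0_um, psf_red.w0_um)
    margin = 3 * psf_green.w0_um
    centers = []
    for _ in range(10000):
        if len(centers) == n_beads:
            break
        cand = np.array(
            [
                rng.uniform(margin, w * px - margin),
                rng.uniform(margin, h * px - margin),
                rng.uniform(-0.2, 0.2),
            ]
        )
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < n_beads:
        raise ValueError("could not place beads with the required separation")
    centers = np.array(centers)
    # slices span +/- z_range/2 around focus at z_step spacing
    nz = int(round(z_range_um / 2 / z_step_um)) * 2 + 1
    z = (np.arange(nz) - nz // 2) * z_step_um
    xx = np.arange(w) * px
    yy = np.arange(h) * px
    off_um = tuple(v * 1e-3 for v in offsets_nm)

    def render(psf: PSFModel, off) -> np.ndarray:
        stack = np.zeros((nz, h, w))
        for cx, cy, cz in centers:
            gx = np.exp(-2 * ((xx - cx - off[0]) / psf.w0_um) ** 2)
            gy = np.exp(-2 * ((yy - cy - off[1]) / psf.w0_um) ** 2)
            gz = np.exp(-2 * ((z - cz - off[2]) / psf.wz_um) ** 2)
            stack += brightness * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        if noise_sd > 0:
            stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
        return np.clip(np.round(stack), 0, None)

    return BeadStack(
        green=render(psf_green, (0.0, 0.0, 0.0)),
        red=render(psf_red, off_um),
        z_um=z,
        centers_um=centers,
        offsets_um=off_um,
        pixel_size_um=px,
        psf_green=psf_green,
        psf_red=psf_red,
    )


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------


def save_movie(movie: Movie, outdir: str | Path) -> Path:
    """Write a movie as 16-bit multi-page TIFFs plus sidecar metadata."""
    import tifffile
    import yaml
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "green.tif", movie.green.astype(np.uint16))
    tifffile.imwrite(outdir / "red.tif", movie.red.astype(np.uint16))
    meta = {
        "geometry": movie.geometry.to_dict(),
        "psf_green": movie.psf_green.to_dict(),
        "psf_red": movie.psf_red.to_dict(),
        "layout": {
            "centers_px": [list(c) for c in movie.layout.centers_px],
            "radius_px": movie.layout.radius_px,
            "z_half_um": movie.layout.z_half_um,
        },
    }
    (outdir / "scan.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    pd.DataFrame([movie.truth.to_dict()]).to_csv(outdir / "truth.csv", index=False)
    return outdir


def save_bead_stack(stack: BeadStack, outdir: str | Path) -> Path:
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "beads_green.tif", stack.green.astype(np.uint16))
    tifffile.imwrite(outdir / "beads_red.tif", stack.red.astype(np.uint16))
    np.savetxt(outdir / "beads_z_um.txt", stack.z_um)
    return outdir
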