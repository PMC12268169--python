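"""Fitting RICS/ccRICS models to correlation surfaces.

Two-step autocorrelation fit:

1. the fast-axis cut G(dx, 0) is fitted with the Gaussian PSF shape
   ``A exp(-dr^2 dx^2 / w0^2) + B`` — along the fast axis the diffusive
   decay over microsecond pixel dwells is negligible, so this yields an
   accurate amplitude ``A``;
2. holding A fixed, the full 2D surface is fitted with a linear
   combination of an immobile (D = 0) kernel and a freely diffusing
   kernel, whose weight ``phi`` is the immobile fraction and whose decay
   along the slow (line-time) axis carries the diffusivity ``D``.

The cross-correlation surface is fitted with a laterally displaced
Gaussian whose amplitude, divided by the red-channel amplitude, gives
``psi`` — the fraction of green molecules co-moving with the red label.
Amplitudes convert to absolute concentrations through the PSF
observation volume, and a bead-stack calibration provides the axial
channel displacement entering the cross-amplitude correction factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .geometry import ScanGeometry, PSFModel, concentration_nM
from .correlation import CorrelationSurface

B_MAX = 1e-3  # magnitude bound on the background constant
D_MIN, D_MAX = 0.01, 100.0  # um^2/s


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


def diffusion_kernel(
    dx: np.ndarray, dy: np.ndarray, D: float, geometry: ScanGeometry, w0_um: float, wz_um: float
) -> np.ndarray:
    """Normalized RICS kernel G_n(dx, dy) for diffusivity D; G_n(0,0)=1.

    The time separation between pixels at lag (dx, dy) is
    ``|tau_p dx + tau_l dy|``; the kernel is the product of the two
    diffusion factors and the Gaussian scanning factor whose width
    broadens with the diffusion time.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    tau = np.abs(geometry.pixel_dwell_s * dx + geometry.line_time_s * dy)
    a = 4.0 * D * tau
    f_lat = 1.0 / (1.0 + a / w0_um**2)
    f_ax = 1.0 / np.sqrt(1.0 + a / wz_um**2)
    dr = geometry.pixel_size_um
    scan = np.exp(-(dr**2) * (dx**2 + dy**2) / w0_um**2 * f_lat)
    return f_lat * f_ax * scan


def immobile_kernel(dx: np.ndarray, dy: np.ndarray, geometry: ScanGeometry, w0_um: float) -> np.ndarray:
    """D = 0 limit: the pure Gaussian scanning kernel."""
    dr = geometry.pixel_size_um
    return np.exp(-(dr**2) * (np.asarray(dx, float) ** 2 + np.asarray(dy, float) ** 2) / w0_um**2)


def model_rics_acf(
    dx: np.ndarray,
    dy: np.ndarray,
    A: float,
    D: float,
    geometry: ScanGeometry,
    psf: PSFModel,
    B: float = 0.0,
) -> np.ndarray:
    """Non-normalized single-component ACF model A*G_n + B."""
    if A <= 0:
        raise ValueError("A must be positive")
    if D < 0:
        raise ValueError("D must be non-negative")
    if D == 0:
        return A * immobile_kernel(dx, dy, geometry, psf.w0_um) + B
    return A * diffusion_kernel(dx, dy, D, geometry, psf.w0_um, psf.wz_um) + B


def two_component_acf(
    dx, dy, A: float, D: float, phi: float, geometry: ScanGeometry, w0_um: float, wz_um: float, B: float = 0.0
):
    """A [phi G_imm + (1-phi) G_dif(D)] + B."""
    g_imm = immobile_kernel(dx, dy, geometry, w0_um)
    g_dif = diffusion_kernel(dx, dy, D, geometry, w0_um, wz_um)
    return A * (phi * g_imm + (1.0 - phi) * g_dif) + B


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class ACFFitResult:
    amplitude: float = float("nan")
    background: float = 0.0
    w0_um: float = float("nan")
    d_um2_s: float = float("nan")
    phi: float = float("nan")
    residual: float = float("nan")
    ok: bool = False
    flags: list = field(default_factory=list)


@dataclass
class CCFFitResult:
    amplitude: float = float("nan")  # axial-corrected cross amplitude
    amplitude_raw: float = float("nan")
    dx0_nm: float = float("nan")
    dy0_nm: float = float("nan")
    background: float = 0.0
    axial_factor: float = 1.0
    residual: float = float("nan")
    ok: bool = False
    flags: list = field(default_factory=list)


@dataclass
class PoolRecord:
    """Per-time-point pool decomposition of the green-labelled factor."""

    time_s: float
    cycle: str = ""
    a_green: float = float("nan")
    a_red: float = float("nan")
    a_cc: float = float("nan")
    phi: float = float("nan")
    psi: float = float("nan")
    n_bar: float = float("nan")
    c_tot_nM: float = float("nan")
    c_free_nM: float = float("nan")
    c_immobile_nM: float = float("nan")
    c_active_nM: float = float("nan")
    c_inactive_nM: float = float("nan")
    d_um2_s: float = float("nan")
    flags: str = ""


# ---------------------------------------------------------------------------
# fast-axis fit (step 1)
# ---------------------------------------------------------------------------


def fit_fast_axis(
    surface: CorrelationSurface, psf: PSFModel, geometry: ScanGeometry, exclude_zero: bool = True
) -> ACFFitResult:
    """Amplitude from the Gaussian fit of the fast-axis cut.

    The zero-lag bin is excluded (it carries uncorrelated shot noise),
    |B| is bounded by 1e-3 and w0 may move +/-30% from its configured
    value.  The fit is flagged when it fails to converge, the amplitude
    is non-positive, or the amplitude sits at the residual noise floor.
    """
    dx, g = surface.fast_axis()
    keep = np.isfinite(g)
    if exclude_zero:
        keep &= dx != 0
    dx, g = dx[keep], g[keep]
    res = ACFFitResult()
    if dx.size < 15:
        res.flags.append("too_few_lags")
        return res
    dr = geometry.pixel_size_um
    a0 = max(float(np.interp(1.0, dx, g)), 1e-6)

    def residuals(p):
        A, B, w0 = p
        return A * np.exp(-(dr**2) * dx**2 / w0**2) + B - g

    try:
        sol = least_squares(
            residuals,
            x0=(a0, 0.0, psf.w0_um),
            bounds=([0.0, -B_MAX, 0.7 * psf.w0_um], [np.inf, B_MAX, 1.3 * psf.w0_um]),
        )
    except Exception:
        res.flags.append("fit_failed")
        return res
    A, B, w0 = sol.x
    res.amplitude, res.background, res.w0_um = float(A), float(B), float(w0)
    res.residual = float(np.sqrt(np.mean(sol.fun**2)))
    if not sol.success or A <= 0:
        res.flags.append("not_converged" if not sol.success else "non_positive_amplitude")
        return res
    if A < 3.0 * res.residual:
        res.flags.append("noise_floor")
        return res
    res.ok = True
    return res


# ---------------------------------------------------------------------------
# two-component fit (step 2)
# ---------------------------------------------------------------------------


def fit_two_component(
    surface: CorrelationSurface,
    a_fixed: float,
    geometry: ScanGeometry,
    psf: PSFModel,
    w0_um: float | None = None,
    n_starts: int = 8,
    seed: int = 0,
    exclude_zero: bool = True,
) -> ACFFitResult:
    """Immobile fraction and diffusivity from the full 2D surface.

    Fits ``A_fixed [phi G_imm + (1-phi) G_dif(D)] + B`` with bounded
    least squares from ``n_starts`` random starting points (D drawn
    log-uniformly, phi uniformly); the best residual wins and residual
    ties break toward the smaller D.
    """
    w0 = w0_um if w0_um is not None else psf.w0_um
    DX, DY = np.meshgrid(surface.x_lags, surface.y_lags)
    vals = surface.values
    keep = np.isfinite(vals)
    if exclude_zero:
        keep &= ~((DX == 0) & (DY == 0))
    dx, dy, g = DX[keep].astype(float), DY[keep].astype(float), vals[keep]
    res = ACFFitResult(amplitude=a_fixed, w0_um=w0)
    if g.size < 30:
        res.flags.append("too_few_lags")
        return res
    g_imm = immobile_kernel(dx, dy, geometry, w0)

    def residuals(p):
        phi, D, B = p
        g_dif = diffusion_kernel(dx, dy, D, geometry, w0, psf.wz_um)
        return a_fixed * (phi * g_imm + (1.0 - phi) * g_dif) + B - g

    rng = np.random.default_rng(seed)
    starts = [(0.5, 2.0, 0.0)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            (
                rng.uniform(0.0, 1.0),
                10 ** rng.uniform(math.log10(D_MIN), math.log10(D_MAX)),
                0.0,
            )
        )
    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0=x0, bounds=([0.0, D_MIN, -B_MAX], [1.0, D_MAX, B_MAX])
            )
        except Exception:
            continue
        if not sol.success:
            continue
        cost = float(np.sqrt(np.mean(sol.fun**2)))
        # residual ties (to numerical precision) break toward smaller D
        if best is None or cost < best[0] * (1 - 1e-9) or (
            abs(cost - best[0]) <= best[0] * 1e-9 and sol.x[1] < best[1][1]
        ):
            best = (cost, sol.x)
    if best is None:
        res.flags.append("fit_failed")
        return res
    cost, (phi, D, B) = best
    res.phi, res.d_um2_s, res.background, res.residual = float(phi), float(D), float(B), cost
    if phi <= 1e-6 or phi >= 1 - 1e-6:
        res.flags.append("phi_at_boundary")
    if D <= D_MIN * (1 + 1e-6) or D >= D_MAX * (1 - 1e-6):
        res.flags.append("d_at_boundary")
    res.ok = True
    return res


# ---------------------------------------------------------------------------
# cross-correlation fit
# ---------------------------------------------------------------------------


def fit_ccf(
    surface: CorrelationSurface,
    psf_green: PSFModel,
    psf_red: PSFModel,
    geometry: ScanGeometry,
    axial_factor: float = 1.0,
    max_disp_px: float = 10.0,
    n_starts: int = 8,
    seed: int = 0,
    diffusive: bool = False,
) -> CCFFitResult:
    """Displaced-Gaussian fit of the 2D cross-correlation surface.

    The co-bound pool is chromatin-associated, so the default model is
    the immobile kernel displaced by the inter-channel registration
    offsets (dx0, dy0), with width from the average PSF,
    ``w0_avg^2 = (w0_g^2 + w0_r^2)/2``.  ``axial_factor`` (from the bead
    calibration) multiplies the recovered amplitude.  An amplitude below
    the residual noise floor is set to zero (no detectable co-binding).
    Setting ``diffusive=True`` adds a free-diffusion decay term.
    """
    DX, DY = np.meshgrid(surface.x_lags, surface.y_lags)
    vals = surface.values
    keep = np.isfinite(vals)
    dx, dy, g = DX[keep].astype(float), DY[keep].astype(float), vals[keep]
    res = CCFFitResult(axial_factor=axial_factor)
    if g.size < 30:
        res.flags.append("too_few_lags")
        return res
    dr = geometry.pixel_size_um
    w0_avg = math.sqrt((psf_green.w0_um**2 + psf_red.w0_um**2) / 2.0)
    wz_avg = math.sqrt((psf_green.wz_um**2 + psf_red.wz_um**2) / 2.0)
    lim = max_disp_px * dr

    def shape(p):
        if diffusive:
            a_cc, x0, y0, B, D = p
            tau = np.abs(geometry.pixel_dwell_s * dx + geometry.line_time_s * dy)
            f_lat = 1.0 / (1.0 + 4.0 * D * tau / w0_avg**2)
            f_ax = 1.0 / np.sqrt(1.0 + 4.0 * D * tau / wz_avg**2)
            core = np.exp(-(((dr * dx - x0) ** 2 + (dr * dy - y0) ** 2) / w0_avg**2) * f_lat)
            return a_cc * f_lat * f_ax * core + B
        a_cc, x0, y0, B = p
        return a_cc * np.exp(-((dr * dx - x0) ** 2 + (dr * dy - y0) ** 2) / w0_avg**2) + B

    def residuals(p):
        return shape(p) - g

    a0 = max(float(np.nanmax(g)), 1e-6)
    rng = np.random.default_rng(seed)
    lo = [0.0, -lim, -lim, -B_MAX] + ([D_MIN] if diffusive else [])
    hi = [np.inf, lim, lim, B_MAX] + ([D_MAX] if diffusive else [])
    starts = [[a0, 0.0, 0.0, 0.0] + ([2.0] if diffusive else [])]
    for _ in range(max(n_starts - 1, 0)):
        s = [
            a0 * 10 ** rng.uniform(-1, 0.3),
            rng.uniform(-lim / 2, lim / 2),
            rng.uniform(-lim / 2, lim / 2),
            0.0,
        ]
        if diffusive:
            s.append(10 ** rng.uniform(math.log10(D_MIN), math.log10(D_MAX)))
        starts.append(s)
    best = None
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0=x0, bounds=(lo, hi))
        except Exception:
            continue
        if not sol.success:
            continue
        cost = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or cost < best[0]:
            best = (cost, sol.x)
    if best is None:
        res.flags.append("fit_failed")
        return res
    cost, p = best
    a_cc, x0, y0, B = p[:4]
    res.amplitude_raw = float(a_cc)
    res.dx0_nm, res.dy0_nm = float(x0 * 1e3), float(y0 * 1e3)
    res.background, res.residual = float(B), cost
    if a_cc < 3.0 * cost:
        res.amplitude_raw = 0.0
        res.flags.append("below_noise_floor")
    res.amplitude = res.amplitude_raw * axial_factor
    res.ok = True
    return res


def compute_psi(a_cc_corrected: float, a_red: float) -> float:
    """Fraction of green-channel molecules co-moving with the red label.

    psi = A_cc / A_red, clipped to [0, 1]; with matched observation
    volumes this ratio equals <N_cc>/<N_green,tot>.
    """
    if not np.isfinite(a_red) or a_red <= 0:
        return float("nan")
    return float(np.clip(a_cc_corrected / a_red, 0.0, 1.0))


def amplitude_to_concentration(A: float, psf: PSFModel) -> tuple[float, float]:
    """(mean molecule number, concentration in nM) from an ACF amplitude.

    ``N = gamma / A`` counts molecules in the observation volume
    ``V_obs = gamma * pi^{3/2} w0^2 wz`` (see
    :attr:`PSFModel.observation_volume_um3`); the concentration is
    ``N / (N_A V_obs)`` expressed in nM.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    n_bar = psf.gamma / A
    return n_bar, concentration_nM(n_bar, psf.observation_volume_um3)


def axial_displacement_factor(dz0_um: float, wz_green_um: float, wz_red_um: float) -> float:
    """Cross-amplitude correction for the axial channel displacement.

    The overlap of two axially displaced Gaussian PSFs attenuates the
    measured cross amplitude by exp(-2 dz0^2/(wz_g^2 + wz_r^2)); this
    factor undoes it.  Equals 1 at dz0 = 0.
    """
    if wz_green_um <= 0 or wz_red_um <= 0:
        raise ValueError("wz values must be positive")
    return math.exp(2.0 * dz0_um**2 / (wz_green_um**2 + wz_red_um**2))


# ---------------------------------------------------------------------------
# bead-stack channel registration
# ---------------------------------------------------------------------------


@dataclass
class BeadFitResult:
    centers_green: np.ndarray  # (n, 3) um (x, y, z)
    centers_red: np.ndarray
    fwhm_z_green: np.ndarray
    fwhm_z_red: np.ndarray
    center_differences: np.ndarray  # red - green, (n, 3) um
    dz0_um: float  # robust aggregate axial displacement
    dx0_um: float
    dy0_um: float


def _fit_single_bead(roi: np.ndarray, z_um: np.ndarray, pixel_um: float, psf: PSFModel):
    """3D Gaussian fit of one bead ROI -> (x, y, z center in um, wz)."""
    nz, h, w = roi.shape
    zi = int(np.argmax(roi.reshape(nz, -1).max(axis=1)))
    plane = roi[zi]
    total = plane.sum()
    yy, xx = np.mgrid[0:h, 0:w]
    cy0 = float((yy * plane).sum() / total) * pixel_um
    cx0 = float((xx * plane).sum() / total) * pixel_um
    cz0 = float(z_um[zi])
    x_um = np.arange(w) * pixel_um
    y_um = np.arange(h) * pixel_um
    Z, Y, X = np.meshgrid(z_um, y_um, x_um, indexing="ij")
    data = roi.ravel()
    amp0 = float(roi.max())

    def residuals(p):
        amp, cx, cy, cz, w0, wz, off = p
        model = off + amp * np.exp(
            -2 * ((X - cx) ** 2 + (Y - cy) ** 2) / w0**2 - 2 * (Z - cz) ** 2 / wz**2
        )
        return model.ravel() - data

    sol = least_squares(
        residuals,
        x0=(amp0, cx0, cy0, cz0, psf.w0_um, psf.wz_um, float(np.median(roi))),
        bounds=(
            [0, 0, 0, z_um.min(), 0.3 * psf.w0_um, 0.3 * psf.wz_um, -np.inf],
            [np.inf, w * pixel_um, h * pixel_um, z_um.max(), 3 * psf.w0_um, 3 * psf.wz_um, np.inf],
        ),
    )
    if not sol.success:
        raise RuntimeError("bead fit diverged")
    amp, cx, cy, cz, w0, wz, off = sol.x
    return np.array([cx, cy, cz]), float(wz)


def fit_bead_3d(stack, min_beads: int = 3) -> BeadFitResult:
    """Per-bead 3D Gaussian fits of a two-channel bead z-stack.

    Beads are detected on the z-averaged green image; each bead is fitted
    independently per channel in a local ROI.  Initial guesses come from
    the intensity centroid and the brightest z-plane.  The aggregate
    axial displacement is the mean over beads after dropping >3 MAD
    outliers.  Accepts a :class:`ricstf.simulate.BeadStack`-like object.
    """
    from skimage.feature import peak_local_max

    px = stack.pixel_size_um
    avg = stack.green.mean(axis=0)
    min_dist = max(int(3 * stack.psf_green.w0_um / px), 3)
    peaks = peak_local_max(avg, min_distance=min_dist, threshold_rel=0.2)
    if len(peaks) < min_beads:
        raise ValueError(f"need at least {min_beads} detected beads, found {len(peaks)}")
    # lateral ROI of +/- ~3 sigma of the PSF (sigma = w0/2) keeps the
    # per-bead fit small without truncating the profile
    half = max(int(1.5 * stack.psf_green.w0_um / px), 8)
    cg, cr, fz_g, fz_r = [], [], [], []
    for r0, c0 in peaks:
        r0, c0 = int(r0), int(c0)
        rs = slice(max(r0 - half, 0), min(r0 + half + 1, avg.shape[0]))
        cs = slice(max(c0 - half, 0), min(c0 + half + 1, avg.shape[1]))
        try:
            center_g, wz_g = _fit_single_bead(stack.green[:, rs, cs], stack.z_um, px, stack.psf_green)
            center_r, wz_r = _fit_single_bead(stack.red[:, rs, cs], stack.z_um, px, stack.psf_red)
        except RuntimeError:
            continue  # diverged bead dropped
        offset = np.array([cs.start * px, rs.start * px, 0.0])
        cg.append(center_g + offset)
        cr.append(center_r + offset)
        fz_g.append(wz_g * math.sqrt(2 * math.log(2)))
        fz_r.append(wz_r * math.sqrt(2 * math.log(2)))
    if len(cg) < min_beads:
        raise ValueError("too few beads survived fitting")
    cg, cr = np.array(cg), np.array(cr)
    diff = cr - cg
    agg = []
    for k in range(3):
        d = diff[:, k]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        keep = np.abs(d - med) <= 3 * mad if mad > 0 else np.ones(len(d), bool)
        agg.append(float(d[keep].mean()))
    return BeadFitResult(
        centers_green=cg,
        centers_red=cr,
        fwhm_z_green=np.array(fz_g),
        fwhm_z_red=np.array(fz_r),
        center_differences=diff,
        dx0_um=agg[0],
        dy0_um=agg[1],
        dz0_um=agg[2],
    )


# ---------------------------------------------------------------------------
# pool assembly
# ---------------------------------------------------------------------------


def build_pool_record(
    time_s: float,
    acf_green: ACFFitResult,
    acf_red: ACFFitResult,
    ccf: CCFFitResult,
    psf_green: PSFModel,
    cycle: str = "",
) -> PoolRecord:
    """Combine the three per-group fits into a :class:`PoolRecord`.

    Pool identities hold by construction: C_immobile = phi C_tot,
    C_active = psi C_tot, C_free = (1 - phi) C_tot and C_inactive =
    (phi - psi) C_tot; when psi exceeds phi (fit noise) the record is
    flagged and C_inactive set to zero rather than negative.
    """
    rec = PoolRecord(time_s=time_s, cycle=cycle)
    flags = list(acf_green.flags)
    if not acf_green.ok:
        flags.append("green_fit_failed")
        rec.flags = ";".join(flags)
        return rec
    rec.a_green = acf_green.amplitude
    rec.phi = acf_green.phi
    rec.d_um2_s = acf_green.d_um2_s
    rec.n_bar, rec.c_tot_nM = amplitude_to_concentration(acf_green.amplitude, psf_green)
    if np.isfinite(rec.phi):
        rec.c_immobile_nM = rec.phi * rec.c_tot_nM
        rec.c_free_nM = (1.0 - rec.phi) * rec.c_tot_nM
    if acf_red.ok and ccf.ok:
        rec.a_red = acf_red.amplitude
        rec.a_cc = ccf.amplitude
        rec.psi = compute_psi(ccf.amplitude, acf_red.amplitude)
        if np.isfinite(rec.psi):
            rec.c_active_nM = rec.psi * rec.c_tot_nM
            if np.isfinite(rec.phi):
                if rec.psi <= rec.phi:
                    rec.c_inactive_nM = (rec.phi - rec.psi) * rec.c_tot_nM
                else:
                    rec.c_inactive_nM = 0.0
                    flags.append("psi_exceeds_phi")
    else:
        flags.append("cross_missing")
    rec.flags = ";".join(flags)
    return rec
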