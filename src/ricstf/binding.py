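"""Thermodynamic equilibrium model of TF-chromatin binding.

The bound concentration of a transcription factor at equilibrium follows
a Hill isotherm,

    C_bound = C_B * C_free^n / (K_D^n + C_free^n),

with dissociation constant K_D, site capacity C_B and Hill coefficient
n.  Two bound pools are tracked: an "active" pool (co-localized with
the His2Av-marked, transcriptionally competent chromatin) and an
"inactive" pool.  Conservation,

    C_tot = C_free + C_active + C_inactive,

is strictly increasing in C_free, so the free concentration at any total
concentration has a unique root, found by bracketed bisection.  For a
factor whose accessible active sites shrink with nuclear concentration
(Zelda-like), the active capacity can follow a power law
C_B_a = a * C_free^k instead of a constant.

Also here: accessible-site concentration from site counts and nuclear
volume, the accessible-site time course from inverting the isotherm,
and diffusion-limited (Smoluchowski) on-rate / residence-time
calculators.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares

from .geometry import MOLECULES_PER_UM3_PER_NM

#: conversion from nm^3/s per molecule pair to nM^-1 s^-1
NM3_PER_S_TO_PER_NM_PER_S = MOLECULES_PER_UM3_PER_NM * 1e-9  # molecules/nm^3 at 1 nM


@dataclass
class BindingModelParams:
    """Parameters of the two-pool equilibrium model (concentrations nM)."""

    kd_active_nM: float = 17.0
    kd_inactive_nM: float = 24.0
    cb_active_nM: float = 35.0
    cb_inactive_nM: float = 34.0
    n_active: int = 1
    n_inactive: int = 1
    power_law_active: bool = False
    power_a: float = 420.0  # nM^(1-k) scale of the accessible-site power law
    power_k: float = 0.7

    def __post_init__(self):
        if self.kd_active_nM <= 0 or self.kd_inactive_nM <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.cb_active_nM < 0 or self.cb_inactive_nM < 0:
            raise ValueError("site capacities must be non-negative")
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("Hill coefficients must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def hill_bound(c_free, kd: float, cb, n: float = 1) -> np.ndarray | float:
    """Bound concentration of the Hill isotherm; saturates at cb.

    ``cb`` may be an array (e.g. a per-time-point site capacity).
    """
    c = np.asarray(c_free, dtype=float)
    if (c < 0).any() or kd < 0 or np.any(np.asarray(cb) < 0) or n < 1:
        raise ValueError("arguments must be non-negative, n >= 1")
    out = cb * c**n / (kd**n + c**n)
    return float(out) if np.isscalar(c_free) and np.isscalar(cb) else out


def power_law_sites(c_free, a: float = 420.0, k: float = 0.7) -> np.ndarray | float:
    """Accessible active-site capacity as a power law of free TF."""
    c = np.asarray(c_free, dtype=float)
    if (c < 0).any():
        raise ValueError("c_free must be non-negative")
    out = a * c**k
    return float(out) if np.isscalar(c_free) else out


def _bound_pools(c_free: np.ndarray, p: BindingModelParams):
    cb_a = power_law_sites(c_free, p.power_a, p.power_k) if p.power_law_active else p.cb_active_nM
    active = cb_a * c_free**p.n_active / (p.kd_active_nM**p.n_active + c_free**p.n_active)
    inactive = (
        p.cb_inactive_nM
        * c_free**p.n_inactive
        / (p.kd_inactive_nM**p.n_inactive + c_free**p.n_inactive)
    )
    return active, inactive


def solve_free_concentration(
    c_tot, params: BindingModelParams, tol_nM: float = 1e-10
):
    """Free, active and inactive concentrations at a given total.

    Solves C_tot = C_free + active(C_free) + inactive(C_free) by
    bisection on [0, C_tot]; the left side is strictly increasing in
    C_free so the root is unique.  Accepts scalars or arrays.
    """
    scalar = np.isscalar(c_tot)
    ct = np.atleast_1d(np.asarray(c_tot, dtype=float))
    if (ct < 0).any():
        raise ValueError("c_tot must be non-negative")
    lo = np.zeros_like(ct)
    hi = ct.copy()
    n_iter = max(int(np.ceil(np.log2(max(hi.max(), tol_nM) / tol_nM))) + 1, 1)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        a, i = _bound_pools(mid, params)
        too_low = mid + a + i < ct
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    c_free = 0.5 * (lo + hi)
    active, inactive = _bound_pools(c_free, params)
    # exact conservation: assign the bisection residue to the free pool
    c_free = ct - active - inactive
    if scalar:
        return float(c_free[0]), float(active[0]), float(inactive[0])
    return c_free, active, inactive


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class EquilibriumFit:
    params: BindingModelParams
    residual: float
    n_records: int
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"params": self.params.to_dict(), "residual": self.residual,
             "n_records": self.n_records, "flags": self.flags},
            indent=2,
        )


def fit_equilibrium_model(
    c_tot: np.ndarray,
    c_active: np.ndarray,
    c_inactive: np.ndarray,
    n_active: int = 1,
    n_inactive: int = 1,
    power_law_active: bool = False,
    fit_power_k: bool = False,
    n_starts: int = 20,
    seed: int = 0,
    bounds_nM: tuple = (1e-2, 1e3),
    relative: bool = True,
) -> EquilibriumFit:
    """Fit (K_D, C_B) of both pools to a dose/response record set.

    Minimizes the squared residuals between observed and predicted
    (C_active, C_inactive) across records, where predictions come from
    :func:`solve_free_concentration` at each record's C_tot.  Residuals
    are observation-normalized by default (the measurement noise is
    multiplicative).  Parameters are fitted in log space from
    ``n_starts`` log-uniform random starts; the best residual wins.
    Hill coefficients are fixed by configuration.  In power-law mode the
    active capacity is ``a * C_free^k`` with ``a`` (and optionally
    ``k``) fitted instead of a constant C_B.
    """
    c_tot = np.asarray(c_tot, dtype=float)
    c_active = np.asarray(c_active, dtype=float)
    c_inactive = np.asarray(c_inactive, dtype=float)
    ok = np.isfinite(c_tot) & np.isfinite(c_active) & np.isfinite(c_inactive)
    c_tot, c_active, c_inactive = c_tot[ok], c_active[ok], c_inactive[ok]
    if len(c_tot) < 8:
        raise ValueError("need at least 8 usable records")
    lo, hi = bounds_nM
    scale_a = np.maximum(np.abs(c_active), 1e-3) if relative else np.ones_like(c_active)
    scale_i = np.maximum(np.abs(c_inactive), 1e-3) if relative else np.ones_like(c_inactive)

    def make_params(theta):
        kd_a, p2, kd_i, cb_i = 10.0 ** theta[:4]
        kw = dict(
            kd_active_nM=kd_a,
            kd_inactive_nM=kd_i,
            cb_inactive_nM=cb_i,
            n_active=n_active,
            n_inactive=n_inactive,
            power_law_active=power_law_active,
        )
        if power_law_active:
            kw["power_a"] = p2
            kw["cb_active_nM"] = 0.0
            if fit_power_k:
                kw["power_k"] = theta[4]
        else:
            kw["cb_active_nM"] = p2
        return BindingModelParams(**kw)

    def residuals(theta):
        p = make_params(theta)
        _, act, inact = solve_free_concentration(c_tot, p, tol_nM=1e-8)
        return np.concatenate([(act - c_active) / scale_a, (inact - c_inactive) / scale_i])

    rng = np.random.default_rng(seed)
    llo, lhi = math.log10(lo), math.log10(hi)
    lbounds = [llo] * 4 + ([0.1] if (power_law_active and fit_power_k) else [])
    ubounds = [lhi] * 4 + ([2.0] if (power_law_active and fit_power_k) else [])
    best = None
    for s in range(n_starts):
        theta0 = list(rng.uniform(llo, lhi, size=4))
        if power_law_active and fit_power_k:
            theta0.append(rng.uniform(0.3, 1.5))
        try:
            sol = least_squares(residuals, x0=theta0, bounds=(lbounds, ubounds))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all multistarts failed")
    params = make_params(best.x)
    flags = []
    for i, name in enumerate(["kd_active", "cb_or_a", "kd_inactive", "cb_inactive"]):
        if abs(best.x[i] - llo) < 1e-3 or abs(best.x[i] - lhi) < 1e-3:
            flags.append(f"{name}_at_boundary")
    return EquilibriumFit(
        params=params,
        residual=float(np.sqrt(np.mean(residuals(best.x) ** 2))),
        n_records=len(c_tot),
        flags=flags,
    )


def prepare_records(
    records,
    drop_cycles: tuple = ("10",),
    drop_first: int = 2,
) -> np.ndarray:
    """Select usable dose/response records from a PoolRecord table.

    Drops whole excluded cycles (default nuclear cycle 10, too short for
    equilibrium) and the first ``drop_first`` points of every remaining
    cycle (equilibrium not yet established after mitosis).  ``records``
    is a pandas DataFrame with columns cycle, c_tot_nM, c_active_nM,
    c_inactive_nM; returns a boolean keep mask.
    """
    import pandas as pd  # lazy; table plumbing only

    df = pd.DataFrame(records)
    keep = np.ones(len(df), dtype=bool)
    cycles = df["cycle"].astype(str).values
    keep &= ~np.isin(cycles, [str(c) for c in drop_cycles])
    for cyc in pd.unique(cycles):
        idx = np.flatnonzero(cycles == cyc)
        keep[idx[:drop_first]] = False
    return keep


# ---------------------------------------------------------------------------
# sites, back-out helpers, kinetics
# ---------------------------------------------------------------------------


def sites_concentration(n_sites: float, nuclear_volume_um3: float, ploidy: int = 2) -> float:
    """Nuclear-averaged concentration (nM) of ``n_sites`` binding sites.

    L = ploidy * n_sites / (N_A * V); 0.6022 molecules/um^3 per nM.
    """
    if n_sites <= 0 or nuclear_volume_um3 <= 0 or ploidy <= 0:
        raise ValueError("all arguments must be positive")
    return ploidy * n_sites / (MOLECULES_PER_UM3_PER_NM * nuclear_volume_um3)


def kd_from_occupancy(c_free_nM: float, c_bound_nM: float, sites_nM: float) -> float:
    """K_D from one measured occupancy: K_D = C_free (L - C_bound)/C_bound.

    Direct inversion of the n = 1 isotherm; used for single-cycle
    estimates where the site concentration L is known independently.
    """
    if c_bound_nM <= 0 or c_free_nM <= 0:
        raise ValueError("concentrations must be positive")
    if c_bound_nM >= sites_nM:
        raise ValueError("bound concentration cannot exceed site concentration")
    return c_free_nM * (sites_nM - c_bound_nM) / c_bound_nM


def accessible_sites_timecourse(
    c_active_nM: np.ndarray,
    c_free_nM: np.ndarray,
    kd_active_nM: float,
    nuclear_volume_um3: float | np.ndarray | None = None,
    ploidy: int = 2,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Accessible-site capacity over time by inverting the n=1 isotherm.

    C_B(t) = C_active(t) (K_D + C_free(t)) / C_free(t); points with
    C_free = 0 are returned as NaN.  When a nuclear volume (scalar or
    per-point) is given, capacities are also converted to approximate
    site counts per haploid genome copy.
    """
    c_a = np.asarray(c_active_nM, dtype=float)
    c_f = np.asarray(c_free_nM, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cb = np.where(c_f > 0, c_a * (kd_active_nM + c_f) / c_f, np.nan)
    counts = None
    if nuclear_volume_um3 is not None:
        vol = np.broadcast_to(np.asarray(nuclear_volume_um3, dtype=float), cb.shape)
        counts = cb * MOLECULES_PER_UM3_PER_NM * vol / ploidy
    return cb, counts


def smoluchowski_kon(d_um2_s: float, b_nm: float, reactive_fraction: float) -> float:
    """Diffusion-limited on-rate k_on = 4 pi D b a, in nM^-1 s^-1.

    D in um^2/s, reaction cross-section b in nm, reactive surface
    fraction a in (0, 1].
    """
    if d_um2_s <= 0 or b_nm <= 0:
        raise ValueError("D and b must be positive")
    if not 0 < reactive_fraction <= 1:
        raise ValueError("reactive fraction must lie in (0, 1]")
    d_nm2_s = d_um2_s * 1e6
    kon_nm3_s = 4.0 * math.pi * d_nm2_s * b_nm * reactive_fraction
    return kon_nm3_s * NM3_PER_S_TO_PER_NM_PER_S


def residence_time(kd_nM: float, kon_per_nM_s: float) -> float:
    """Mean binding-event duration tau = 1/(k_on K_D), in seconds."""
    if kd_nM <= 0 or kon_per_nM_s <= 0:
        raise ValueError("K_D and k_on must be positive")
    return 1.0 / (kon_per_nM_s * kd_nM)
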