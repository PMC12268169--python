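"""Diagnostic plots: correlation-surface cuts, pool time courses,
dose/response maps."""

from __future__ import annotations

import numpy as np

from .correlation import CorrelationSurface
from .geometry import ScanGeometry, PSFModel
from .model_fit import ACFFitResult, two_component_acf


def plot_acf_cuts(
    surface: CorrelationSurface,
    fit: ACFFitResult | None = None,
    geometry: ScanGeometry | None = None,
    psf: PSFModel | None = None,
    ax=None,
):
    """Fast- and slow-axis cuts of a correlation surface, with the
    fitted two-component model overlaid when a fit is given."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    dx, fast = surface.fast_axis()
    j0 = int(np.flatnonzero(surface.x_lags == 0)[0])
    slow = surface.values[:, j0]
    ax.plot(dx, fast, "o", ms=3, label="fast axis G(dx, 0)")
    ax.plot(surface.y_lags, slow, "s", ms=3, label="slow axis G(0, dy)")
    if fit is not None and fit.ok and geometry is not None and psf is not None:
        w0 = fit.w0_um if np.isfinite(fit.w0_um) else psf.w0_um
        lags = np.linspace(0, surface.y_lags.max(), 200)
        model = two_component_acf(
            np.zeros_like(lags), lags, fit.amplitude, fit.d_um2_s, fit.phi,
            geometry, w0, psf.wz_um, fit.background,
        )
        ax.plot(lags, model, "-", lw=1, label="two-component fit")
    ax.set_xlabel("lag (pixels)")
    ax.set_ylabel("G")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_pool_timecourse(pool, ax=None):
    """Concentration of each pool over time from a pool-record table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = pool["time_s"]
    for col, label in [
        ("c_tot_nM", "total"),
        ("c_free_nM", "free"),
        ("c_active_nM", "active"),
        ("c_inactive_nM", "inactive"),
    ]:
        ax.plot(t, pool[col], "o-", ms=3, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("concentration (nM)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_dose_response(params, c_tot_max: float = 80.0, ax=None):
    """Model-predicted active/inactive pools against total concentration."""
    import matplotlib.pyplot as plt

    from .binding import solve_free_concentration

    if ax is None:
        _, ax = plt.subplots()
    c_tot = np.linspace(0, c_tot_max, 200)
    free, act, inact = solve_free_concentration(c_tot, params)
    ax.plot(c_tot, act, "-", label="active")
    ax.plot(c_tot, inact, "--", label="inactive")
    ax.plot(c_tot, free, ":", label="free")
    ax.set_xlabel("total concentration (nM)")
    ax.set_ylabel("pool concentration (nM)")
    ax.legend(frameon=False, fontsize=8)
    return ax
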