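"""End-to-end orchestration: simulate -> preprocess -> correlate -> fit
-> brightness-correct -> (optionally) fit the binding model.

Everything is driven by a :class:`RunConfig`, serializable to YAML, so a
run is reproducible from its config and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ScanGeometry, PSFModel
from .simulate import Movie, NucleiLayout, truth_from_concentrations, simulate_timeseries
from . import preprocess as pp
from .correlation import average_group_correlation
from . import model_fit as mf
from . import brightness as br


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_frames: int = 30
    n_rows: int = 256
    n_cols: int = 256
    group_size: int = 10
    # scan timing (paper-style defaults; frame time follows n_rows)
    pixel_size_nm: float = 31.95
    pixel_dwell_s: float = 2.06e-6
    line_time_s: float = 4.94e-3
    # optics
    w0_um: float = 0.25
    wz_um: float = 1.5
    # simulated truth
    c_green_nM: float = 30.0
    c_red_nM: float = 25.0
    phi: float = 0.5
    psi: float = 0.3
    d_um2_s: float = 2.0
    # nuclei layout
    nuclei_centers_px: tuple = ((64.0, 64.0), (64.0, 192.0), (192.0, 64.0), (192.0, 192.0))
    nuclei_radius_px: float = 60.0
    z_half_um: float = 2.5
    # analysis
    erode_px: int = 2
    max_lag: int = 32
    axial_factor: float = 1.0
    min_area_px: int = 500
    use_truth_mask: bool = False
    # brightness reference window: (start_s, end_s) or None for "whole run"
    brightness_reference_s: tuple | None = None

    def geometry(self) -> ScanGeometry:
        return ScanGeometry(
            pixel_size_nm=self.pixel_size_nm,
            pixel_dwell_s=self.pixel_dwell_s,
            line_time_s=self.line_time_s,
            frame_time_s=self.n_rows * self.line_time_s,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
        )

    def psf(self) -> PSFModel:
        return PSFModel(w0_um=self.w0_um, wz_um=self.wz_um)

    def layout(self) -> NucleiLayout:
        return NucleiLayout(
            centers_px=tuple(tuple(c) for c in self.nuclei_centers_px),
            radius_px=self.nuclei_radius_px,
            z_half_um=self.z_half_um,
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "nuclei_centers_px" in data:
            data["nuclei_centers_px"] = tuple(tuple(c) for c in data["nuclei_centers_px"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False, default_flow_style=None))


def simulate_movie(config: RunConfig) -> Movie:
    """Generate the synthetic movie a config describes."""
    geometry = config.geometry()
    layout = config.layout()
    truth = truth_from_concentrations(
        config.c_green_nM,
        config.phi,
        config.psi,
        layout,
        geometry,
        c_red_nM=config.c_red_nM,
        seed=config.seed,
        d_free_um2_s=config.d_um2_s,
    )
    return simulate_timeseries(truth, geometry, config.n_frames, layout, config.psf(), config.psf())


def analyze_movie(
    green: np.ndarray,
    red: np.ndarray | None,
    geometry: ScanGeometry,
    psf_green: PSFModel,
    psf_red: PSFModel | None = None,
    config: RunConfig | None = None,
    cycle_labels=None,
    truth_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the RICS/ccRICS analysis chain on a two-channel movie.

    Returns (pool table, brightness table), one row per frame group.
    The brightness table carries the detector-facing quantities (mean
    nuclear intensity, variance, apparent brightness, shot noise); the
    corrected amplitude/fraction columns are appended by
    :func:`apply_brightness_corrections`.
    """
    config = config or RunConfig()
    psf_red = psf_red or psf_green
    groups = pp.group_frames(
        green, red, group_size=config.group_size, frame_time_s=geometry.frame_time_s, cycle_labels=cycle_labels
    )
    pool_rows, bright_rows = [], []
    for gi, group in enumerate(groups):
        prep = pp.preprocess_group(group, seg_kwargs={"min_area_px": config.min_area_px}, erode_px=config.erode_px)
        mask = prep["mask"]
        if config.use_truth_mask and truth_mask is not None:
            mask = truth_mask
        if not mask.any():
            rec = mf.PoolRecord(time_s=group.time_s, cycle=group.cycle, flags="empty_mask")
            pool_rows.append(dataclasses.asdict(rec))
            continue
        # moving-average correction: subtracting the n-frame group mean
        # scales the fluctuation ACF of uncorrelated frames by (n-1)/n;
        # undo it so amplitudes stay unbiased
        n_mem = group.n_members
        ma_scale = n_mem / (n_mem - 1) if n_mem > 1 else 1.0
        surf_gg = average_group_correlation(prep["green"], None, mask, pair="gg", max_lag=config.max_lag)
        surf_gg.values *= ma_scale
        fast_g = mf.fit_fast_axis(surf_gg, psf_green, geometry)
        two = mf.ACFFitResult()
        if fast_g.ok:
            two = mf.fit_two_component(
                surf_gg, fast_g.amplitude, geometry, psf_green, w0_um=fast_g.w0_um, seed=config.seed + gi
            )
            two.amplitude = fast_g.amplitude
            two.flags = fast_g.flags + two.flags
        fast_r = mf.ACFFitResult()
        ccf = mf.CCFFitResult()
        if red is not None:
            surf_rr = average_group_correlation(prep["red"], None, mask, pair="rr", max_lag=config.max_lag)
            surf_rr.values *= ma_scale
            fast_r = mf.fit_fast_axis(surf_rr, psf_red, geometry)
            surf_gc = average_group_correlation(
                prep["green"], prep["red"], mask, pair="gc", max_lag=config.max_lag
            )
            surf_gc.values *= ma_scale
            ccf = mf.fit_ccf(
                surf_gc, psf_green, psf_red, geometry, axial_factor=config.axial_factor, seed=config.seed + gi
            )
        rec = mf.build_pool_record(group.time_s, two if fast_g.ok else fast_g, fast_r, ccf, psf_green, cycle=group.cycle)
        pool_rows.append(dataclasses.asdict(rec))

        # brightness on raw (background-subtracted, non-detrended) frames
        bg = prep["background_green"]
        means, varis = zip(*(br.nuclear_moments(f - bg, mask) for f in group.green))
        var0 = float(np.mean([br.background_variance(f - bg, mask) for f in group.green]))
        I, V = float(np.mean(means)), float(np.mean(varis))
        row = br.BrightnessRecord(time_s=group.time_s, intensity=I, variance=V, variance0=var0)
        if I > 0:
            row.b_app = br.apparent_brightness(I, V, var0)
            if fast_g.ok:
                row.shot = br.shot_noise(V, fast_g.amplitude, I)
                if row.shot < 0:
                    row.flags = "negative_shot_noise"
        bright_rows.append(dataclasses.asdict(row))
    return pd.DataFrame(pool_rows), pd.DataFrame(bright_rows)


def apply_brightness_corrections(
    pool: pd.DataFrame,
    bright: pd.DataFrame,
    s_factor: float | None = None,
    reference_s: tuple | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append molecular brightness, q(t) and corrected pool columns.

    ``s_factor`` defaults to the slope fitted from this run's own shot
    noise/intensity series when the series is rich enough, else the
    correction is skipped (q = 1).  ``reference_s`` is the time window
    whose maximum Q defines Q_min (no corrections inside it); default is
    the whole run.
    """
    bright = bright.copy()
    pool = pool.copy()
    if s_factor is None:
        try:
            s_factor, _ = br.estimate_s_factor(bright["shot"].values, bright["intensity"].values)
        except ValueError:
            s_factor = None
    if s_factor is not None and s_factor > 0:
        bright["q_mol"] = [
            br.molecular_brightness(b, s_factor) if np.isfinite(b) else np.nan
            for b in bright["b_app"].values
        ]
        t = bright["time_s"].values
        ref = (
            (t >= reference_s[0]) & (t <= reference_s[1])
            if reference_s is not None
            else np.ones(len(t), dtype=bool)
        )
        bright["q_norm"] = br.normalized_q(bright["q_mol"].values, ref)
        bright["corrected"] = bright["q_norm"] > 1
    else:
        bright["q_mol"] = np.nan
        bright["q_norm"] = 1.0
        bright["corrected"] = False
    q = bright["q_norm"].values
    a_new = pool["a_green"].values / q
    phi_new = pool["phi"].values / q
    pool["a_green_corrected"] = a_new
    pool["phi_corrected"] = phi_new
    scale = pool["a_green"].values / a_new  # C propto 1/A
    pool["c_tot_nM_corrected"] = pool["c_tot_nM"].values * scale
    pool["c_immobile_nM_corrected"] = phi_new * pool["c_tot_nM_corrected"]
    pool["c_free_nM_corrected"] = (1 - phi_new) * pool["c_tot_nM_corrected"]
    pool["psi_corrected"] = pool["psi"].values / q
    pool["c_active_nM_corrected"] = pool["psi_corrected"] * pool["c_tot_nM_corrected"]
    pool["c_inactive_nM_corrected"] = np.clip(
        (phi_new - pool["psi_corrected"]) * pool["c_tot_nM_corrected"], 0, None
    )
    return pool, bright


def run_full_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate a movie per the config, analyze it, write all artifacts.

    Returns a result bundle: pool and brightness DataFrames plus summary
    statistics (median over groups) and provenance.  When ``outdir`` is
    given, pool.csv, brightness.csv, config.yaml and run.json are
    written there.
    """
    movie = simulate_movie(config)
    pool, bright = analyze_movie(
        movie.green,
        movie.red,
        movie.geometry,
        movie.psf_green,
        movie.psf_red,
        config=config,
        truth_mask=movie.truth_mask,
    )
    pool, bright = apply_brightness_corrections(pool, bright, reference_s=config.brightness_reference_s)
    ok = pool["flags"].fillna("").str.contains("fit_failed|empty_mask") == False  # noqa: E712
    summary = {
        "c_tot_nM": float(np.nanmedian(pool.loc[ok, "c_tot_nM"])),
        "phi": float(np.nanmedian(pool.loc[ok, "phi"])),
        "psi": float(np.nanmedian(pool.loc[ok, "psi"])),
        "d_um2_s": float(np.nanmedian(pool.loc[ok, "d_um2_s"])),
        "n_groups": int(len(pool)),
    }
    bundle = {
        "pool": pool,
        "brightness": bright,
        "summary": summary,
        "truth": movie.truth.to_dict(),
        "provenance": {"seed": config.seed, "config_digest": config.digest()},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pool.to_csv(outdir / "pool.csv", index=False, float_format="%.10g")
        bright.to_csv(outdir / "brightness.csv", index=False, float_format="%.10g")
        config.to_yaml(outdir / "config.yaml")
        (outdir / "run.json").write_text(
            json.dumps({"summary": summary, "truth": bundle["truth"], "provenance": bundle["provenance"]}, indent=2)
        )
    return bundle
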