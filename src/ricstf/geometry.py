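"""Scan geometry and point-spread-function descriptions.

Raster-scanned confocal images have two hidden time axes: neighbouring
pixels along a line are separated by the pixel dwell time (microseconds)
while neighbouring lines are separated by the line time (milliseconds).
RICS exploits this timing asymmetry, so the geometry travels with every
correlation surface and fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

# molecules per um^3 at 1 nM  (1 nM = 1e-9 mol/L * N_A / 1e15 um^3/L)
MOLECULES_PER_UM3_PER_NM = 0.6022140857

#: default illumination shape factor for a 3D Gaussian excitation profile
GAMMA_3D_GAUSSIAN = 2.0 ** -1.5


@dataclass(frozen=True)
class ScanGeometry:
    """Timing and sampling of a raster scan.

    Parameters
    ----------
    pixel_size_nm :
        Lateral size of a pixel (nm).
    pixel_dwell_s :
        Time spent on one pixel along the fast axis (s).
    line_time_s :
        Time between the starts of consecutive lines (s); includes the
        flyback, so it is at least ``n_cols * pixel_dwell_s``.
    frame_time_s :
        Time between the starts of consecutive frames (s).
    n_rows, n_cols :
        Image shape in pixels.
    """

    pixel_size_nm: float = 31.95
    pixel_dwell_s: float = 2.06e-6
    line_time_s: float = 4.94e-3
    frame_time_s: float = field(default=0.0)
    n_rows: int = 1024
    n_cols: int = 1024

    def __post_init__(self):
        if self.frame_time_s == 0.0:
            object.__setattr__(self, "frame_time_s", self.n_rows * self.line_time_s)
        for name in ("pixel_size_nm", "pixel_dwell_s", "line_time_s", "frame_time_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("image shape must be positive")
        if self.line_time_s < self.n_cols * self.pixel_dwell_s:
            raise ValueError("line_time_s shorter than n_cols * pixel_dwell_s")
        # small slack for rounding of vendor-reported retrace timing
        if self.frame_time_s < 0.99 * self.n_rows * self.line_time_s:
            raise ValueError("frame_time_s shorter than n_rows * line_time_s")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm * 1e-3

    @staticmethod
    def line_time_from_frame(frame_time_s: float, n_rows: int) -> float:
        """Line time implied by a frame time and row count (s)."""
        if frame_time_s <= 0 or n_rows < 1:
            raise ValueError("frame_time_s and n_rows must be positive")
        return frame_time_s / n_rows

    def with_shape(self, n_rows: int, n_cols: int) -> "ScanGeometry":
        """Same per-pixel/per-line timing on a different image shape."""
        return ScanGeometry(
            pixel_size_nm=self.pixel_size_nm,
            pixel_dwell_s=self.pixel_dwell_s,
            line_time_s=self.line_time_s,
            frame_time_s=n_rows * self.line_time_s,
            n_rows=n_rows,
            n_cols=n_cols,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PSFModel:
    """3D Gaussian point spread function.

    The detection profile is ``exp(-2 r^2/w0^2 - 2 z^2/wz^2)`` with ``w0``
    and ``wz`` the lateral and axial 1/e^2 radii (um).  ``gamma`` is the
    illumination shape factor relating the ACF amplitude to the mean
    molecule number (2^-3/2 for a 3D Gaussian).
    """

    w0_um: float = 0.25
    wz_um: float = 1.5
    gamma: float = GAMMA_3D_GAUSSIAN

    def __post_init__(self):
        if self.w0_um <= 0 or self.wz_um <= 0:
            raise ValueError("PSF radii must be positive")
        if not self.w0_um < self.wz_um:
            raise ValueError("w0 must be smaller than wz")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def observation_volume_um3(self) -> float:
        """Effective volume such that N = gamma/A counts molecules in it.

        For a 3D Gaussian profile the zero-lag amplitude of the
        fluctuation ACF is exactly 1/(c * pi^{3/2} w0^2 wz), hence the
        volume paired with ``gamma`` is ``gamma * pi^{3/2} w0^2 wz``
        (= (pi/2)^{3/2} w0^2 wz at the default gamma).
        """
        import math

        return self.gamma * math.pi ** 1.5 * self.w0_um**2 * self.wz_um

    def to_dict(self) -> dict:
        return asdict(self)


def concentration_nM(count: float, volume_um3: float) -> float:
    """Concentration in nM of `count` molecules in `volume_um3`."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return count / (MOLECULES_PER_UM3_PER_NM * volume_um3)


def molecules(concentration_nM_: float, volume_um3: float) -> float:
    """Mean molecule count of a concentration (nM) in a volume (um^3)."""
    return concentration_nM_ * MOLECULES_PER_UM3_PER_NM * volume_um3
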