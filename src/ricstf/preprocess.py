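"""Movie preprocessing: background, frame grouping, segmentation, detrend.

The analysis operates on groups of 7-12 consecutive frames.  Each group
is averaged; the average frame serves two purposes: the nuclei are
segmented on it (one mask reused for every member frame), and it is
subtracted pixelwise from each member to remove static structure
("detrending"), with the scalar nuclear mean added back so intensities
keep their physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed
from skimage.measure import label as sk_label


# -- background -------------------------------------------------------------


def estimate_background(image: np.ndarray, n_bins: int = 256) -> float:
    """Background level from a Gaussian fit to the low-intensity mode.

    The pixel histogram of a fluorescence frame is bimodal: a narrow
    background mode and a broad nuclear mode.  A Gaussian is fitted
    around the lowest-intensity peak; its mean is the background.  If no
    clear low mode exists (bright unimodal image) the 1st percentile is
    returned as a fallback.
    """
    from scipy.signal import find_peaks

    img = np.asarray(image, dtype=float).ravel()
    if img.size < 1000:
        raise ValueError("image too small for background estimation")
    if np.ptp(img) == 0:
        return float(img[0])
    def low_mode(data, lo, hi):
        """(center, sigma estimate, counts, centers, peak index)."""
        counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        width = edges[1] - edges[0]
        # smooth so bin-to-bin noise does not spawn spurious modes, then
        # take the lowest-intensity prominent, substantial peak
        smooth = ndi.gaussian_filter1d(counts.astype(float), 2.0)
        peaks, _ = find_peaks(smooth, prominence=0.1 * smooth.max(), height=0.25 * smooth.max())
        peak = int(peaks[0]) if len(peaks) else int(np.argmax(smooth))
        # half-height crossings give the mode width
        half = smooth[peak] / 2.0
        left = peak
        while left > 0 and smooth[left] > half:
            left -= 1
        right = peak
        while right < len(smooth) - 1 and smooth[right] > half:
            right += 1
        sigma = max((right - left) * width / 2.355, width)
        return centers[peak], sigma, counts, centers, peak

    # coarse pass locates the background mode even when bright nuclei
    # stretch the intensity range by orders of magnitude; the fine pass
    # resolves its center and width
    c0, s0, *_ = low_mode(img, img.min(), np.percentile(img, 99.9))
    half_range = 5 * s0
    sel = img[(img >= c0 - half_range) & (img <= c0 + half_range)]
    c1, s1, counts, centers, peak = low_mode(sel, c0 - half_range, c0 + half_range)

    # Gaussian fit over the mode core (+/- 2.5 sigma around the peak)
    core = np.abs(centers - c1) <= 2.5 * s1
    x, y = centers[core], counts[core]

    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    try:
        popt, _ = curve_fit(gauss, x, y, p0=(counts[peak], c1, s1), maxfev=5000)
        mu = float(popt[1])
        if abs(mu - c1) > 2 * s1:
            raise RuntimeError("fit wandered off the low mode")
        return mu
    except RuntimeError:
        # no clean background mode (e.g. unimodal bright image)
        return float(np.percentile(img, 1.0))


# -- grouping ---------------------------------------------------------------


GROUP_MIN, GROUP_MAX = 7, 12


def plan_groups(n_frames: int, group_size: int = 10) -> list[int]:
    """Partition ``n_frames`` into group sizes within [7, 12].

    Greedy: full groups of ``group_size`` are taken while what remains
    can still form valid groups; a trailing remainder below 7 is
    redistributed over the last groups.  If no partition with all sizes
    in [7, 12] exists (only n = 13), the excess rides in the final
    group.
    """
    if not GROUP_MIN <= group_size <= GROUP_MAX:
        raise ValueError("group_size must be within [7, 12]")
    if n_frames < GROUP_MIN:
        raise ValueError(f"movie shorter than {GROUP_MIN} frames")
    sizes = []
    rem = n_frames
    while rem >= group_size + GROUP_MIN or GROUP_MIN <= rem <= GROUP_MAX:
        if GROUP_MIN <= rem <= GROUP_MAX:
            sizes.append(rem)
            rem = 0
            break
        sizes.append(group_size)
        rem -= group_size
    if rem:
        if rem > GROUP_MAX:
            # split the remainder as evenly as possible
            k = int(np.ceil(rem / GROUP_MAX))
            while k * GROUP_MIN > rem:
                k -= 1
            if k >= 1:
                base, extra = divmod(rem, k)
                sizes.extend([base + (1 if i < extra else 0) for i in range(k)])
                rem = 0
        if rem:
            if sizes:
                sizes[-1] += rem
            else:
                sizes.append(rem)
    return sizes


@dataclass
class FrameGroup:
    """A group of 7-12 consecutive frames per channel, plus derived data."""

    green: np.ndarray  # (n_members, h, w)
    red: np.ndarray | None
    time_s: float  # midpoint of the group
    cycle: str = ""
    avg_green: np.ndarray = field(init=False)
    avg_red: np.ndarray | None = field(init=False, default=None)
    mask: np.ndarray | None = None  # labeled nuclei

    def __post_init__(self):
        self.avg_green = self.green.mean(axis=0)
        if self.red is not None:
            if self.red.shape != self.green.shape:
                raise ValueError("channel shapes differ")
            self.avg_red = self.red.mean(axis=0)

    @property
    def n_members(self) -> int:
        return self.green.shape[0]


def group_frames(
    green: np.ndarray,
    red: np.ndarray | None = None,
    group_size: int = 10,
    frame_time_s: float = 1.0,
    cycle_labels=None,
) -> list[FrameGroup]:
    """Split a movie into consecutive, non-overlapping frame groups."""
    sizes = plan_groups(green.shape[0], group_size)
    groups, start = [], 0
    for s in sizes:
        sl = slice(start, start + s)
        t = (start + (s - 1) / 2.0) * frame_time_s
        cyc = cycle_labels[start] if cycle_labels is not None else ""
        groups.append(
            FrameGroup(
                green=np.asarray(green[sl], dtype=float),
                red=None if red is None else np.asarray(red[sl], dtype=float),
                time_s=t,
                cycle=cyc,
            )
        )
        start += s
    return groups


# -- segmentation -----------------------------------------------------------


def segment_nuclei(
    average_frame: np.ndarray,
    sigma_px: float = 2.0,
    min_area_px: int = 500,
    h_frac: float = 0.10,
    discard_border: bool = False,
) -> np.ndarray:
    """Label nuclei in a background-subtracted average frame.

    Gaussian smoothing -> Otsu threshold -> distance transform ->
    h-maxima seeds -> watershed.  Touching nuclei are split along the
    distance-transform ridge.  Returns a labeled int image (0 =
    background); an empty mask if nothing passes ``min_area_px``.
    """
    img = np.asarray(average_frame, dtype=float)
    sm = gaussian(img, sigma=sigma_px, preserve_range=True)
    if np.ptp(sm) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(sm)
    fg = sm > thr
    if not fg.any() or fg.all():
        return np.zeros(img.shape, dtype=np.int32)
    # contrast guard: an Otsu split of pure noise separates the modes by
    # only a couple of noise widths; real nuclei are far brighter
    if sm[fg].mean() - sm[~fg].mean() < 4.0 * sm[~fg].std():
        return np.zeros(img.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    h = max(h_frac * dist.max(), 1.0)
    seeds = sk_label(h_maxima(dist, h))
    if seeds.max() == 0:
        seeds = sk_label(fg)
    labels = watershed(-dist, markers=seeds, mask=fg)
    # prune small regions and (optionally) border-touching ones
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        n = int(region.sum())
        if n < min_area_px:
            continue
        if discard_border:
            rr, cc = np.nonzero(region)
            if (
                rr.min() == 0
                or cc.min() == 0
                or rr.max() == img.shape[0] - 1
                or cc.max() == img.shape[1] - 1
            ):
                continue
        out[region] = nxt
        nxt += 1
    return out


def correlation_mask(labels: np.ndarray, erode_px: int = 2) -> np.ndarray:
    """Boolean mask for correlation: all nuclei, eroded to drop edge
    gradients."""
    mask = labels > 0
    if erode_px > 0 and mask.any():
        mask = ndi.binary_erosion(mask, ndi.generate_binary_structure(2, 1), iterations=erode_px)
    return mask


# -- detrend ----------------------------------------------------------------


def detrend_frames(
    frames: np.ndarray, avg_frame: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Remove static structure from each frame of a group.

    ``f' = f - avg + s`` where ``s`` is the scalar mean of the average
    frame (over the nuclear mask when given, so the retained scalar is
    the nuclear intensity the correlation normalization needs).  The
    mean of each output frame over the mask equals ``s`` up to the
    frame's own fluctuation.
    """
    frames = np.asarray(frames, dtype=float)
    avg = np.asarray(avg_frame, dtype=float)
    s = float(avg[mask].mean()) if mask is not None and mask.any() else float(avg.mean())
    return frames - avg[None] + s


def preprocess_group(
    group: FrameGroup,
    subtract_background: bool = True,
    seg_kwargs: dict | None = None,
    erode_px: int = 2,
) -> dict:
    """Background-subtract, segment and detrend one frame group.

    Returns a dict with detrended member frames per channel, the
    labeled mask, the eroded correlation mask, and scalar means.
    Background is estimated on the group-average frame (lower noise than
    per-frame) and applied to all members.
    """
    seg_kwargs = seg_kwargs or {}
    bg_g = estimate_background(group.avg_green) if subtract_background else 0.0
    avg_g = group.avg_green - bg_g
    labels = segment_nuclei(avg_g, **seg_kwargs)
    mask = correlation_mask(labels, erode_px=erode_px)
    out = {
        "labels": labels,
        "mask": mask,
        "background_green": bg_g,
        "time_s": group.time_s,
        "cycle": group.cycle,
        "n_members": group.n_members,
    }
    out["green"] = detrend_frames(group.green - bg_g, avg_g, mask)
    out["mean_green"] = float(avg_g[mask].mean()) if mask.any() else float("nan")
    if group.red is not None:
        bg_r = estimate_background(group.avg_red) if subtract_background else 0.0
        avg_r = group.avg_red - bg_r
        out["background_red"] = bg_r
        out["red"] = detrend_frames(group.red - bg_r, avg_r, mask)
        out["mean_red"] = float(avg_r[mask].mean()) if mask.any() else float("nan")
    return out
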