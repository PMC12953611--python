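"""Image-quality metrics: SSIM, contrast-to-noise ratio, edge rise
distance, and PSF side-lobe energy.

SSIM follows the standard Gaussian-windowed formulation (11 px window,
sigma = 1.5, K1 = 0.01, K2 = 0.03) with the dynamic range taken from the
*reference* (first) image unless given; only fully valid windows enter the
mean.  CNR is defined as the difference of the two ROI means divided by the
standard deviation inside a background noise ROI.  The edge rise distance
is the sub-pixel distance between the 10% and 90% crossings of a normalized
edge profile — smaller is sharper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "RoiSet",
    "ssim",
    "cnr",
    "edge_rise_distance",
    "sidelobe_energy",
    "peak_sidelobe",
    "radial_edge_profiles",
]

_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03


def _gaussian_window(size: int = _SSIM_WIN, sigma: float = _SSIM_SIGMA) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def ssim(
    img_a: np.ndarray,
    img_b: np.ndarray,
    data_range: float | None = None,
) -> float:
    """Mean local structural similarity between two images.

    ``img_a`` is the reference; ``data_range`` defaults to its max - min.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("images must be finite")
    if min(a.shape) < _SSIM_WIN:
        raise ValueError(f"images must be at least {_SSIM_WIN} px per side")
    if data_range is None:
        data_range = float(a.max() - a.min())
    if data_range == 0:
        raise ValueError("zero dynamic range in the reference image")

    w = _gaussian_window()
    mu_a = fftconvolve(a, w, mode="valid")
    mu_b = fftconvolve(b, w, mode="valid")
    var_a = fftconvolve(a * a, w, mode="valid") - mu_a ** 2
    var_b = fftconvolve(b * b, w, mode="valid") - mu_b ** 2
    cov = fftconvolve(a * b, w, mode="valid") - mu_a * mu_b
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


@dataclass
class RoiSet:
    """Regions of interest for CNR: two tissue ROIs and a noise ROI, plus
    optional edge profiles for sharpness analysis."""

    myelin_roi: np.ndarray
    gm_roi: np.ndarray
    noise_roi: np.ndarray
    edge_profiles: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("myelin_roi", "gm_roi", "noise_roi"):
            m = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, m)
            if not m.any():
                raise ValueError(f"{name} is empty")
        if (
            (self.myelin_roi & self.gm_roi).any()
            or (self.myelin_roi & self.noise_roi).any()
            or (self.gm_roi & self.noise_roi).any()
        ):
            raise ValueError("ROIs must be mutually disjoint")


def cnr(image: np.ndarray, rois: RoiSet) -> float:
    """Contrast-to-noise ratio between the two tissue ROIs.

    ``(mean over myelin_roi - mean over gm_roi) / SD over noise_roi``; the
    sign indicates the contrast direction.
    """
    img = np.asarray(image, dtype=float)
    noise_sd = float(img[rois.noise_roi].std())
    if noise_sd == 0:
        raise ValueError("zero noise standard deviation in noise ROI")
    return float((img[rois.myelin_roi].mean() - img[rois.gm_roi].mean()) / noise_sd)


def edge_rise_distance(profile: np.ndarray) -> float:
    """10%-90% rise distance of an edge profile, in pixels (sub-pixel).

    The profile must trend across one edge; it is normalized to [0, 1] by
    its own extrema and flipped to rising if needed.  Crossings are linearly
    interpolated: the last upward 10% crossing before the first 90%
    crossing, and that 90% crossing itself.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise ValueError("profile must be a 1D array of length >= 2")
    if p[-1] < p[0]:
        p = p[::-1]
    rng = p.max() - p.min()
    if rng == 0:
        raise ValueError("flat profile has no edge")
    q = (p - p.min()) / rng

    def _cross(level: float, lo: int, hi: int, last: bool) -> float | None:
        hits = []
        for i in range(lo, hi):
            a, b = q[i], q[i + 1]
            if a <= level < b or (a < level <= b):
                hits.append(i + (level - a) / (b - a))
        if not hits:
            return None
        return hits[-1] if last else hits[0]

    t90 = _cross(0.9, 0, len(q) - 1, last=False)
    if t90 is None:
        raise ValueError("profile never crosses the 90% level upward")
    t10 = _cross(0.1, 0, int(np.ceil(t90)), last=True)
    if t10 is None:
        raise ValueError("profile never crosses the 10% level upward")
    return float(t90 - t10)


def sidelobe_energy(psf_image: np.ndarray, core_radius: float = 3.0) -> float:
    """Fraction of PSF energy outside a central core.

    ``sum |psf|^2 outside core_radius / sum |psf|^2``; the PSF is expected
    peak-normalized but the ratio is scale-invariant regardless.
    """
    if core_radius < 1:
        raise ValueError("core_radius must be >= 1 px")
    p = np.abs(np.asarray(psf_image)) ** 2
    n = p.shape[0]
    y, x = np.indices(p.shape)
    r = np.hypot(y - n // 2, x - (p.shape[1] // 2))
    total = p.sum()
    if total == 0:
        return 0.0
    return float(p[r > core_radius].sum() / total)


def peak_sidelobe(psf_image: np.ndarray, core_radius: float = 3.0) -> float:
    """Largest PSF magnitude outside the central core, relative to the peak.

    Coherence-sensitive companion to :func:`sidelobe_energy`: a concentrated
    streak artifact shows up as a high peak side-lobe even when its total
    energy is modest, whereas pseudo-randomly dispersed data loss yields a
    low, noise-like side-lobe floor.
    """
    if core_radius < 1:
        raise ValueError("core_radius must be >= 1 px")
    p = np.abs(np.asarray(psf_image))
    peak = p.max()
    if peak == 0:
        return 0.0
    n = p.shape[0]
    y, x = np.indices(p.shape)
    r = np.hypot(y - n // 2, x - (p.shape[1] // 2))
    return float(p[r > core_radius].max() / peak)


def radial_edge_profiles(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    half_width: float = 6.0,
    n_angles: int = 8,
    step: float = 0.5,
) -> list[np.ndarray]:
    """Sample intensity profiles along radial lines crossing a circular
    tissue boundary at ``radius`` px from ``center``.

    Used to measure the edge rise distance across the deep myelin annulus;
    profiles run from ``radius - half_width`` to ``radius + half_width``
    with sub-pixel sampling (bilinear interpolation).
    """
    from scipy.ndimage import map_coordinates

    img = np.abs(np.asarray(image, dtype=float)) if np.iscomplexobj(image) \
        else np.asarray(image, dtype=float)
    cy, cx = center
    rr = np.arange(radius - half_width, radius + half_width + 1e-9, step)
    profiles = []
    for ang in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
        ys = cy + rr * np.sin(ang)
        xs = cx + rr * np.cos(ang)
        profiles.append(map_coordinates(img, [ys, xs], order=1, mode="nearest"))
    return profiles
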