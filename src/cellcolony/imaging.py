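"""Synthetic fluorescence micrographs and nucleus-centroid detection.

Stands in for the stained two-channel images (cytoskeleton + nucleus) of the
in vitro experiment: :func:`render_nuclei` paints isotropic Gaussian blobs at
known centroid positions with additive pixel noise, and :func:`detect_nuclei`
recovers centroids by a deterministic blur -> Otsu threshold -> connected
components -> intensity-weighted centroid chain.  Only the nucleus channel is
ever analysed; the cytoskeleton channel is render-only decoration.

Convention: pixel (row, col) = (0, 0) has its centre at physical position
(0.5 * pixel_size, 0.5 * pixel_size); x maps to columns, y to rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian as _gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

from .spatial_stats import PointPattern

__all__ = ["Micrograph", "render_nuclei", "detect_nuclei", "count_vs_time"]


@dataclass
class Micrograph:
    """Raster image; intensities in [0, 1], pixel_size in um/px."""

    nucleus: np.ndarray
    pixel_size: float = 1.0
    cytoskeleton: np.ndarray | None = None

    def __post_init__(self):
        self.nucleus = np.asarray(self.nucleus, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.nucleus.ndim != 2 or min(self.nucleus.shape) < 16:
            raise ValueError("nucleus channel must be a 2-D raster of at least 16x16")


def _stamp_blobs(shape, centers_px, sigma_px, peak):
    img = np.zeros(shape)
    half = int(np.ceil(4 * sigma_px))
    for (cy, cx) in centers_px:
        r0 = max(int(np.floor(cy)) - half, 0)
        r1 = min(int(np.ceil(cy)) + half + 1, shape[0])
        c0 = max(int(np.floor(cx)) - half, 0)
        c1 = min(int(np.ceil(cx)) + half + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += peak * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma_px ** 2))
    return img


def render_nuclei(pattern: PointPattern, nucleus_sigma: float = 3.5,
                  peak: float = 0.8, noise_sigma: float = 0.02,
                  pixel_size: float = 1.0, rng=None,
                  render_cytoskeleton: bool = False) -> Micrograph:
    """Paint each point as an isotropic Gaussian blob plus iid pixel noise.

    ``nucleus_sigma`` is in um; the raster covers the pattern's window.
    Deterministic for a given ``rng`` seed; intensities clipped to [0, 1].
    """
    if nucleus_sigma <= 0:
        raise ValueError("nucleus_sigma must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x0, y0, x1, y1 = pattern.window
    shape = (int(round((y1 - y0) / pixel_size)), int(round((x1 - x0) / pixel_size)))
    # physical (x, y) -> pixel (row, col): centre of pixel k is (k + 0.5) * s
    centers = [((y - y0) / pixel_size - 0.5, (x - x0) / pixel_size - 0.5)
               for x, y in pattern.points]
    img = _stamp_blobs(shape, centers, nucleus_sigma / pixel_size, peak)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, shape)
    img = np.clip(img, 0.0, 1.0)
    cyto = None
    if render_cytoskeleton:
        # crude halo around each nucleus; never analysed downstream
        cyto = np.clip(_stamp_blobs(shape, centers, 2.5 * nucleus_sigma / pixel_size,
                                    0.5 * peak), 0.0, 1.0)
    return Micrograph(img, pixel_size=pixel_size, cytoskeleton=cyto)


def detect_nuclei(img: Micrograph, min_area_px: int = 9) -> PointPattern:
    """Recover nucleus centroids from the nucleus channel.

    Chain: Gaussian blur (1 px) -> Otsu threshold -> 8-connected components
    -> discard components below ``min_area_px`` -> intensity-weighted centroid
    (weights from the blurred image), converted to um.  Blank images yield an
    empty pattern with a warning.
    """
    raster = img.nucleus
    window = (0.0, 0.0, raster.shape[1] * img.pixel_size,
              raster.shape[0] * img.pixel_size)
    blurred = _gaussian_filter(raster, sigma=1.0, preserve_range=True)
    if np.ptp(blurred) < 1e-12:
        warnings.warn("blank image: no nuclei detected")
        return PointPattern(np.empty((0, 2)), window, meta={"n_detected": 0})
    mask = blurred > threshold_otsu(blurred)
    labels = _cc_label(mask, connectivity=2)
    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[areas >= min_area_px]
    if keep.size == 0:
        warnings.warn("no component above min_area_px: empty detection")
        return PointPattern(np.empty((0, 2)), window, meta={"n_detected": 0})
    coms = ndimage.center_of_mass(blurred * mask, labels, keep)
    pts = np.array([[(cx + 0.5) * img.pixel_size, (cy + 0.5) * img.pixel_size]
                    for cy, cx in coms])
    pts[:, 0] = np.clip(pts[:, 0], window[0], window[2])
    pts[:, 1] = np.clip(pts[:, 1], window[1], window[3])
    return PointPattern(pts, window, meta={"n_detected": len(pts)})


def count_vs_time(patterns) -> pd.DataFrame:
    """Per-time cell counts: columns time_h, mean_N, n_images, counts.

    Each pattern must carry ``meta['time_h']``; replicate images at a time
    point are aggregated, emulating a growth-curve readout.
    """
    rows = []
    for pat in patterns:
        if "time_h" not in pat.meta:
            raise ValueError("every pattern needs meta['time_h']")
        rows.append({"time_h": pat.meta["time_h"], "N": pat.N})
    df = pd.DataFrame(rows)
    out = (df.groupby("time_h")["N"]
           .agg(mean_N="mean", n_images="count", counts=lambda s: tuple(s))
           .reset_index())
    return out
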