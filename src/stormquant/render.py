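"""Super-resolution rendering, automatic segmentation and intensity readout.

Rendering turns a localization table into a raster for visualisation and for
the DoG/peak-finding stage.  ``histogram`` mode bins localizations into
half-open pixel bins (the sum of the raster equals the number of in-field
localizations); ``gaussian`` mode splats each localization as a unit-integral
Gaussian with sigma = max(precision, pixel/2).

Masks in the original study were drawn manually; :func:`auto_segment_nucleus`
is the automated fallback (smooth, Otsu threshold, fill holes, keep the
largest connected component) that makes the pipeline testable end to end.
Manually supplied masks always take precedence downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .io import Mask

logger = logging.getLogger(__name__)


@dataclass
class RenderedImage:
    """2-D intensity raster with physical pixel size and origin (nm)."""

    data: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)
    mode: str = "histogram"

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


def render(
    table: pd.DataFrame,
    pixel_size_nm: float = 10.0,
    mode: str = "histogram",
    origin_nm: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> RenderedImage:
    """Render a localization table to a raster.

    ``origin_nm``/``shape`` fix the output grid (rows, cols); by default the
    grid starts at (0, 0) and covers all localizations.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be positive")
    if len(table) == 0:
        raise ValueError("cannot render an empty localization table")
    x = table["x_nm"].to_numpy(float)
    y = table["y_nm"].to_numpy(float)
    if origin_nm is None:
        origin_nm = (0.0, 0.0)
    if shape is None:
        w = int(np.floor((x.max() - origin_nm[0]) / pixel_size_nm)) + 1
        h = int(np.floor((y.max() - origin_nm[1]) / pixel_size_nm)) + 1
        shape = (h, w)
    h, w = shape
    col = np.floor((x - origin_nm[0]) / pixel_size_nm).astype(np.int64)
    row = np.floor((y - origin_nm[1]) / pixel_size_nm).astype(np.int64)
    infield = (col >= 0) & (col < w) & (row >= 0) & (row < h)

    if mode == "histogram":
        img = np.zeros((h, w), dtype=float)
        np.add.at(img, (row[infield], col[infield]), 1.0)
    elif mode == "gaussian":
        img = np.zeros((h, w), dtype=float)
        prec = table["precision_nm"].to_numpy(float)
        sigma_px = np.maximum(prec, pixel_size_nm / 2.0) / pixel_size_nm
        cx = (x - origin_nm[0]) / pixel_size_nm
        cy = (y - origin_nm[1]) / pixel_size_nm
        for xi, yi, s in zip(cx[infield], cy[infield], sigma_px[infield]):
            r = max(1, int(np.ceil(4 * s)))
            c0, c1 = int(np.floor(xi)) - r, int(np.floor(xi)) + r + 1
            r0, r1 = int(np.floor(yi)) - r, int(np.floor(yi)) + r + 1
            c0, c1 = max(c0, 0), min(c1, w)
            r0, r1 = max(r0, 0), min(r1, h)
            if c0 >= c1 or r0 >= r1:
                continue
            gx = np.exp(-((np.arange(c0, c1) + 0.5 - xi) ** 2) / (2 * s**2))
            gy = np.exp(-((np.arange(r0, r1) + 0.5 - yi) ** 2) / (2 * s**2))
            patch = np.outer(gy, gx) / (2 * np.pi * s**2)
            img[r0:r1, c0:c1] += patch
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    return RenderedImage(img, pixel_size_nm, origin_nm, mode)


def auto_segment_nucleus(
    image: RenderedImage,
    smooth_sigma_nm: float = 500.0,
) -> Mask:
    """Segment the nucleus from a rendered DNA-channel image.

    Gaussian-smoothed density -> Otsu global threshold -> fill holes ->
    largest connected component.  Raises on an empty foreground.
    """
    sigma_px = smooth_sigma_nm / image.pixel_size_nm
    smooth = ndimage.gaussian_filter(image.data, sigma_px)
    if smooth.max() <= 0 or np.allclose(smooth, smooth.flat[0]):
        raise ValueError("empty region: blank image, cannot segment a nucleus")
    thresh = threshold_otsu(smooth)
    fg = smooth > thresh
    if not fg.any():
        raise ValueError("empty region: no foreground after thresholding")
    fg = ndimage.binary_fill_holes(fg)
    labels, n = cc_label(fg, return_num=True)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        logger.info("auto_segment_nucleus: keeping largest of %d components, discarding %d", n, n - 1)
        fg = labels == keep
    return Mask(fg, image.pixel_size_nm, image.origin_nm, "nucleus")


def make_cytoplasm_mask(
    nucleus: Mask,
    band_nm: float = 2000.0,
    cell_mask: Mask | None = None,
) -> Mask:
    """Cytoplasm region: (cell − nucleus) when a cell mask is supplied, else
    a dilation band of ``band_nm`` around the nucleus."""
    nucleus.require_nonempty()
    if cell_mask is not None:
        if cell_mask.data.shape != nucleus.data.shape or cell_mask.pixel_size_nm != nucleus.pixel_size_nm:
            raise ValueError("cell mask and nucleus mask must share a grid")
        cyto = cell_mask.data & ~nucleus.data
    else:
        r = max(1, int(round(band_nm / nucleus.pixel_size_nm)))
        dilated = ndimage.binary_dilation(nucleus.data, structure=disk(r))
        cyto = dilated & ~nucleus.data
    return Mask(cyto, nucleus.pixel_size_nm, nucleus.origin_nm, "cytoplasm")


def mean_intensity(widefield: np.ndarray, mask: Mask) -> float:
    """Mean wide-field intensity over the mask foreground (marker readout)."""
    widefield = np.asarray(widefield, dtype=float)
    if widefield.shape != mask.data.shape:
        raise ValueError(
            f"grid mismatch: image {widefield.shape} vs mask {mask.data.shape}"
        )
    mask.require_nonempty()
    return float(widefield[mask.data].mean())
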