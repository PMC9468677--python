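"""Extract aggregate geometry from a side-view image.

The tensiometer camera sees the flattened aggregate in profile: a dark,
roughly axisymmetric blob sitting on the substrate, on a bright background.
Segmentation is a global Otsu threshold (polarity auto-detected), largest
connected component, holes filled.  Geometry follows the pixel-counting
conventions below:

* height   h = (substrate row - top row + 1) * scale
* width    w = max over rows of (right - left + 1) * scale
* volume   V = sum over rows of pi * r(row)^2 * scale^3, with r(row) the
  mean of the left and right half-widths about the symmetry axis

The substrate row is the lowest populated mask row (the magnet is below the
slide); the symmetry axis is the width-weighted mean of per-row midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from .laplace_shape import GeometryObservables


class ExtractionError(ValueError):
    """Segmentation or geometry extraction failed."""


@dataclass(frozen=True)
class SideViewImage:
    """Grayscale side-view image plus its physical pixel scale (um/px)."""

    pixels: np.ndarray
    scale: float
    substrate: str = "bottom"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"pixel scale must be positive, got {self.scale}")
        if np.asarray(self.pixels).ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.substrate != "bottom":
            raise NotImplementedError("only bottom-substrate orientation is supported")

    @classmethod
    def from_file(cls, path, scale: float) -> "SideViewImage":
        import imageio.v3 as iio

        img = np.asarray(iio.imread(path), dtype=float)
        if img.ndim == 3:  # collapse RGB(A) to luminance
            img = img[..., :3].mean(axis=-1)
        return cls(pixels=img, scale=scale)


@dataclass(frozen=True)
class ExtractedContour:
    """Per-row edges of the segmented aggregate (pixel indices).

    ``rows`` are the populated row indices, ``left``/``right`` the first and
    last foreground column of each row, ``axis_col`` the (fractional)
    symmetry-axis column and ``substrate_row`` the lowest populated row.
    """

    rows: np.ndarray
    left: np.ndarray
    right: np.ndarray
    axis_col: float
    substrate_row: int

    @property
    def asymmetry(self) -> float:
        """Mean |left half-width - right half-width| over the maximal width."""
        lw = self.axis_col - self.left
        rw = self.right - self.axis_col
        w_max = (self.right - self.left + 1).max()
        return float(np.mean(np.abs(lw - rw)) / w_max)


def segment_aggregate(img: SideViewImage) -> np.ndarray:
    """Binary mask of the aggregate: Otsu threshold, largest component, filled.

    Polarity is auto-detected by assuming the border pixels are background;
    the object is kept on whichever side of the threshold the border is not.
    """
    px = np.asarray(img.pixels, dtype=float)
    if px.max() == px.min():
        raise ExtractionError("image has no contrast; cannot segment")
    t = threshold_otsu(px)
    border = np.concatenate([px[0], px[-1], px[:, 0], px[:, -1]])
    background_is_bright = np.median(border) > t
    mask = px < t if background_is_bright else px > t
    if not mask.any():
        raise ExtractionError("empty mask after thresholding")
    lbl = label(mask)
    counts = np.bincount(lbl.ravel())
    counts[0] = 0
    mask = lbl == counts.argmax()
    mask = ndimage.binary_fill_holes(mask)
    cols = np.nonzero(mask.any(axis=0))[0]
    if cols[0] == 0 or cols[-1] == mask.shape[1] - 1:
        raise ExtractionError("aggregate touches the left/right image border")
    return mask


def _contour_from_mask(mask: np.ndarray) -> ExtractedContour:
    rows = np.nonzero(mask.any(axis=1))[0]
    left = np.empty(rows.size, dtype=float)
    right = np.empty(rows.size, dtype=float)
    for i, r in enumerate(rows):
        cols = np.nonzero(mask[r])[0]
        left[i], right[i] = cols[0], cols[-1]
    widths = right - left + 1.0
    mid = (left + right) / 2.0
    axis_col = float(np.average(mid, weights=widths))
    return ExtractedContour(rows=rows, left=left, right=right, axis_col=axis_col, substrate_row=int(rows[-1]))


def extract_geometry(img: SideViewImage) -> tuple[GeometryObservables, ExtractedContour]:
    """Measure (h, w, V) in physical units and return the contour for QC.

    Volume treats each populated row as a cylinder of radius equal to the
    mean of the two half-widths about the symmetry axis — the discrete
    counterpart of the solid of revolution of the model profile.
    """
    mask = segment_aggregate(img)
    contour = _contour_from_mask(mask)
    s = img.scale
    h = (contour.substrate_row - contour.rows[0] + 1) * s
    w = (contour.right - contour.left + 1).max() * s
    half_l = contour.axis_col - contour.left + 0.5
    half_r = contour.right - contour.axis_col + 0.5
    r_rows = (half_l + half_r) / 2.0
    v = float(np.sum(np.pi * r_rows**2) * s**3)
    return GeometryObservables(h=float(h), w=float(w), V=v), contour


def write_overlay(img: SideViewImage, contour: ExtractedContour, path) -> None:
    """Save a QC figure of the image with the extracted contour overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(img.pixels, cmap="gray")
    ax.plot(contour.left, contour.rows, "r-", lw=1)
    ax.plot(contour.right, contour.rows, "r-", lw=1)
    ax.axvline(contour.axis_col, color="c", ls="--", lw=0.8)
    ax.set_title("extracted contour")
    fig.savefig(path, dpi=120)
    plt.close(fig)
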