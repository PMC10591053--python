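"""Eigen-cell analysis of extreme-scoring cells.

To characterise what the network has learned, the highest-scoring decile
of cells from sarcomatoid cores and the lowest-scoring decile from
epithelioid cores are cropped, rotated so the nucleus major axis is
vertical, masked to a small region around the cell, reduced to the
hematoxylin channel and decomposed by PCA -- the image-analysis analogue
of eigenfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon
from skimage.transform import rotate as sk_rotate

from .model import ScoreSet
from .stains import stain_deconvolve

__all__ = ["AlignedCellImage", "EigenCellResult", "select_extreme_cells",
           "polygon_major_axis_angle", "align_and_mask_cell", "eigen_cells"]


@dataclass
class AlignedCellImage:
    """H-channel patch of one cell, major axis vertical, background zeroed."""

    pixels: np.ndarray
    rotation: float  # radians applied, in [0, pi)
    core_id: str = ""
    cell_id: int = -1
    group: str = ""  # "top" (sarcomatoid decile) or "bottom"


def select_extreme_cells(scoresets: dict[str, ScoreSet],
                         subtypes: dict[str, str],
                         fraction: float = 0.10
                         ) -> tuple[list[tuple[str, int]],
                                    list[tuple[str, int]]]:
    """Pick the extreme-scoring cell ids from S and E cores.

    The top set is the ceil(fraction * n) highest cell scores among
    cells of sarcomatoid-labelled cores; the bottom set the lowest
    scores among epithelioid cores.  Score ties at the boundary are
    broken toward the lowest (core_id, cell index).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")

    def pool(label: str) -> list[tuple[float, str, int]]:
        out = []
        for cid, ss in sorted(scoresets.items()):
            if subtypes.get(cid) == label:
                out.extend((float(s), cid, i)
                           for i, s in enumerate(ss.cell_score))
        if not out:
            raise ValueError(f"no cores with label {label}")
        return out

    s_pool = pool("S")
    e_pool = pool("E")
    n_top = math.ceil(fraction * len(s_pool))
    n_bot = math.ceil(fraction * len(e_pool))
    # stable sort: primary score, ties toward earlier (core, index)
    top = sorted(s_pool, key=lambda t: (-t[0], t[1], t[2]))[:n_top]
    bottom = sorted(e_pool, key=lambda t: (t[0], t[1], t[2]))[:n_bot]
    return ([(cid, i) for _, cid, i in top],
            [(cid, i) for _, cid, i in bottom])


def _polygon_moments(coords: np.ndarray) -> tuple[float, float, float]:
    """Central second moments (mxx, myy, mxy) of a polygon interior."""
    x = coords[:, 0]
    y = coords[:, 1]
    x1 = np.roll(x, -1)
    y1 = np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    if area == 0:
        raise ValueError("degenerate polygon")
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    mxx = ((x**2 + x * x1 + x1**2) * cross).sum() / (12.0 * area) - cx**2
    myy = ((y**2 + y * y1 + y1**2) * cross).sum() / (12.0 * area) - cy**2
    mxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() \
        / (24.0 * area) - cx * cy
    return mxx, myy, mxy


def polygon_major_axis_angle(polygon: Polygon) -> float:
    """Major-axis angle from the x-axis, in [0, pi)."""
    coords = np.asarray(polygon.exterior.coords)[:-1]
    mxx, myy, mxy = _polygon_moments(coords)
    angle = 0.5 * math.atan2(2.0 * mxy, mxx - myy)
    return angle % math.pi


def align_and_mask_cell(image: np.ndarray, nucleus_polygon: Polygon,
                        cell_polygon: Polygon, mpp: float,
                        patch_size: int = 72,
                        dilation_margin_um: float = 2.0,
                        core_id: str = "", cell_id: int = -1,
                        group: str = "") -> AlignedCellImage:
    """Rotate, mask and crop one cell's H-channel image.

    The patch is rotated about the nucleus centroid by minus the major
    axis angle (so the axis ends up vertical), masked to the cell
    polygon dilated by ``dilation_margin_um``, and cropped to
    ``patch_size`` squared.
    """
    angle = polygon_major_axis_angle(nucleus_polygon)
    rotation = (angle - math.pi / 2.0) % math.pi
    if math.pi - rotation < 1e-9:  # axis angle: pi is the same as 0
        rotation = 0.0

    c = nucleus_polygon.centroid
    cr, cc = c.y / mpp, c.x / mpp
    half = patch_size  # extra margin so rotation never clips the cell
    window = 2 * half + 1
    pad = ((half, half), (half, half), (0, 0))
    padded = np.pad(image, pad, mode="reflect")
    r0 = int(round(cr))
    c0 = int(round(cc))
    patch_rgb = padded[r0:r0 + window, c0:c0 + window]
    h_chan = stain_deconvolve(patch_rgb).hematoxylin

    mask_poly = cell_polygon.buffer(dilation_margin_um, quad_segs=4)
    coords = np.asarray(mask_poly.exterior.coords).copy()
    coords[:, 0] = coords[:, 0] / mpp - c0 + half
    coords[:, 1] = coords[:, 1] / mpp - r0 + half
    mask = np.zeros(h_chan.shape, dtype=float)
    rr, cc_idx = draw_polygon(coords[:, 1], coords[:, 0],
                              shape=h_chan.shape)
    mask[rr, cc_idx] = 1.0

    # with rows growing downward, skimage's rotation decreases the
    # moment angle of the content, so the sign is positive here
    deg = math.degrees(rotation)
    h_rot = sk_rotate(h_chan, deg, center=(half, half), order=3,
                      preserve_range=True)
    # bilinear mask rotation then thresholding tracks the true rotated
    # boundary more faithfully than nearest-neighbour snapping
    m_rot = sk_rotate(mask, deg, center=(half, half), order=1,
                      preserve_range=True)
    out = h_rot * (m_rot > 0.5)
    lo = half - patch_size // 2
    out = out[lo:lo + patch_size, lo:lo + patch_size]
    return AlignedCellImage(pixels=out, rotation=rotation,
                            core_id=core_id, cell_id=cell_id, group=group)


@dataclass
class EigenCellResult:
    """PCA decomposition of aligned cell images."""

    mean_image: np.ndarray
    components: np.ndarray        # (k, h, w), orthonormal
    projections: np.ndarray       # (n, k), centred
    explained_variance: np.ndarray

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        k = n_components or self.components.shape[0]
        flat = self.projections[:, :k] @ \
            self.components[:k].reshape(k, -1)
        return flat.reshape((-1,) + self.mean_image.shape) \
            + self.mean_image


def eigen_cells(images: list[AlignedCellImage] | list[np.ndarray],
                n_components: int = 10) -> EigenCellResult:
    """PCA of aligned cell images ('eigen-cells').

    Components are orthonormal with nonincreasing explained variance;
    each component's sign is fixed so its maximum-magnitude pixel is
    positive, making the decomposition reproducible up to ordering.
    """
    arrays = [im.pixels if isinstance(im, AlignedCellImage) else
              np.asarray(im, dtype=np.float64) for im in images]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all images must share one shape")
    if len(arrays) < n_components + 1:
        raise ValueError("need more images than components")
    x = np.stack([a.ravel() for a in arrays])
    mean = x.mean(axis=0)
    centred = x - mean
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    comps = vt[:n_components]
    # sign fix: maximum-magnitude pixel positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    proj = centred @ comps.T
    ev = (s[:n_components] ** 2) / max(1, len(arrays) - 1)
    return EigenCellResult(
        mean_image=mean.reshape(shape),
        components=comps.reshape((n_components,) + shape),
        projections=proj,
        explained_variance=ev,
    )
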