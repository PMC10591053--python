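"""Per-cell feature extraction for cell graphs.

The canonical schema mirrors the QuPath-style cell measurements used for
cell-graph nodes, grouped as:

* ``shape`` (10): area, perimeter, circularity, max/min caliper diameter
  for nucleus and whole cell (um / um^2);
* ``intensity`` (18): mean, median, population SD of the hematoxylin and
  eosin OD channels over nucleus, cytoplasm and whole cell;
* ``smoothed`` (29): shape+intensity features smoothed over nearby cells
  with a Gaussian kernel of 50 um support diameter, plus the nearby
  detection count;
* ``delaunay`` (33): Delaunay neighbour count, edge-length statistics and
  neighbourhood means of the shape+intensity features;
* ``haralick`` (39): the 13 classical co-occurrence texture statistics on
  a small circular region around each detection, for the hematoxylin,
  eosin and total-OD channels;
* ``deep`` (optional, 512): embedding of the 72x72 RGB patch centred on
  the cell, from a pluggable backbone.

Pixel/um conversion happens once at extraction time through the image
microns-per-pixel; all downstream constants (30 um graph radius, 50 um
smoothing kernel) are physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import Polygon
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon

from .graphs import DelaunayResult, delaunay_adjacency
from .stains import HE_STAIN_MATRIX, StainChannels, stain_deconvolve

__all__ = [
    "FeatureSchema", "canonical_schema", "shape_features",
    "intensity_features", "smooth_features", "delaunay_cluster_features",
    "haralick_features", "deep_features", "random_projection_backbone",
    "extract_patch", "compute_core_features", "Standardizer",
    "assemble_feature_matrix", "SHAPE_NAMES", "INTENSITY_NAMES",
    "HARALICK_STAT_NAMES",
]

SHAPE_NAMES = [
    f"{comp}_{name}"
    for comp in ("nucleus", "cell")
    for name in ("area", "perimeter", "circularity",
                 "max_caliper", "min_caliper")
]

INTENSITY_NAMES = [
    f"{stain}_{stat}_{comp}"
    for stain in ("h", "e")
    for stat in ("mean", "median", "sd")
    for comp in ("nucleus", "cytoplasm", "cell")
]

HARALICK_STAT_NAMES = [
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
]

SMOOTH_KERNEL_DIAMETER_UM = 50.0
HARALICK_REGION_RADIUS_UM = 15.0
HARALICK_LEVELS = 32
DEEP_PATCH_SIZE = 72
DEEP_EMBEDDING_DIM = 512


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature layout stored with every feature matrix."""

    entries: tuple[tuple[str, str, str], ...]  # (name, group, units)

    @property
    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def groups(self) -> list[str]:
        return [e[1] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __post_init__(self):
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")


def canonical_schema(include_deep: bool = False) -> FeatureSchema:
    """The documented feature enumeration used throughout the package."""
    entries: list[tuple[str, str, str]] = []
    for name in SHAPE_NAMES:
        units = "um^2" if name.endswith("area") else (
            "" if name.endswith("circularity") else "um")
        entries.append((name, "shape", units))
    for name in INTENSITY_NAMES:
        entries.append((name, "intensity", "od"))
    for name in SHAPE_NAMES + INTENSITY_NAMES:
        entries.append((f"smoothed_{name}", "smoothed", "mixed"))
    entries.append(("nearby_detection_count", "smoothed", "count"))
    entries.append(("delaunay_neighbor_count", "delaunay", "count"))
    for stat in ("mean", "median", "min", "max"):
        entries.append((f"delaunay_edge_{stat}", "delaunay", "um"))
    for name in SHAPE_NAMES + INTENSITY_NAMES:
        entries.append((f"cluster_mean_{name}", "delaunay", "mixed"))
    for channel in ("h", "e", "odsum"):
        for stat in HARALICK_STAT_NAMES:
            entries.append((f"haralick_{channel}_{stat}", "haralick", ""))
    if include_deep:
        for i in range(DEEP_EMBEDDING_DIM):
            entries.append((f"deep_{i:03d}", "deep", ""))
    return FeatureSchema(tuple(entries))


# ---------------------------------------------------------------------------
# shape


def _caliper_diameters(poly: Polygon) -> tuple[float, float]:
    """Max and min caliper (Feret) diameters via the convex hull."""
    hull = np.asarray(poly.convex_hull.exterior.coords)[:-1]
    d = np.linalg.norm(hull[:, None, :] - hull[None, :, :], axis=-1)
    max_cal = float(d.max())
    # min width: smallest extent over hull edge normals (rotating calipers)
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.column_stack([-edges[:, 1], edges[:, 0]])
    normals = normals[lengths > 0] / lengths[lengths > 0, None]
    proj = hull @ normals.T
    min_cal = float((proj.max(axis=0) - proj.min(axis=0)).min())
    return max_cal, min_cal


def _one_compartment_shape(poly: Polygon) -> list[float]:
    if len(poly.exterior.coords) < 4:  # closed ring repeats first vertex
        raise ValueError("degenerate polygon (<3 vertices)")
    area = poly.area
    perim = poly.length
    if area <= 0 or perim <= 0:
        raise ValueError("polygon must have positive area and perimeter")
    circ = min(1.0, 4.0 * math.pi * area / perim**2)
    max_cal, min_cal = _caliper_diameters(poly)
    return [area, perim, circ, max_cal, min_cal]


def shape_features(nucleus_polygon: Polygon,
                   cell_polygon: Polygon) -> dict[str, float]:
    """Area, perimeter, circularity and caliper diameters per compartment.

    Circularity is 4*pi*A/P^2 clipped to [0, 1]; caliper diameters are
    the max and min widths of the convex hull.
    """
    values = (_one_compartment_shape(nucleus_polygon)
              + _one_compartment_shape(cell_polygon))
    return dict(zip(SHAPE_NAMES, values))


# ---------------------------------------------------------------------------
# intensity


def _stats(values: np.ndarray) -> tuple[float, float, float]:
    # population SD (ddof=0), matching the documented convention
    return (float(values.mean()), float(np.median(values)),
            float(values.std()))


def intensity_features(channels: StainChannels,
                       nucleus_mask: np.ndarray,
                       cell_mask: np.ndarray) -> dict[str, float]:
    """Mean/median/SD of the H and E channels per cell compartment.

    Cytoplasm is the cell mask minus the nucleus mask; an empty cytoplasm
    yields the sentinel 0 with the ``cytoplasm_empty`` flag set.
    """
    if channels.hematoxylin.shape != nucleus_mask.shape:
        raise ValueError("mask/image shape mismatch")
    if not nucleus_mask.any() or not cell_mask.any():
        raise ValueError("nucleus and cell masks must be nonempty")
    cyto_mask = cell_mask & ~nucleus_mask
    out: dict[str, float] = {}
    for stain, img in (("h", channels.hematoxylin), ("e", channels.eosin)):
        for comp, mask in (("nucleus", nucleus_mask),
                           ("cytoplasm", cyto_mask),
                           ("cell", cell_mask)):
            if mask.any():
                m, med, sd = _stats(img[mask])
            else:
                m = med = sd = 0.0
            out[f"{stain}_mean_{comp}"] = m
            out[f"{stain}_median_{comp}"] = med
            out[f"{stain}_sd_{comp}"] = sd
    out["cytoplasm_empty"] = float(not cyto_mask.any())
    return out


# ---------------------------------------------------------------------------
# smoothing


def smooth_features(centroids: np.ndarray, base: pd.DataFrame,
                    kernel_diameter: float = SMOOTH_KERNEL_DIAMETER_UM
                    ) -> pd.DataFrame:
    """Gaussian-smooth features over nearby cells; count neighbours.

    The kernel diameter is the full support: sigma = diameter/4 and the
    kernel is truncated at diameter/2, so for the default 50 um kernel
    sigma is 12.5 um and cells beyond 25 um contribute nothing.  Each
    cell's own value is included at weight 1.  The extra
    ``nearby_detection_count`` column counts other cells within support.
    """
    if kernel_diameter <= 0:
        raise ValueError("kernel_diameter must be positive")
    centroids = np.asarray(centroids, dtype=np.float64)
    support = kernel_diameter / 2.0
    sigma = kernel_diameter / 4.0
    tree = cKDTree(centroids)
    values = base.to_numpy(dtype=np.float64)
    smoothed = np.empty_like(values)
    counts = np.empty(len(base), dtype=np.int64)
    for i, nbrs in enumerate(tree.query_ball_point(centroids, support)):
        nbrs = np.asarray(nbrs)
        d = np.linalg.norm(centroids[nbrs] - centroids[i], axis=1)
        w = np.exp(-0.5 * (d / sigma) ** 2)
        smoothed[i] = w @ values[nbrs] / w.sum()
        counts[i] = len(nbrs) - 1
    out = pd.DataFrame(smoothed, columns=[f"smoothed_{c}" for c in base],
                       index=base.index)
    out["nearby_detection_count"] = counts
    return out


# ---------------------------------------------------------------------------
# delaunay cluster features


def delaunay_cluster_features(adjacency: DelaunayResult,
                              base: pd.DataFrame) -> pd.DataFrame:
    """Neighbour counts, edge-length statistics and neighbourhood means.

    Neighbour means are taken over the cell itself plus its Delaunay
    neighbours; cells with no neighbours keep their own values and get
    zero-length statistics, flagged in ``delaunay_isolated``.
    """
    n = len(base)
    values = base.to_numpy(dtype=np.float64)
    rows = np.empty((n, 5), dtype=np.float64)
    means = np.empty_like(values)
    isolated = np.zeros(n, dtype=np.float64)
    for i in range(n):
        nbrs = adjacency.neighbors[i]
        lengths = adjacency.edge_lengths[i]
        if nbrs.size:
            rows[i] = [nbrs.size, lengths.mean(), np.median(lengths),
                       lengths.min(), lengths.max()]
            means[i] = values[np.concatenate([[i], nbrs])].mean(axis=0)
        else:
            rows[i] = [0, 0.0, 0.0, 0.0, 0.0]
            means[i] = values[i]
            isolated[i] = 1.0
    out = pd.DataFrame(
        rows, columns=["delaunay_neighbor_count", "delaunay_edge_mean",
                       "delaunay_edge_median", "delaunay_edge_min",
                       "delaunay_edge_max"], index=base.index)
    cluster = pd.DataFrame(means,
                           columns=[f"cluster_mean_{c}" for c in base],
                           index=base.index)
    out = pd.concat([out, cluster], axis=1)
    out.attrs["delaunay_fallback"] = adjacency.fallback_used
    out.attrs["delaunay_isolated"] = isolated
    return out


# ---------------------------------------------------------------------------
# haralick texture


def _masked_glcm(levels_img: np.ndarray, mask: np.ndarray,
                 n_levels: int, distance: int = 1) -> np.ndarray:
    """Symmetric, direction-averaged GLCM over masked pixels only."""
    offsets = [(0, distance), (distance, 0),
               (distance, distance), (distance, -distance)]
    glcm = np.zeros((n_levels, n_levels), dtype=np.float64)
    h, w = levels_img.shape
    for dr, dc in offsets:
        r0 = np.arange(max(0, -dr), min(h, h - dr))
        c0 = np.arange(max(0, -dc), min(w, w - dc))
        if r0.size == 0 or c0.size == 0:
            continue
        rr, cc = np.meshgrid(r0, c0, indexing="ij")
        valid = mask[rr, cc] & mask[rr + dr, cc + dc]
        a = levels_img[rr, cc][valid]
        b = levels_img[rr + dr, cc + dc][valid]
        np.add.at(glcm, (a, b), 1.0)
        np.add.at(glcm, (b, a), 1.0)  # symmetric
    total = glcm.sum()
    if total > 0:
        glcm /= total
    return glcm


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_from_glcm(p: np.ndarray) -> dict[str, float]:
    """The 13 classical texture statistics of a normalised GLCM.

    Correlation (and the information measures) are defined as 0 for
    degenerate zero-variance regions.
    """
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = math.sqrt(max(0.0, float(((i - mu_x) ** 2) @ px)))
    sd_y = math.sqrt(max(0.0, float(((i - mu_y) ** 2) @ py)))

    # sum / difference distributions
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * n - 1, dtype=np.float64)
    k_diff = np.arange(n, dtype=np.float64)

    asm = float((p ** 2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x * sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y)
                            / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = -float(_xlog2x(p_sum).sum())
    entropy = -float(_xlog2x(p).sum())
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    difference_entropy = -float(_xlog2x(p_diff).sum())

    hxy = entropy
    hx = -float(_xlog2x(px).sum())
    hy = -float(_xlog2x(py).sum())
    pxpy = px[:, None] * py[None, :]
    nz = (p > 0) & (pxpy > 0)
    hxy1 = -float((p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = -float((pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "asm": asm, "contrast": contrast, "correlation": correlation,
        "variance": variance, "idm": idm, "sum_average": sum_average,
        "sum_variance": sum_variance, "sum_entropy": sum_entropy,
        "entropy": entropy, "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1, "imc2": imc2,
    }


def haralick_features(channel_patch: np.ndarray, circular_mask: np.ndarray,
                      n_levels: int = HARALICK_LEVELS,
                      distance: int = 1) -> dict[str, float]:
    """13 texture statistics over the circular region of one channel.

    The region is quantised to ``n_levels`` grey levels by per-region
    min-max scaling; the co-occurrence matrix is symmetric, normalised
    and averaged over the four standard directions at the given pixel
    distance.
    """
    if channel_patch.shape != circular_mask.shape:
        raise ValueError("patch/mask shape mismatch")
    if not circular_mask.any():
        raise ValueError("region entirely outside image")
    vals = channel_patch[circular_mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels_img = np.zeros(channel_patch.shape, dtype=np.int64)
    if hi > lo:
        scaled = (channel_patch - lo) / (hi - lo)
        levels_img = np.clip((scaled * n_levels).astype(np.int64),
                             0, n_levels - 1)
    glcm = _masked_glcm(levels_img, circular_mask, n_levels, distance)
    return haralick_from_glcm(glcm)


# ---------------------------------------------------------------------------
# deep embedding (pluggable backbone)

_PROJECTION_CACHE: dict[int, np.ndarray] = {}


def random_projection_backbone(patch: np.ndarray,
                               dim: int = DEEP_EMBEDDING_DIM) -> np.ndarray:
    """Deterministic seeded random-projection embedding of a patch.

    A fixed Gaussian projection of the standardised pixel vector; not a
    learned network, but a stable, deterministic 512-d embedding with the
    same interface, so a pretrained CNN can be swapped in via the
    ``backbone`` argument of :func:`deep_features`.
    """
    flat = patch.astype(np.float64).ravel()
    flat = (flat - flat.mean()) / (flat.std() + 1e-8)
    key = (flat.size, dim).__hash__()
    if key not in _PROJECTION_CACHE:
        rng = np.random.default_rng(20230517)
        _PROJECTION_CACHE[key] = rng.normal(
            0.0, 1.0 / math.sqrt(flat.size), (flat.size, dim))
    return flat @ _PROJECTION_CACHE[key]


def deep_features(rgb_patch: np.ndarray,
                  backbone="default") -> np.ndarray | None:
    """Embed a 72x72 RGB patch with the configured backbone.

    ``backbone`` may be "default" (random projection, 512-d), "none"
    (deep group disabled; returns None), or any callable mapping a
    (72, 72, 3) array to a 1-d vector.
    """
    if backbone == "none" or backbone is None:
        return None
    if rgb_patch.shape != (DEEP_PATCH_SIZE, DEEP_PATCH_SIZE, 3):
        raise ValueError(
            f"patch must be {DEEP_PATCH_SIZE}x{DEEP_PATCH_SIZE}x3, "
            f"got {rgb_patch.shape}")
    if backbone == "default":
        return random_projection_backbone(rgb_patch)
    return np.asarray(backbone(rgb_patch), dtype=np.float64)


def extract_patch(image: np.ndarray, centre_px: tuple[float, float],
                  size: int = DEEP_PATCH_SIZE) -> np.ndarray:
    """Crop a size x size patch centred on a pixel, reflect-padded."""
    half = size // 2
    r, c = int(round(centre_px[0])), int(round(centre_px[1]))
    pad = ((half, half), (half, half), (0, 0))
    padded = np.pad(image, pad, mode="reflect")
    return padded[r:r + size, c:c + size]


# ---------------------------------------------------------------------------
# per-core assembly


def _rasterize(poly_um: np.ndarray, mpp: float,
               shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    return draw_polygon(poly_um[:, 1] / mpp, poly_um[:, 0] / mpp,
                        shape=shape)


def compute_core_features(detections: pd.DataFrame, image: np.ndarray,
                          mpp: float,
                          include_deep: bool = False,
                          backbone="default") -> pd.DataFrame:
    """Full per-cell feature table for one core, ordered by the schema."""
    schema = canonical_schema(include_deep=include_deep)
    channels = stain_deconvolve(image)
    shape_hw = image.shape[:2]
    n = len(detections)
    centroids = detections[["cx_um", "cy_um"]].to_numpy(dtype=np.float64)

    base_rows = []
    haralick_rows = []
    deep_rows = []
    disk_r_px = HARALICK_REGION_RADIUS_UM / mpp
    for row in detections.itertuples(index=False):
        nucleus = shapely_wkt.loads(row.nucleus_wkt)
        cell = shapely_wkt.loads(row.cell_wkt)
        feats = shape_features(nucleus, cell)

        # local bounding-box window keeps per-cell work O(cell size)
        minx, miny, maxx, maxy = cell.bounds
        br0 = int(np.clip(math.floor(miny / mpp) - 1, 0, shape_hw[0] - 1))
        br1 = int(np.clip(math.ceil(maxy / mpp) + 2, 1, shape_hw[0]))
        bc0 = int(np.clip(math.floor(minx / mpp) - 1, 0, shape_hw[1] - 1))
        bc1 = int(np.clip(math.ceil(maxx / mpp) + 2, 1, shape_hw[1]))
        local_shape = (br1 - br0, bc1 - bc0)
        local_channels = StainChannels(
            hematoxylin=channels.hematoxylin[br0:br1, bc0:bc1],
            eosin=channels.eosin[br0:br1, bc0:bc1],
            od_sum=channels.od_sum[br0:br1, bc0:bc1])

        def local_mask(poly: Polygon) -> np.ndarray:
            coords = np.asarray(poly.exterior.coords).copy()
            coords[:, 0] -= bc0 * mpp
            coords[:, 1] -= br0 * mpp
            mask = np.zeros(local_shape, dtype=bool)
            rr, cc = _rasterize(coords, mpp, local_shape)
            mask[rr, cc] = True
            return mask

        nuc_mask = local_mask(nucleus)
        cell_mask = local_mask(cell) | nuc_mask
        if not nuc_mask.any():  # sub-pixel cell at coarse mpp
            r = int(np.clip(round(row.cy_um / mpp) - br0, 0,
                            local_shape[0] - 1))
            c = int(np.clip(round(row.cx_um / mpp) - bc0, 0,
                            local_shape[1] - 1))
            nuc_mask[r, c] = True
            cell_mask[r, c] = True
        inten = intensity_features(local_channels, nuc_mask, cell_mask)
        inten.pop("cytoplasm_empty")
        feats.update(inten)
        base_rows.append(feats)

        # circular texture region
        cr, cc_px = row.cy_um / mpp, row.cx_um / mpp
        r0 = int(max(0, math.floor(cr - disk_r_px)))
        r1 = int(min(shape_hw[0], math.ceil(cr + disk_r_px) + 1))
        c0 = int(max(0, math.floor(cc_px - disk_r_px)))
        c1 = int(min(shape_hw[1], math.ceil(cc_px + disk_r_px) + 1))
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"cell {row.cell_id}: texture region outside"
                             " image")
        rows_idx, cols_idx = np.meshgrid(np.arange(r0, r1),
                                         np.arange(c0, c1), indexing="ij")
        disk = ((rows_idx - cr) ** 2 + (cols_idx - cc_px) ** 2
                <= disk_r_px ** 2)
        hrow: dict[str, float] = {}
        for ch_name, img in (("h", channels.hematoxylin),
                             ("e", channels.eosin),
                             ("odsum", channels.od_sum)):
            stats = haralick_features(img[r0:r1, c0:c1], disk)
            for stat, v in stats.items():
                hrow[f"haralick_{ch_name}_{stat}"] = v
        haralick_rows.append(hrow)

        if include_deep:
            patch = extract_patch(image, (cr, cc_px))
            deep_rows.append(deep_features(patch, backbone=backbone))

    base = pd.DataFrame(base_rows)[SHAPE_NAMES + INTENSITY_NAMES]
    smoothed = smooth_features(centroids, base)
    delaunay = delaunay_cluster_features(delaunay_adjacency(centroids), base)
    haralick = pd.DataFrame(haralick_rows)
    parts = [base, smoothed, delaunay, haralick]
    if include_deep:
        parts.append(pd.DataFrame(
            np.asarray(deep_rows),
            columns=[f"deep_{i:03d}" for i in range(DEEP_EMBEDDING_DIM)]))
    table = pd.concat(parts, axis=1)[schema.names]
    table.attrs["schema"] = schema
    return table


@dataclass
class Standardizer:
    """Column z-scoring fitted on training cores and reused at test time."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sd: np.ndarray = field(default_factory=lambda: np.zeros(0))
    names: list[str] = field(default_factory=list)

    def fit(self, matrices: list[pd.DataFrame]) -> "Standardizer":
        stacked = pd.concat(matrices, axis=0)
        self.names = list(stacked.columns)
        arr = stacked.to_numpy(dtype=np.float64)
        self.mean = arr.mean(axis=0)
        self.sd = arr.std(axis=0)
        self.sd[self.sd == 0] = 1.0  # constant columns pass through
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if list(matrix.columns) != self.names:
            raise ValueError("schema mismatch in standardization")
        arr = (matrix.to_numpy(dtype=np.float64) - self.mean) / self.sd
        if not np.isfinite(arr).all():
            raise ValueError("non-finite values after standardization")
        return pd.DataFrame(arr, columns=self.names, index=matrix.index)

    def inverse_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        arr = matrix.to_numpy(dtype=np.float64) * self.sd + self.mean
        return pd.DataFrame(arr, columns=self.names, index=matrix.index)


def assemble_feature_matrix(
    group_tables: dict[str, pd.DataFrame],
    schema: FeatureSchema,
) -> pd.DataFrame:
    """Concatenate per-group feature tables in schema order.

    Raises if any schema group is missing from ``group_tables`` or any
    named column is absent.
    """
    present = pd.concat(group_tables.values(), axis=1)
    missing = [n for n in schema.names if n not in present.columns]
    if missing:
        raise ValueError(f"missing features: {missing[:5]}...")
    table = present[schema.names]
    table.attrs["schema"] = schema
    return table
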