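"""Synthetic tissue-microarray cores with known cell-level composition.

Real mesothelioma TMA cohorts are access-controlled, so every downstream
stage (features, graphs, training, evaluation) is exercised on simulated
cores instead.  A core is a hard-core point pattern of textured elliptical
cells inside a circular disc.  Two phenotypes are planted:

* ``epithelioid`` -- smaller, rounder nuclei, lower stain density;
* ``sarcomatoid`` -- larger, elongated (spindle-like) nuclei, denser
  hematoxylin uptake and a slightly more dispersed spatial pattern.

Bags (cores) carry an ordinal subtype label E < B < S encoding the
expected predominance of sarcomatoid cells, with biphasic cores containing
a controlled sarcomatoid fraction ``rho``.

Detection tables are plain :class:`pandas.DataFrame` objects with columns

    core_id, cell_id, cx_um, cy_um, nucleus_wkt, cell_wkt, planted_class

plus the synthetic-only rendering columns ``stain_h``, ``stain_e``,
``texture_contrast``.  All geometry is in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .stains import HE_STAIN_MATRIX

__all__ = [
    "CellPhenotypeSpec",
    "CoreSpec",
    "CohortCore",
    "InfeasibleDensityError",
    "default_phenotypes",
    "sample_cell_population",
    "render_core",
    "simulate_cohort",
    "SUBTYPE_TO_LABELS",
]

#: ordinal labels for the two ranking tasks; they always sum to 2.
SUBTYPE_TO_LABELS = {
    "E": (0, 2),  # (sarcomatoid task, epithelioid task)
    "B": (1, 1),
    "S": (2, 0),
}

DETECTION_COLUMNS = [
    "core_id", "cell_id", "cx_um", "cy_um",
    "nucleus_wkt", "cell_wkt", "planted_class",
]


class InfeasibleDensityError(RuntimeError):
    """Raised when hard-core sampling cannot place the requested cells."""


@dataclass(frozen=True)
class CellPhenotypeSpec:
    """Morphology and staining distribution of one planted cell class.

    Areas are nucleus areas in um^2; eccentricity is the ellipse
    eccentricity in [0, 1); stain levels are optical-density-like
    amplitudes for the hematoxylin / eosin pseudo-stains.
    """

    class_name: str
    area_mean: float
    area_sd: float
    eccentricity_mean: float
    eccentricity_sd: float
    texture_contrast: float
    stain_h_mean: float
    stain_h_sd: float
    stain_e_mean: float
    stain_e_sd: float
    cytoplasm_margin_um: float = 2.5

    def __post_init__(self) -> None:
        if self.area_mean <= 0:
            raise ValueError("area_mean must be positive")
        if min(self.area_sd, self.eccentricity_sd,
               self.stain_h_sd, self.stain_e_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.eccentricity_mean < 1:
            raise ValueError("eccentricity_mean must lie in [0, 1)")
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be >= 0")


def default_phenotypes() -> dict[str, CellPhenotypeSpec]:
    """Default epithelioid / sarcomatoid phenotype pair.

    Sarcomatoid cells get larger, more elongated nuclei, stronger
    hematoxylin uptake and coarser chromatin texture, mirroring the
    qualitative spindle-cell morphology of the sarcomatoid subtype.
    """
    return {
        "epithelioid": CellPhenotypeSpec(
            class_name="epithelioid",
            area_mean=40.0, area_sd=8.0,
            eccentricity_mean=0.35, eccentricity_sd=0.12,
            texture_contrast=0.06,
            stain_h_mean=0.55, stain_h_sd=0.06,
            stain_e_mean=0.25, stain_e_sd=0.04,
        ),
        "sarcomatoid": CellPhenotypeSpec(
            class_name="sarcomatoid",
            area_mean=60.0, area_sd=15.0,
            eccentricity_mean=0.85, eccentricity_sd=0.07,
            texture_contrast=0.14,
            stain_h_mean=0.75, stain_h_sd=0.08,
            stain_e_mean=0.20, stain_e_sd=0.04,
        ),
    }


@dataclass(frozen=True)
class CoreSpec:
    """Composition and geometry of one simulated core (one bag)."""

    n_cells: int
    sarcomatoid_fraction: float
    bag_class: str
    core_diameter: float = 500.0
    spatial_dispersion: str = "uniform"
    component_arrangement: str = "regional"
    rho_e_max: float = 0.05
    rho_s_min: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2")
        if not 0.0 <= self.sarcomatoid_fraction <= 1.0:
            raise ValueError("sarcomatoid_fraction must lie in [0, 1]")
        if self.bag_class not in ("E", "B", "S"):
            raise ValueError("bag_class must be one of E, B, S")
        if self.spatial_dispersion not in ("uniform", "clustered"):
            raise ValueError("spatial_dispersion must be uniform|clustered")
        if self.component_arrangement not in ("regional", "mixed"):
            raise ValueError(
                "component_arrangement must be regional|mixed")
        rho = self.sarcomatoid_fraction
        if self.bag_class == "E" and rho > self.rho_e_max:
            raise ValueError(f"E core requires rho <= {self.rho_e_max}")
        if self.bag_class == "S" and rho < self.rho_s_min:
            raise ValueError(f"S core requires rho >= {self.rho_s_min}")
        if self.bag_class == "B" and not (self.rho_e_max < rho < self.rho_s_min):
            raise ValueError("B core requires rho strictly between bounds")


def _ellipse_polygon(cx: float, cy: float, area: float, ecc: float,
                     theta: float, n_vertices: int = 24) -> Polygon:
    """Ellipse of given area/eccentricity/orientation as a polygon."""
    ratio = math.sqrt(1.0 - ecc * ecc)  # b/a
    a = math.sqrt(area / (math.pi * ratio))
    b = a * ratio
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    ct, st = math.cos(theta), math.sin(theta)
    return Polygon(np.column_stack([cx + ct * x - st * y,
                                    cy + st * x + ct * y]))


def _sarcomatoid_chord_offset(rho: float) -> float:
    """Signed chord offset (units of core radius) cutting off a circular
    segment of area fraction ``rho``; the sarcomatoid component occupies
    the segment beyond the chord."""
    if rho <= 0:
        return 1.0 + 1e-9
    if rho >= 1:
        return -1.0 - 1e-9
    from scipy.optimize import brentq

    def frac(u: float) -> float:
        return (math.acos(u) - u * math.sqrt(1 - u * u)) / math.pi

    return brentq(lambda u: frac(u) - rho, -1.0 + 1e-12, 1.0 - 1e-12)


def _place_centroids(rng: np.random.Generator, n: int, radius: float,
                     classify, spacing_for: dict[bool, float],
                     clustered: bool,
                     max_attempts_per_cell: int = 300
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Hard-core dart throwing inside a disc of given radius.

    ``classify(point) -> bool`` decides each accepted candidate's class
    (True = sarcomatoid) and ``spacing_for`` maps class to the minimum
    centroid spacing; a candidate is accepted when it is at least
    max(own, neighbour) spacing away from every accepted point.
    """
    centre = np.array([radius, radius])
    pts: list[np.ndarray] = []
    classes: list[bool] = []
    spacings: list[float] = []
    # clustered mode seeds a few attractor points and samples around them
    attractors = None
    if clustered:
        k = max(3, n // 40)
        ang = rng.uniform(0, 2 * math.pi, k)
        rad = radius * 0.7 * np.sqrt(rng.uniform(0, 1, k))
        attractors = centre + np.column_stack([rad * np.cos(ang),
                                               rad * np.sin(ang)])
    for i in range(n):
        placed = False
        for _ in range(max_attempts_per_cell):
            if attractors is not None:
                c = attractors[rng.integers(len(attractors))]
                cand = c + rng.normal(0.0, radius * 0.18, 2)
                if np.hypot(*(cand - centre)) > radius * 0.95:
                    continue
            else:
                ang = rng.uniform(0, 2 * math.pi)
                rad = radius * 0.95 * math.sqrt(rng.uniform())
                cand = centre + [rad * math.cos(ang), rad * math.sin(ang)]
            is_sar = bool(classify(np.asarray(cand)))
            spacing = spacing_for[is_sar]
            if pts:
                d = np.hypot(*(np.asarray(pts) - cand).T)
                req = np.maximum(spacings, spacing)
                if np.any(d < req):
                    continue
            pts.append(np.asarray(cand))
            classes.append(is_sar)
            spacings.append(spacing)
            placed = True
            break
        if not placed:
            raise InfeasibleDensityError(
                f"could not place cell {i + 1}/{n} after "
                f"{max_attempts_per_cell} attempts; density infeasible")
    return np.asarray(pts), np.asarray(classes, dtype=bool)


def sample_cell_population(
    spec: CoreSpec,
    phenotypes: dict[str, CellPhenotypeSpec] | None = None,
    core_id: str = "core",
) -> pd.DataFrame:
    """Sample one core's detection table with planted per-cell classes.

    Exactly ``spec.n_cells`` cells are placed inside the core disc by a
    hard-core (minimum-spacing) process; the minimum centroid spacing is
    0.8x the class mean nucleus diameter, with sarcomatoid cells spread
    slightly further apart.  Each detection carries its centroid, a
    24-vertex nucleus ellipse polygon, a dilated cell polygon and the
    planted class.

    With the default ``regional`` arrangement the sarcomatoid component
    occupies a circular segment of the core covering a ``rho`` fraction
    of its area (biphasic tumours present regionally separated
    components, not salt-and-pepper mixtures); ``mixed`` plants classes
    independently of position.
    """
    phenotypes = phenotypes or default_phenotypes()
    epi, sar = phenotypes["epithelioid"], phenotypes["sarcomatoid"]
    if sar.eccentricity_mean <= epi.eccentricity_mean:
        raise ValueError(
            "sarcomatoid eccentricity_mean must exceed epithelioid")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    radius = spec.core_diameter / 2.0
    rho = spec.sarcomatoid_fraction

    def mean_diam(p: CellPhenotypeSpec) -> float:
        return 2.0 * math.sqrt(p.area_mean / math.pi)

    if spec.component_arrangement == "regional":
        phi = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.cos(phi), math.sin(phi)])
        offset = _sarcomatoid_chord_offset(rho) * radius
        centre = np.array([radius, radius])

        def classify(p: np.ndarray) -> bool:
            return float((p - centre) @ direction) >= offset
    else:
        def classify(p: np.ndarray) -> bool:
            return bool(rng.random() < rho)

    # hard-core spacing: 0.8 x mean nucleus diameter; the sarcomatoid
    # pattern is more dispersed (larger nearest-neighbour distances)
    spacing_for = {False: 0.8 * mean_diam(epi),
                   True: 1.1 * 0.8 * mean_diam(sar)}
    xy, is_sar = _place_centroids(
        rng, n, radius, classify, spacing_for,
        clustered=spec.spatial_dispersion == "clustered")

    rows = []
    for i in range(n):
        p = sar if is_sar[i] else epi
        area = max(5.0, rng.normal(p.area_mean, p.area_sd))
        ecc = float(np.clip(rng.normal(p.eccentricity_mean,
                                       p.eccentricity_sd), 0.0, 0.98))
        theta = rng.uniform(0.0, math.pi)
        nucleus = _ellipse_polygon(xy[i, 0], xy[i, 1], area, ecc, theta)
        cell = nucleus.buffer(p.cytoplasm_margin_um, quad_segs=4)
        rows.append({
            "core_id": core_id,
            "cell_id": i,
            "cx_um": xy[i, 0],
            "cy_um": xy[i, 1],
            "nucleus_wkt": nucleus.wkt,
            "cell_wkt": cell.wkt,
            "planted_class": p.class_name,
            "stain_h": max(0.05, rng.normal(p.stain_h_mean, p.stain_h_sd)),
            "stain_e": max(0.02, rng.normal(p.stain_e_mean, p.stain_e_sd)),
            "texture_contrast": p.texture_contrast,
        })
    return pd.DataFrame(rows)


BACKGROUND_RGB = np.array([244, 244, 244], dtype=np.uint8)


def render_core(detections: pd.DataFrame, mpp: float,
                core_diameter: float = 500.0, seed: int = 0) -> np.ndarray:
    """Render a detection table as an RGB image on a bright background.

    Cells are drawn in an H&E-like Beer-Lambert colour model: per-pixel
    stain concentrations (hematoxylin over the nucleus, eosin over the
    cytoplasm) are modulated by a seeded, spatially smoothed noise texture
    and converted to RGB transmittance through the standard H&E
    optical-density matrix, so stain deconvolution round-trips.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    from skimage.draw import polygon as draw_polygon

    size = int(math.ceil(core_diameter / mpp))
    od = np.zeros((size, size, 3), dtype=np.float64)
    bg_od = -np.log10((BACKGROUND_RGB.astype(float) + 1.0) / 256.0)
    od[:] = bg_od

    h_vec = HE_STAIN_MATRIX[0]
    e_vec = HE_STAIN_MATRIX[1]

    for row in detections.itertuples(index=False):
        cell_rng = np.random.default_rng(
            np.random.SeedSequence([seed, int(row.cell_id) & 0x7FFFFFFF]))
        for wkt_text, conc, vec in (
                (row.cell_wkt, row.stain_e, e_vec),
                (row.nucleus_wkt, row.stain_h, h_vec)):
            poly = _wkt_coords(wkt_text)
            rr, cc = draw_polygon(poly[:, 1] / mpp, poly[:, 0] / mpp,
                                  shape=(size, size))
            if rr.size == 0:
                continue
            tex = _texture_field(cell_rng, rr, cc,
                                 float(row.texture_contrast))
            od[rr, cc] += conc * tex[:, None] * vec[None, :]

    rgb = np.clip(256.0 * np.power(10.0, -od) - 1.0, 0, 255)
    return rgb.astype(np.uint8)


def _wkt_coords(wkt_text: str) -> np.ndarray:
    from shapely import wkt as shapely_wkt
    return np.asarray(shapely_wkt.loads(wkt_text).exterior.coords)


def _texture_field(rng: np.random.Generator, rr: np.ndarray, cc: np.ndarray,
                   contrast: float) -> np.ndarray:
    """Multiplicative chromatin-like texture over the masked pixels."""
    if contrast <= 0 or rr.size == 0:
        return np.ones(rr.size)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    noise = rng.normal(0.0, 1.0, (r1 - r0, c1 - c0))
    noise = gaussian_filter(noise, sigma=1.0)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    field_vals = 1.0 + contrast * noise[rr - r0, cc - c0]
    return np.clip(field_vals, 0.2, 2.0)


@dataclass
class CohortCore:
    """One simulated bag: detections, optional image, and its labels."""

    core_id: str
    slide_id: str
    patient_id: str
    subtype: str
    y_s_task: int
    y_e_task: int
    detections: pd.DataFrame
    mpp: float
    core_diameter: float
    image: np.ndarray | None = None
    spec: CoreSpec | None = None


def simulate_cohort(
    n_per_class: tuple[int, int, int],
    slide_count: int,
    seed: int = 0,
    n_cells_range: tuple[int, int] = (150, 300),
    core_diameter: float = 500.0,
    mpp: float = 1.0,
    phenotypes: dict[str, CellPhenotypeSpec] | None = None,
    render: bool = True,
    cores_per_patient: int = 2,
) -> list[CohortCore]:
    """Simulate a labelled TMA cohort of E / B / S cores.

    Cores are assigned round-robin to ``slide_count`` slides and grouped
    into patients of ``cores_per_patient`` consecutive cores within each
    slide.  Both ordinal label tasks are populated (sarcomatoid task
    E=0, B=1, S=2; epithelioid task S=0, B=1, E=2).
    """
    n_e, n_b, n_s = n_per_class
    if n_e + n_b + n_s == 0:
        raise ValueError("cohort must contain at least one core")
    if slide_count < 2:
        raise ValueError("need >= 2 slides for hold-one-slide-out")
    rng = np.random.default_rng(seed)
    subtypes = ["E"] * n_e + ["B"] * n_b + ["S"] * n_s
    rng.shuffle(subtypes)

    cores: list[CohortCore] = []
    slide_fill: dict[int, int] = {s: 0 for s in range(slide_count)}
    for idx, subtype in enumerate(subtypes):
        if subtype == "E":
            rho = rng.uniform(0.0, 0.05)
        elif subtype == "S":
            rho = rng.uniform(0.9, 1.0)
        else:
            rho = rng.uniform(0.3, 0.7)
        spec = CoreSpec(
            n_cells=int(rng.integers(n_cells_range[0], n_cells_range[1] + 1)),
            sarcomatoid_fraction=float(rho),
            bag_class=subtype,
            core_diameter=core_diameter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        core_id = f"core_{idx:03d}"
        det = sample_cell_population(spec, phenotypes, core_id=core_id)
        slide = idx % slide_count
        within = slide_fill[slide]
        slide_fill[slide] += 1
        y_s, y_e = SUBTYPE_TO_LABELS[subtype]
        image = None
        if render:
            image = render_core(det, mpp, core_diameter, seed=spec.seed)
        cores.append(CohortCore(
            core_id=core_id,
            slide_id=f"slide_{slide}",
            patient_id=f"patient_{slide}_{within // cores_per_patient:03d}",
            subtype=subtype,
            y_s_task=y_s,
            y_e_task=y_e,
            detections=det,
            mpp=mpp,
            core_diameter=core_diameter,
            image=image,
            spec=spec,
        ))
    return cores
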