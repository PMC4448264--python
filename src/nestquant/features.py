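"""Multi-level morphologic feature catalog (730 parameters per image).

The catalog has three levels:

* pixel level (400): 4 regions (whole image, nest, stroma, nuclei) x 10
  channels (R, G, B, H, S, V, L, chroma, hematoxylin OD, eosin OD) x 10
  statistics (mean, sd, min, max, median, p10, p90, skewness, kurtosis,
  entropy);
* object level (314): 4 object classes (tumor nests, epithelial nuclei,
  stromal round nuclei, stromal non-round nuclei) x 11 per-object shape
  descriptors x 7 aggregates = 308, plus 6 topological parameters (tumor-nest
  boundary fractal dimension, Delaunay area sum / edge mean / edge variance
  over epithelial centroids, the stromal cell structure parameter, and the
  epithelial nearest-neighbor mean distance);
* semantic level (16): densities and area ratios tying nuclei to tissue
  compartments (cell densities per px^2, nuclei/nest area ratio,
  nest/stroma ratio, nuclei/cytoplasm ratio, ...).

All areas and lengths are in pixel units; variances are population
variances; missing values (empty object class, zero denominator) are NaN.
The pixel-level block is computed but conventionally excluded from survival
modeling, where the interpretable object- and semantic-level parameters are
used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import Delaunay, QhullError, cKDTree
from skimage import color as skcolor
from skimage import morphology

from .cells import ClassifiedNuclei
from .nuclei import NucleusObject, measure_nuclei
from .preprocessing import color_deconvolve
from .synthetic import EPITHELIAL, STROMAL_NONROUND, STROMAL_ROUND

logger = logging.getLogger(__name__)

#: Tumor nests are measured with the same per-object descriptor set as nuclei.
TumorNest = NucleusObject

PIXEL_REGIONS = ("image", "nest", "stroma", "nuclei")
PIXEL_CHANNELS = ("R", "G", "B", "H", "S", "V", "L", "chroma", "hema_od", "eosin_od")
PIXEL_STATS = ("mean", "sd", "min", "max", "median", "p10", "p90", "skewness", "kurtosis", "entropy")

OBJECT_CLASSES = ("nest", EPITHELIAL, STROMAL_ROUND, STROMAL_NONROUND)
OBJECT_DESCRIPTORS = (
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "circularity",
    "major_axis",
    "minor_axis",
    "extent",
    "boundary_gradient",
    "feret_diameter",
    "orientation",
)
OBJECT_AGGREGATES = ("count", "sum", "mean", "variance", "min", "max", "median")

TOPOLOGICAL = (
    "tns_fractal_dimension",
    "tns_cell_delaunay_area_sum",
    "tns_cell_delaunay_edge_mean",
    "tns_cell_delaunay_edge_variance",
    "stromal_cell_structure",
    "epithelial_nn_mean_distance",
)

SEMANTIC = (
    "tns_cell_density",
    "stromal_round_cell_density",
    "stromal_nonround_cell_density",
    "stromal_cell_density",
    "tns_nuclei_area_tns_area_ratio",
    "tns_area_perimeter_ratio",
    "nest_stroma_area_ratio",
    "nest_area_fraction",
    "stroma_area_fraction",
    "nuclei_cytoplasm_ratio",
    "nuclei_area_fraction",
    "epithelial_nuclei_fraction",
    "stromal_round_nuclei_fraction",
    "stromal_nonround_nuclei_fraction",
    "mean_epithelial_count_per_nest",
    "total_nuclei_density",
)

#: Field-standard names for the catalog entries used in survival modeling.
ALIASES = {
    "tns_number": "obj__nest__area__count",
    "tns_perimeter_sum": "obj__nest__perimeter__sum",
    "tns_area_average": "obj__nest__area__mean",
    "tns_area_variance": "obj__nest__area__variance",
    "tns_cell_nuclei_area_average": "obj__epithelial__area__mean",
    "tns_cell_nuclei_area_variance": "obj__epithelial__area__variance",
    "tns_cell_nuclei_eccentricity_maximum": "obj__epithelial__eccentricity__max",
    "tns_fractal_dimension": "tns_fractal_dimension",
    "tns_cell_delaunay_area_sum": "tns_cell_delaunay_area_sum",
    "stromal_cell_structure": "stromal_cell_structure",
    "tns_cell_density": "tns_cell_density",
    "stromal_nonround_cell_density": "stromal_nonround_cell_density",
    "tns_cell_nuclei_area_tns_area_ratio": "tns_nuclei_area_tns_area_ratio",
    "tns_area_perimeter_ratio": "tns_area_perimeter_ratio",
}


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    level: str  # pixel | object | semantic
    definition: str


def build_catalog() -> list[CatalogEntry]:
    """The ordered 730-entry feature catalog (400 pixel / 314 object / 16
    semantic)."""
    entries: list[CatalogEntry] = []
    for region in PIXEL_REGIONS:
        for channel in PIXEL_CHANNELS:
            for stat in PIXEL_STATS:
                entries.append(
                    CatalogEntry(
                        f"px__{region}__{channel}__{stat}",
                        "pixel",
                        f"{stat} of channel {channel} over region {region}",
                    )
                )
    for cls in OBJECT_CLASSES:
        for desc in OBJECT_DESCRIPTORS:
            for agg in OBJECT_AGGREGATES:
                entries.append(
                    CatalogEntry(
                        f"obj__{cls}__{desc}__{agg}",
                        "object",
                        f"{agg} of per-object {desc} over class {cls}",
                    )
                )
    for name in TOPOLOGICAL:
        entries.append(CatalogEntry(name, "object", "topological parameter"))
    for name in SEMANTIC:
        entries.append(CatalogEntry(name, "semantic", "semantic ratio/density"))
    return entries


def catalog_names(level: str | None = None) -> list[str]:
    return [e.name for e in build_catalog() if level is None or e.level == level]


def catalog_manifest() -> pd.DataFrame:
    """Catalog as a DataFrame (name, level, definition)."""
    return pd.DataFrame([e.__dict__ for e in build_catalog()])


# ---------------------------------------------------------------------------
# Topological parameters
# ---------------------------------------------------------------------------


def _box_count(pixels: np.ndarray, size: int) -> int:
    """Number of size x size boxes containing at least one foreground pixel."""
    boxes = np.unique(pixels // size, axis=0)
    return len(boxes)


def fractal_dimension(
    boundary: np.ndarray, box_sizes: list[int] | None = None
) -> float:
    """Box-counting dimension of a binary pixel set.

    Least-squares slope of log N(s) against log s; the dimension is the
    negated slope, clipped into [0, 2].  Returns NaN for an empty set.
    """
    mask = np.asarray(boundary, bool)
    pixels = np.argwhere(mask)
    if len(pixels) == 0:
        return float("nan")
    if box_sizes is None:
        smax = max(2, min(mask.shape) // 4)
        box_sizes = [2**k for k in range(1, int(np.log2(smax)) + 1)]
    if len(box_sizes) < 2:
        raise ValueError("need at least 2 box sizes")
    counts = np.array([_box_count(pixels, s) for s in box_sizes], float)
    slope, _ = np.polyfit(np.log(box_sizes), np.log(counts), 1)
    return float(np.clip(-slope, 0.0, 2.0))


def nest_boundary(tissue_mask: np.ndarray) -> np.ndarray:
    """8-connected contour pixels of the nest regions."""
    m = np.asarray(tissue_mask, bool)
    return m & ~morphology.erosion(m, morphology.footprint_rectangle((3, 3)))


def delaunay_area_sum(points: np.ndarray) -> float:
    """Sum of Delaunay-triangle areas over a centroid set (px^2).

    Equals the convex-hull area of the point set; NaN for fewer than 3 or
    collinear points.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 3:
        return float("nan")
    try:
        tri = Delaunay(pts)
    except QhullError:
        return float("nan")
    a, b, c = (pts[tri.simplices[:, i]] for i in range(3))
    u, v = b - a, c - a
    areas = 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    return float(areas.sum())


def delaunay_edge_stats(points: np.ndarray) -> tuple[float, float]:
    """(mean, population variance) of unique Delaunay edge lengths (px)."""
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 3:
        return float("nan"), float("nan")
    try:
        tri = Delaunay(pts)
    except QhullError:
        return float("nan"), float("nan")
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            e = (min(simplex[i], simplex[(i + 1) % 3]), max(simplex[i], simplex[(i + 1) % 3]))
            edges.add(e)
    idx = np.array(sorted(edges))
    lengths = np.linalg.norm(pts[idx[:, 0]] - pts[idx[:, 1]], axis=1)
    return float(lengths.mean()), float(lengths.var())


def nearest_neighbor_mean_distance(points: np.ndarray) -> float:
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) < 2:
        return float("nan")
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(d[:, 1].mean())


# ---------------------------------------------------------------------------
# Object level
# ---------------------------------------------------------------------------


def tumor_nests(tissue_mask: np.ndarray, intensity: np.ndarray) -> list[TumorNest]:
    """Measure each 8-connected nest component into a TumorNest record."""
    from skimage import measure as skmeasure

    labels = skmeasure.label(np.asarray(tissue_mask, bool), connectivity=2)
    return measure_nuclei(labels, np.asarray(intensity, float))


def _descriptor(obj: NucleusObject, desc: str) -> float:
    if desc == "circularity":
        return 4 * np.pi * obj.area / obj.perimeter**2 if obj.perimeter > 0 else np.nan
    if desc == "boundary_gradient":
        return obj.mean_boundary_gradient
    return getattr(obj, desc)


def _aggregate(values: np.ndarray, agg: str) -> float:
    if agg == "count":
        return float(len(values))
    if len(values) == 0:
        return float("nan")
    return {
        "sum": np.sum,
        "mean": np.mean,
        "variance": np.var,
        "min": np.min,
        "max": np.max,
        "median": np.median,
    }[agg](values)


def object_level_features(
    nests: list[TumorNest], nuclei: ClassifiedNuclei
) -> dict[str, float]:
    """The 314 object-level parameters (308 shape aggregates + 6 topological)."""
    groups: dict[str, list[NucleusObject]] = {"nest": nests}
    for cls in (EPITHELIAL, STROMAL_ROUND, STROMAL_NONROUND):
        groups[cls] = nuclei.of_class(cls)
    out: dict[str, float] = {}
    for cls in OBJECT_CLASSES:
        objs = groups[cls]
        if not objs:
            logger.info("no objects of class %s; aggregates set to missing", cls)
        for desc in OBJECT_DESCRIPTORS:
            vals = np.array([_descriptor(o, desc) for o in objs], float)
            for agg in OBJECT_AGGREGATES:
                out[f"obj__{cls}__{desc}__{agg}"] = float(_aggregate(vals, agg))

    epi = nuclei.centroids(EPITHELIAL)
    nonround = nuclei.centroids(STROMAL_NONROUND)
    edge_mean, edge_var = delaunay_edge_stats(epi)
    sc_mean, _ = delaunay_edge_stats(nonround)
    out["tns_cell_delaunay_area_sum"] = delaunay_area_sum(epi)
    out["tns_cell_delaunay_edge_mean"] = edge_mean
    out["tns_cell_delaunay_edge_variance"] = edge_var
    out["stromal_cell_structure"] = sc_mean
    out["epithelial_nn_mean_distance"] = nearest_neighbor_mean_distance(epi)
    out["tns_fractal_dimension"] = float("nan")  # needs the tissue mask; see extract_catalog
    return out


# ---------------------------------------------------------------------------
# Semantic level
# ---------------------------------------------------------------------------


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def semantic_level_features(
    tissue_mask: np.ndarray,
    nuclei: ClassifiedNuclei,
    nests: list[TumorNest],
    nuclei_labels: np.ndarray | None = None,
) -> dict[str, float]:
    """The 16 semantic-level ratios and densities."""
    mask = np.asarray(tissue_mask, bool)
    nest_area = float(mask.sum())
    total_area = float(mask.size)
    stroma_area = total_area - nest_area
    nest_perimeter = float(sum(n.perimeter for n in nests))

    n_epi = nuclei.counts.get(EPITHELIAL, 0)
    n_round = nuclei.counts.get(STROMAL_ROUND, 0)
    n_nonround = nuclei.counts.get(STROMAL_NONROUND, 0)
    n_total = n_epi + n_round + n_nonround
    epi_area = float(sum(n.area for n in nuclei.of_class(EPITHELIAL)))
    if nuclei_labels is not None:
        nuclei_area = float((np.asarray(nuclei_labels) > 0).sum())
    else:
        nuclei_area = float(sum(n.area for n in nuclei.nuclei))

    return {
        "tns_cell_density": _safe_div(n_epi, nest_area),
        "stromal_round_cell_density": _safe_div(n_round, stroma_area),
        "stromal_nonround_cell_density": _safe_div(n_nonround, stroma_area),
        "stromal_cell_density": _safe_div(n_round + n_nonround, stroma_area),
        "tns_nuclei_area_tns_area_ratio": _safe_div(epi_area, nest_area),
        "tns_area_perimeter_ratio": _safe_div(nest_area, nest_perimeter),
        "nest_stroma_area_ratio": _safe_div(nest_area, stroma_area),
        "nest_area_fraction": nest_area / total_area,
        "stroma_area_fraction": stroma_area / total_area,
        "nuclei_cytoplasm_ratio": _safe_div(nuclei_area, total_area - nuclei_area),
        "nuclei_area_fraction": nuclei_area / total_area,
        "epithelial_nuclei_fraction": _safe_div(n_epi, n_total),
        "stromal_round_nuclei_fraction": _safe_div(n_round, n_total),
        "stromal_nonround_nuclei_fraction": _safe_div(n_nonround, n_total),
        "mean_epithelial_count_per_nest": _safe_div(n_epi, len(nests)),
        "total_nuclei_density": n_total / total_area,
    }


# ---------------------------------------------------------------------------
# Pixel level
# ---------------------------------------------------------------------------

_CHANNEL_RANGES = {
    "R": (0, 255), "G": (0, 255), "B": (0, 255),
    "H": (0, 1), "S": (0, 1), "V": (0, 1),
    "L": (0, 100), "chroma": (0, 150),
    "hema_od": (0, 3), "eosin_od": (0, 3),
}


def _channel_stack(image: np.ndarray) -> dict[str, np.ndarray]:
    img = np.asarray(image)
    hsv = skcolor.rgb2hsv(img)
    lab = skcolor.rgb2lab(img)
    stains = color_deconvolve(img)
    return {
        "R": img[..., 0].astype(float),
        "G": img[..., 1].astype(float),
        "B": img[..., 2].astype(float),
        "H": hsv[..., 0],
        "S": hsv[..., 1],
        "V": hsv[..., 2],
        "L": lab[..., 0],
        "chroma": np.hypot(lab[..., 1], lab[..., 2]),
        "hema_od": stains.hematoxylin_od,
        "eosin_od": stains.eosin_od,
    }


def _region_stats(values: np.ndarray, rng: tuple[float, float]) -> dict[str, float]:
    if values.size == 0:
        return {s: float("nan") for s in PIXEL_STATS}
    hist, _ = np.histogram(values, bins=64, range=rng)
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())
    sd = float(values.std())
    return {
        "mean": float(values.mean()),
        "sd": sd,
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
        "p10": float(np.percentile(values, 10)),
        "p90": float(np.percentile(values, 90)),
        "skewness": float(sps.skew(values)) if sd > 0 else 0.0,
        "kurtosis": float(sps.kurtosis(values)) if sd > 0 else 0.0,
        "entropy": entropy,
    }


def pixel_level_features(
    image: np.ndarray, tissue_mask: np.ndarray, nuclei_labels: np.ndarray
) -> dict[str, float]:
    """The 400 pixel-level parameters."""
    channels = _channel_stack(image)
    regions = {
        "image": np.ones(np.asarray(tissue_mask).shape, bool),
        "nest": np.asarray(tissue_mask, bool),
        "stroma": ~np.asarray(tissue_mask, bool),
        "nuclei": np.asarray(nuclei_labels) > 0,
    }
    out: dict[str, float] = {}
    for rname, rmask in regions.items():
        for cname, cvals in channels.items():
            stats = _region_stats(cvals[rmask], _CHANNEL_RANGES[cname])
            for sname, v in stats.items():
                out[f"px__{rname}__{cname}__{sname}"] = v
    return out


# ---------------------------------------------------------------------------
# Catalog assembly and patient aggregation
# ---------------------------------------------------------------------------


def extract_catalog(
    image: np.ndarray,
    tissue_mask: np.ndarray,
    nuclei_labels: np.ndarray,
    nuclei: ClassifiedNuclei,
    nests: list[TumorNest],
) -> pd.Series:
    """Assemble the full 730-value feature vector for one image.

    Returns a Series indexed by catalog name, in catalog order; missing
    values are NaN.
    """
    values: dict[str, float] = {}
    values.update(pixel_level_features(image, tissue_mask, nuclei_labels))
    values.update(object_level_features(nests, nuclei))
    values["tns_fractal_dimension"] = fractal_dimension(nest_boundary(tissue_mask))
    values.update(
        semantic_level_features(tissue_mask, nuclei, nests, nuclei_labels)
    )
    names = catalog_names()
    missing = set(names) - set(values)
    if missing:
        raise RuntimeError(f"catalog assembly incomplete: {sorted(missing)[:5]}")
    return pd.Series({n: values[n] for n in names}, name="features")


def with_aliases(features: pd.Series | pd.DataFrame):
    """Append the field-standard alias names as extra columns/entries."""
    out = features.copy()
    for alias, target in ALIASES.items():
        if alias != target:
            out[alias] = features[target]
    return out


def aggregate_patient(vectors: list[pd.Series]) -> pd.Series:
    """Per-feature mean over a patient's images, ignoring missing values."""
    if not vectors:
        raise ValueError("need at least one feature vector")
    return pd.concat(vectors, axis=1).mean(axis=1, skipna=True)
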