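"""Contour extraction, shape features, DBSCAN clustering, and singles filtering.

Contours are outer boundaries of 8-connected foreground components,
represented as closed polygons in (x, y) pixel coordinates together with a
rasterized interior mask.  Five features are computed per contour — area,
circularity ``4*pi*area/perimeter**2``, inertia (minor/major fitted-axis
ratio), circular mean hue, and area ratio (contour area over its minimum
enclosing circle's area; a compactness proxy).  Contours are clustered with
DBSCAN on z-scored features (hue embedded as a sin/cos pair so 359 and 1
degree are near neighbors); the cluster containing the user-selected
prototype is taken as the single-colony cluster and gates which contours
count directly versus go to watershed separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from scipy.stats import circmean, circstd
from shapely.geometry import MultiPoint
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateContourError, ParameterError, PipelineError
from .plate_io import PlateImage, circular_hue_distance, region_mean_hue

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "ContourFeatures",
    "ClusterModel",
    "SingleColonyStats",
    "SinglesCutoffs",
    "extract_contours",
    "contour_from_mask",
    "contour_from_polygon",
    "compute_features",
    "feature_matrix",
    "estimate_eps",
    "default_min_samples",
    "cluster_contours",
    "select_single_colony_cluster",
    "stats_from_features",
    "filter_singles",
]

MIN_COMPONENT_AREA = 4  # px^2; smaller components are discarded as dust


@dataclass
class Contour:
    """Outer boundary polygon of one foreground component plus its interior."""

    id: int
    polygon: np.ndarray  # (N, 2) float, (x, y), closed implicitly
    mask: np.ndarray = field(repr=False)  # bool crop of the interior
    offset: tuple[int, int] = (0, 0)  # (x0, y0) of the crop in the full image

    @property
    def pixel_area(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(xs.mean() + self.offset[0]), float(ys.mean() + self.offset[1])

    def contains_point(self, x: float, y: float) -> bool:
        iy = int(round(y)) - self.offset[1]
        ix = int(round(x)) - self.offset[0]
        h, w = self.mask.shape
        return 0 <= iy < h and 0 <= ix < w and bool(self.mask[iy, ix])

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        x0, y0 = self.offset
        h, w = self.mask.shape
        out[y0 : y0 + h, x0 : x0 + w] = self.mask
        return out


@dataclass
class ContourFeatures:
    """The five-feature vector evaluated per contour."""

    contour_id: int
    area: float  # px^2, polygonal (shoelace)
    perimeter: float  # px, closed polyline length
    circularity: float
    inertia: float
    mean_hue: float  # degrees [0, 360)
    area_ratio: float


def contour_from_mask(mask: np.ndarray, offset: tuple[int, int] = (0, 0), id: int = 0) -> Contour:
    """Trace the outer boundary polygon of a (cropped) component mask.

    The marching-squares staircase overestimates the perimeter of smooth
    shapes by ~7%, so the traced polygon is lightly smoothed with a
    circular moving average; polygons supplied explicitly via
    :func:`contour_from_polygon` are never smoothed.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    traces = find_contours(padded.astype(float), 0.5)
    if not traces:
        raise DegenerateContourError("mask has no boundary")
    trace = max(traces, key=len)  # outer boundary only
    # find_contours yields (row, col) in padded coords; convert to global (x, y)
    poly = np.column_stack([trace[:, 1] - 1 + offset[0], trace[:, 0] - 1 + offset[1]])
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    poly = _smooth_closed_polygon(poly, window=5)
    return Contour(id=id, polygon=poly, mask=mask, offset=offset)


def _smooth_closed_polygon(poly: np.ndarray, window: int = 5) -> np.ndarray:
    if len(poly) <= window:
        return poly
    kernel = np.ones(window) / window
    out = np.empty_like(poly)
    for c in range(2):
        wrapped = np.concatenate([poly[-(window // 2):, c], poly[:, c], poly[: window // 2, c]])
        out[:, c] = np.convolve(wrapped, kernel, mode="valid")
    return out


def contour_from_polygon(polygon: np.ndarray, id: int = 0) -> Contour:
    """Build a Contour from an explicit (x, y) polygon, rasterizing its interior."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ParameterError("polygon must be an (N, 2) array with N >= 3")
    x0 = int(np.floor(poly[:, 0].min()))
    y0 = int(np.floor(poly[:, 1].min()))
    w = int(np.ceil(poly[:, 0].max())) - x0 + 1
    h = int(np.ceil(poly[:, 1].max())) - y0 + 1
    rr, cc = draw_polygon(poly[:, 1] - y0, poly[:, 0] - x0, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return Contour(id=id, polygon=poly, mask=mask, offset=(x0, y0))


def extract_contours(mask: np.ndarray) -> list[Contour]:
    """One outer contour per 8-connected foreground component (dust removed)."""
    fg = np.asarray(mask) > 0
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    contours: list[Contour] = []
    slices = ndimage.find_objects(labels)
    cid = 0
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        if comp.sum() < MIN_COMPONENT_AREA:
            continue
        offset = (sl[1].start, sl[0].start)
        contours.append(contour_from_mask(comp, offset=offset, id=cid))
        cid += 1
    return contours


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _axis_ratio(mask: np.ndarray) -> float:
    """Minor/major axis-length ratio from interior second moments.

    1/12 per-pixel variance is added to each eigenvalue so single-row
    regions do not collapse to a zero minor axis.
    """
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    cov = np.cov(pts.T, bias=True) if len(pts) > 1 else np.zeros((2, 2))
    cov += np.eye(2) / 12.0
    ev = np.linalg.eigvalsh(cov)
    return float(np.sqrt(max(ev[0], 0.0) / ev[1])) if ev[1] > 0 else 1.0


def compute_features(contour: Contour, image: PlateImage | None = None) -> ContourFeatures:
    """Five-feature vector of one contour.

    Area and perimeter come from the boundary polygon itself (shoelace /
    polyline length), so a geometric square of side a has circularity
    exactly pi/4.  Inertia and mean hue use the rasterized interior; when no
    image is given the hue is reported as 0.
    """
    poly = contour.polygon
    if len(poly) < 5:
        raise DegenerateContourError(
            f"contour {contour.id} has {len(poly)} points; >= 5 required for shape fitting"
        )
    area = _shoelace_area(poly)
    perim = _perimeter(poly)
    if area <= 0 or perim <= 0:
        raise DegenerateContourError(f"contour {contour.id} has degenerate geometry")
    circularity = 4.0 * np.pi * area / perim**2
    inertia = _axis_ratio(contour.mask)
    if image is not None:
        interior = contour.full_mask(image.hue.shape)
        # hue of the mean interior color: robust where per-pixel hue is
        # chroma-noise-dominated (low saturation, JPEG subsampling)
        mean_hue = region_mean_hue(image.rgb, interior)
    else:
        mean_hue = 0.0
    mec = shapely.minimum_bounding_circle(MultiPoint(poly))
    mec_area = float(mec.area)
    area_ratio = min(area / mec_area, 1.0) if mec_area > 0 else 1.0
    return ContourFeatures(
        contour_id=contour.id,
        area=area,
        perimeter=perim,
        circularity=float(circularity),
        inertia=inertia,
        mean_hue=mean_hue,
        area_ratio=float(area_ratio),
    )


def feature_matrix(features: list[ContourFeatures], standardize: bool = True) -> np.ndarray:
    """Stack features for clustering; hue as sin/cos, z-scored per column.

    Columns: area, circularity, inertia, sin(hue), cos(hue), area_ratio.
    Zero-variance columns are centered but not scaled.
    """
    hue = np.array([f.mean_hue for f in features])
    X = np.column_stack(
        [
            [f.area for f in features],
            [f.circularity for f in features],
            [f.inertia for f in features],
            np.sin(np.deg2rad(hue)),
            np.cos(np.deg2rad(hue)),
            [f.area_ratio for f in features],
        ]
    ).astype(float)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X


def estimate_eps(X: np.ndarray, k: int) -> float:
    """DBSCAN eps from the knee of the sorted kth-nearest-neighbor distances.

    The knee is the point of maximum distance from the chord joining the
    ends of the sorted k-distance curve; when degenerate (flat curve) the
    90th percentile is used instead.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if n <= k:
        raise ParameterError(f"need at least k+1={k + 1} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, _ = nn.kneighbors(X)
    kd = np.sort(dists[:, k])
    span = kd[-1] - kd[0]
    if span < 1e-12 * max(kd[-1], 1.0) or n < 3:
        return float(max(np.percentile(kd, 90), 1e-9))
    # perpendicular distance of each point of the curve from the chord
    t = np.arange(n, dtype=float)
    chord = np.array([n - 1.0, kd[-1] - kd[0]])
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([t, kd - kd[0]])
    dev = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    knee = int(np.argmax(dev))
    if dev[knee] < 1e-12:
        return float(max(np.percentile(kd, 90), 1e-9))
    return float(max(kd[knee], 1e-9))


def default_min_samples(n_contours: int, cap: int = 20) -> int:
    """1/5 of the contour count, at least 2, capped to stay usable on dense plates."""
    return max(2, min(cap, n_contours // 5))


@dataclass
class ClusterModel:
    """DBSCAN result over the contour feature matrix."""

    eps: float
    min_samples: int
    labels: np.ndarray  # per-contour int, -1 = noise


def cluster_contours(X: np.ndarray, eps: float, min_samples: int) -> ClusterModel:
    """Standard DBSCAN semantics over the (standardized) feature matrix."""
    if eps <= 0:
        raise ParameterError(f"eps must be positive, got {eps}")
    if min_samples < 2:
        raise ParameterError(f"min_samples must be >= 2, got {min_samples}")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit(np.asarray(X, float)).labels_
    return ClusterModel(eps=float(eps), min_samples=int(min_samples), labels=labels)


@dataclass
class SingleColonyStats:
    """Per-feature mean/SD over the single-colony cluster of one color."""

    color_label: str
    member_ids: list[int]
    mean_area: float
    sd_area: float
    mean_circularity: float
    sd_circularity: float
    mean_inertia: float
    sd_inertia: float
    mean_hue: float  # circular mean, degrees
    sd_hue: float  # circular SD, degrees
    mean_area_ratio: float
    sd_area_ratio: float


def stats_from_features(members: list[ContourFeatures], color_label: str) -> SingleColonyStats:
    """Per-feature mean/SD (circular for hue) over a set of contours."""
    area = np.array([m.area for m in members])
    circ = np.array([m.circularity for m in members])
    inert = np.array([m.inertia for m in members])
    ar = np.array([m.area_ratio for m in members])
    hue = np.array([m.mean_hue for m in members])
    return SingleColonyStats(
        color_label=color_label,
        member_ids=[m.contour_id for m in members],
        mean_area=float(area.mean()),
        sd_area=float(area.std()),
        mean_circularity=float(circ.mean()),
        sd_circularity=float(circ.std()),
        mean_inertia=float(inert.mean()),
        sd_inertia=float(inert.std()),
        mean_hue=float(circmean(hue, high=360.0)),
        sd_hue=float(circstd(hue, high=360.0)) if len(hue) > 1 else 0.0,
        mean_area_ratio=float(ar.mean()),
        sd_area_ratio=float(ar.std()),
    )


def select_single_colony_cluster(
    model: ClusterModel,
    features: list[ContourFeatures],
    X: np.ndarray,
    prototype_contour_id: int,
    color_label: str = "",
) -> SingleColonyStats:
    """Stats of the cluster containing the prototype's contour.

    When the prototype contour was labeled noise, the cluster whose centroid
    is nearest the prototype's feature vector is used instead (warned).
    """
    labels = model.labels
    cluster_ids = sorted(set(labels) - {-1})
    if not cluster_ids:
        raise PipelineError(
            "DBSCAN produced no clusters at all; inspect the threshold-search "
            "diagnostics — the binarization may be fragmenting colonies"
        )
    idx = next(
        (i for i, f in enumerate(features) if f.contour_id == prototype_contour_id), None
    )
    if idx is None:
        raise ParameterError(
            f"prototype contour id {prototype_contour_id} is not among the clustered contours"
        )
    lab = labels[idx]
    if lab == -1:
        centroids = {cid: X[labels == cid].mean(axis=0) for cid in cluster_ids}
        lab = min(centroids, key=lambda cid: np.linalg.norm(X[idx] - centroids[cid]))
        logger.warning(
            "prototype contour %d was labeled noise; falling back to nearest "
            "cluster %d by feature-space centroid",
            prototype_contour_id,
            lab,
        )
    members = [f for f, l in zip(features, labels) if l == lab]
    return stats_from_features(members, color_label)


@dataclass(frozen=True)
class SinglesCutoffs:
    """Morphology cut-offs tightening the single-colony cluster membership."""

    area_lo: float = 0.3  # x prototype area
    area_hi: float = 3.0
    min_circularity: float = 0.6
    min_inertia: float = 0.5
    max_hue_dist: float = 30.0  # degrees, circular


def filter_singles(
    features: list[ContourFeatures],
    stats: SingleColonyStats,
    prototype,
    cutoffs: SinglesCutoffs = SinglesCutoffs(),
) -> tuple[list[int], list[int]]:
    """Split contour ids into accepted single colonies vs unresolved regions.

    A contour is an accepted single iff it belongs to the single-colony
    cluster and passes every cut-off relative to the prototype.  Everything
    else — members failing cut-offs, other clusters, and noise — is returned
    as unresolved, to be separated by watershed.
    """
    member_set = set(stats.member_ids)
    accepted: list[int] = []
    unresolved: list[int] = []
    for f in features:
        ok = (
            f.contour_id in member_set
            and cutoffs.area_lo * prototype.area <= f.area <= cutoffs.area_hi * prototype.area
            and f.circularity >= cutoffs.min_circularity
            and f.inertia >= cutoffs.min_inertia
            and circular_hue_distance(f.mean_hue, prototype.mean_hue) <= cutoffs.max_hue_dist
        )
        (accepted if ok else unresolved).append(f.contour_id)
    return accepted, unresolved


_stats_from_members = stats_from_features  # backwards-compatible alias
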