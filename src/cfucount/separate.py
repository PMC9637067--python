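"""Split unresolved regions by local-minima markers and marker-based watershed.

Colony centers are darker than their rims (convex colonies against a
backlight), so minima of the grayscale relief — maxima of the inverted
image — mark individual colonies inside a merged blob.  A maximum counts as
a marker only when its prominence (height above the highest saddle
connecting it to a higher maximum) exceeds a noise tolerance.  The relief
flooded by the watershed is the raw gray image itself, not a distance
transform, so unequally sized colonies split correctly.  Resulting segments
are pruned against the single-colony statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import watershed

from .cluster_filter import Contour, ContourFeatures, SingleColonyStats, compute_features, contour_from_mask
from .errors import ParameterError
from .plate_io import PlateImage, circular_hue_distance
from .report import ColonyDetection

__all__ = [
    "MarkerSet",
    "Segment",
    "PruneConfig",
    "detect_local_minima",
    "watershed_separate",
    "prune_segments",
    "default_noise_tolerance",
]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class MarkerSet:
    """Watershed seed points detected inside one unresolved region."""

    points: list[tuple[int, int]]  # (x, y), pairwise distinct
    noise_tolerance: float
    region_id: int = 0

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Segment:
    """One watershed basin of an unresolved region."""

    region_id: int
    label: int
    contour: Contour
    features: ContourFeatures | None = None
    unverified: bool = False  # region had no markers and was passed through unsplit


def default_noise_tolerance(background_mean_gray: float, prototype_mean_gray: float) -> float:
    """Tie marker sensitivity to the prototype's contrast against the plate."""
    return max(5.0, 0.25 * (background_mean_gray - prototype_mean_gray))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def detect_local_minima(
    gray: np.ndarray,
    region_mask: np.ndarray,
    noise_tolerance: float,
    region_id: int = 0,
) -> MarkerSet:
    """Prominence-filtered maxima of the inverted grayscale within a region.

    Pixels are processed in descending order of inverted gray value with a
    union-find, the topographic-persistence construction: a maximum's
    prominence is the height it survives above the merge level at which its
    component is absorbed by one with a higher peak.  Equal-height maxima
    connected only through lower ground both survive until absorbed by
    strictly higher terrain.  Plateau maxima are reduced to their centroid.
    """
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ParameterError("region mask is empty")
    if noise_tolerance <= 0:
        raise ParameterError(f"noise_tolerance must be positive, got {noise_tolerance}")
    inv = 255 - np.asarray(gray, dtype=np.int32)
    ys, xs = np.nonzero(region)
    vals = inv[ys, xs]
    order = np.lexsort((xs, ys, -vals))  # descending value, then row, then col
    n = len(order)
    index_of = -np.ones(region.shape, dtype=np.int64)
    index_of[ys, xs] = np.arange(n)  # pixel -> uf index (original ordering)
    uf = _UnionFind(n)
    # per-root component records
    peak_h: dict[int, int] = {}
    plateaus: dict[int, list[list[tuple[int, int]]]] = {}  # root -> alive plateaus
    active = np.zeros(n, dtype=bool)
    min_level: dict[int, int] = {}
    survivors_out: list[tuple[list[tuple[int, int]], float]] = []  # (plateau, prominence)

    h, w = region.shape
    for oi in order:
        y, x = int(ys[oi]), int(xs[oi])
        v = int(vals[oi])
        active[oi] = True
        roots = []
        for dy, dx in _NEIGHBORS8:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                j = index_of[ny, nx]
                if j >= 0 and active[j]:
                    roots.append(uf.find(j))
        roots = list(dict.fromkeys(roots))
        if not roots:
            # new component: this pixel starts a (potential) maximum plateau
            r = uf.find(oi)
            peak_h[r] = v
            plateaus[r] = [[(x, y)]]
            min_level[r] = v
            continue
        # attach pixel to the first neighboring component
        main = roots[0]
        r = uf.union(main, oi)
        if peak_h[main] == v:
            # still on that component's own peak plateau
            plateaus[main][0].append((x, y))
        min_level[main] = v
        # merge remaining components into `main`
        for other in roots[1:]:
            if other == main:
                continue
            hi_, lo_ = (main, other) if peak_h[main] >= peak_h[other] else (other, main)
            if peak_h[lo_] < peak_h[hi_]:
                # lower peak dies at this level
                for plat in plateaus[lo_]:
                    _record_death(plat, peak_h[lo_], v, noise_tolerance, survivors_out)
            else:  # equal peaks
                if peak_h[hi_] == v:
                    # same plateau, merging through equal-valued pixels
                    plateaus[hi_][0].extend(plateaus[lo_][0])
                    plateaus[lo_] = []
                else:
                    # twin maxima joined through lower ground: both stay alive
                    plateaus[hi_].extend(plateaus[lo_])
            new_root = uf.union(main, other)
            merged_peak = max(peak_h[main], peak_h[other])
            merged_plats = plateaus[hi_]
            merged_min = min(min_level[main], min_level[other], v)
            for key in (main, other):
                peak_h.pop(key, None)
                plateaus.pop(key, None)
                min_level.pop(key, None)
            peak_h[new_root] = merged_peak
            plateaus[new_root] = merged_plats
            min_level[new_root] = merged_min
            main = new_root
        min_level[main] = min(min_level[main], v)

    # remaining components: prominence relative to their own lowest level
    for r, plats in plateaus.items():
        for plat in plats:
            _record_death(plat, peak_h[r], min_level[r], noise_tolerance, survivors_out)

    points: list[tuple[int, int]] = []
    for plat, prom in survivors_out:
        if prom > noise_tolerance:
            points.append(_plateau_centroid(plat))
    points.sort(key=lambda p: (p[1], p[0]))
    return MarkerSet(points=points, noise_tolerance=float(noise_tolerance), region_id=region_id)


def _record_death(plateau, peak: int, level: int, tol: float, out: list) -> None:
    if plateau:
        out.append((plateau, float(peak - level)))


def _plateau_centroid(plateau: list[tuple[int, int]]) -> tuple[int, int]:
    arr = np.asarray(plateau)
    cx, cy = arr[:, 0].mean(), arr[:, 1].mean()
    rx, ry = int(round(cx)), int(round(cy))
    if (rx, ry) in set(map(tuple, plateau)):
        return rx, ry
    d = (arr[:, 0] - cx) ** 2 + (arr[:, 1] - cy) ** 2
    best = arr[int(np.argmin(d))]
    return int(best[0]), int(best[1])


def watershed_separate(
    region_mask: np.ndarray,
    markers: MarkerSet,
    gray: np.ndarray,
    image: PlateImage | None = None,
) -> list[Segment]:
    """Flood the gray relief from the markers, constrained to the region.

    Returns one segment per marker; with zero markers the region is returned
    unsplit and flagged unverified (it is only counted if it later passes
    pruning).  Features are attached when the full image is available.
    """
    region = np.asarray(region_mask, dtype=bool)
    segments: list[Segment] = []
    if len(markers) == 0:
        seg = _segment_from_mask(region, markers.region_id, 1, image)
        if seg is not None:
            seg.unverified = True
            segments.append(seg)
        return segments
    marker_img = np.zeros(region.shape, dtype=np.int32)
    for i, (x, y) in enumerate(markers.points, start=1):
        if not region[y, x]:
            raise ParameterError(f"marker ({x}, {y}) lies outside its source region")
        marker_img[y, x] = i
    labels = watershed(np.asarray(gray), marker_img, mask=region, connectivity=2)
    for lab in range(1, len(markers) + 1):
        seg = _segment_from_mask(labels == lab, markers.region_id, lab, image)
        if seg is not None:
            segments.append(seg)
    return segments


def _segment_from_mask(mask: np.ndarray, region_id: int, label: int, image) -> Segment | None:
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return None
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    contour = contour_from_mask(mask[y0 : y1 + 1, x0 : x1 + 1], offset=(int(x0), int(y0)))
    seg = Segment(region_id=region_id, label=label, contour=contour)
    if image is not None:
        try:
            seg.features = compute_features(contour, image)
        except Exception:
            seg.features = None
    return seg


@dataclass(frozen=True)
class PruneConfig:
    """Mean +/- m*SD acceptance bands around the single-colony statistics."""

    m: float = 3.0
    sd_floor_frac: float = 0.15  # SD floored at this fraction of the mean
    hue_floor_deg: float = 15.0  # absolute floor for the hue band (hue is
    # unstable for low-saturation colonies under chroma-subsampled JPEG)


def _within(value: float, mean: float, sd: float, cfg: PruneConfig) -> bool:
    band = cfg.m * max(sd, cfg.sd_floor_frac * abs(mean))
    return abs(value - mean) <= band


def segment_passes(features: ContourFeatures, stats: SingleColonyStats, cfg: PruneConfig) -> bool:
    """Check one segment against mean +/- m*SD for hue, circularity, inertia, area."""
    hue_band = cfg.m * max(stats.sd_hue, cfg.sd_floor_frac * stats.mean_hue, cfg.hue_floor_deg)
    return (
        circular_hue_distance(features.mean_hue, stats.mean_hue) <= hue_band
        and _within(features.circularity, stats.mean_circularity, stats.sd_circularity, cfg)
        and _within(features.inertia, stats.mean_inertia, stats.sd_inertia, cfg)
        and _within(features.area, stats.mean_area, stats.sd_area, cfg)
    )


def prune_segments(
    segments: list[Segment],
    stats: SingleColonyStats | list[SingleColonyStats],
    config: PruneConfig = PruneConfig(),
) -> list[ColonyDetection]:
    """Keep segments statistically consistent with the single-colony cluster(s).

    A segment is accepted when it passes the band test against any of the
    given per-color statistics; rejected segments are the border/rim noise.
    """
    stats_list = [stats] if isinstance(stats, SingleColonyStats) else list(stats)
    detections: list[ColonyDetection] = []
    for seg in segments:
        if seg.features is None:
            continue
        passing = [s for s in stats_list if segment_passes(seg.features, s, config)]
        if not passing:
            continue
        chosen = min(
            passing, key=lambda s: circular_hue_distance(seg.features.mean_hue, s.mean_hue)
        )
        cx, cy = seg.contour.centroid()
        detections.append(
            ColonyDetection(
                centroid=(cx, cy),
                contour=seg.contour.polygon,
                area=seg.features.area,
                mean_hue=seg.features.mean_hue,
                color_label=chosen.color_label,
                provenance="watershed",
            )
        )
    return detections
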