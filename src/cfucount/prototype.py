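"""User-seeded colony prototypes: the a priori ground truth of the pipeline.

Each user seed point is flood-filled into a colony region whose measured
attributes (mean gray, mean hue, area, shape, bounding box) parameterize
the threshold search, the clustering cut-offs, and the final pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cluster_filter import compute_features, contour_from_mask
from .errors import ParameterError, SeedBackgroundError
from .plate_io import PlateImage, PlateROI, circular_hue_mean, region_mean_hue

__all__ = ["ColonyPrototype", "flood_fill_colony", "extract_prototype", "merge_prototypes"]

#: Smallest region (px^2) accepted as a prototype; below this the shape
#: statistics are degenerate.
MIN_PROTOTYPE_AREA = 9

#: Fraction of the ROI a fill may cover before the seed is declared background.
MAX_FILL_ROI_FRACTION = 0.20

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class ColonyPrototype:
    """Measured attributes of one user-selected representative colony."""

    seed: tuple[int, int]  # (x, y)
    region_mask: np.ndarray = field(repr=False)  # full-size bool raster
    mean_gray: float = 0.0
    mean_hue: float = 0.0  # degrees
    area: float = 0.0  # px^2
    perimeter: float = 0.0
    circularity: float = 0.0
    inertia: float = 0.0
    bbox_w: int = 0
    bbox_h: int = 0
    color_label: str = ""


def flood_fill_colony(
    image: PlateImage,
    seed: tuple[int, int],
    roi: PlateROI,
    tolerance: float = 20.0,
) -> np.ndarray:
    """4-connected region reachable from the seed within a gray tolerance.

    The tolerance is fixed-range against the seed pixel's gray value (not
    floating against the running fill), and the region is clipped to the ROI.
    """
    x, y = int(round(seed[0])), int(round(seed[1]))
    if not roi.contains(x, y):
        raise ParameterError(f"seed point ({x}, {y}) lies outside the dish ROI")
    base = float(image.gray[y, x])
    within = (np.abs(image.gray.astype(np.int16) - base) <= tolerance) & roi.mask
    labels, _ = ndimage.label(within, structure=FOUR_CONNECTED)
    region = labels == labels[y, x]
    if region.sum() > MAX_FILL_ROI_FRACTION * roi.area:
        raise SeedBackgroundError(
            f"flood fill from ({x}, {y}) covered "
            f"{region.sum() / roi.area:.0%} of the dish; " + SeedBackgroundError.hint
        )
    return region


def extract_prototype(
    region_mask: np.ndarray,
    image: PlateImage,
    color_label: str = "",
    seed: tuple[int, int] | None = None,
) -> ColonyPrototype:
    """Measure every prototype attribute over a flood-filled region.

    Circularity and inertia use the same contour formulas as downstream
    contour features, so prototype and contour values are directly
    comparable.
    """
    region = np.asarray(region_mask, dtype=bool)
    npx = int(region.sum())
    if npx == 0:
        raise ParameterError("prototype region is empty")
    if npx < MIN_PROTOTYPE_AREA:
        raise ParameterError(
            f"prototype region of {npx} px^2 is below the {MIN_PROTOTYPE_AREA} px^2 minimum"
        )
    labels, n = ndimage.label(region, structure=FOUR_CONNECTED)
    if n != 1:
        raise ParameterError(f"prototype region must be connected, found {n} components")
    ys, xs = np.nonzero(region)
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    contour = contour_from_mask(region[y0 : y1 + 1, x0 : x1 + 1], offset=(int(x0), int(y0)))
    feats = compute_features(contour, image)
    if seed is None:
        seed = (int(round(xs.mean())), int(round(ys.mean())))
    return ColonyPrototype(
        seed=(int(seed[0]), int(seed[1])),
        region_mask=region,
        mean_gray=float(image.gray[region].mean()),
        mean_hue=region_mean_hue(image.rgb, region),
        area=feats.area,
        perimeter=feats.perimeter,
        circularity=feats.circularity,
        inertia=feats.inertia,
        bbox_w=int(x1 - x0 + 1),
        bbox_h=int(y1 - y0 + 1),
        color_label=color_label,
    )


def merge_prototypes(prototypes: list[ColonyPrototype]) -> ColonyPrototype:
    """Average several same-label prototypes into one governing prototype.

    Scalar attributes are averaged (hue circularly); the union of region
    masks is kept and the seed/bounding box of the largest member is
    retained so the threshold window still covers the biggest exemplar.
    """
    if not prototypes:
        raise ParameterError("no prototypes to merge")
    if len(prototypes) == 1:
        return prototypes[0]
    labels = {p.color_label for p in prototypes}
    if len(labels) != 1:
        raise ParameterError(f"cannot merge prototypes of different labels: {sorted(labels)}")
    biggest = max(prototypes, key=lambda p: p.area)
    union = np.zeros_like(prototypes[0].region_mask)
    for p in prototypes:
        union |= p.region_mask
    return ColonyPrototype(
        seed=biggest.seed,
        region_mask=union,
        mean_gray=float(np.mean([p.mean_gray for p in prototypes])),
        mean_hue=circular_hue_mean([p.mean_hue for p in prototypes]),
        area=float(np.mean([p.area for p in prototypes])),
        perimeter=float(np.mean([p.perimeter for p in prototypes])),
        circularity=float(np.mean([p.circularity for p in prototypes])),
        inertia=float(np.mean([p.inertia for p in prototypes])),
        bbox_w=biggest.bbox_w,
        bbox_h=biggest.bbox_h,
        color_label=biggest.color_label,
    )
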