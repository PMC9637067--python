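"""Synthetic plate-image generator with exact ground truth.

Renders the imaging situation the pipeline assumes: a bright circular dish
on a dark surround, colonies as near-circular blobs whose centers are
darker than their rims (single interior luminance minimum per colony), two
or more color classes, optional pairwise overlaps, colonies clipped by the
dish border, a linear illumination gradient, additive Gaussian noise, and
lossy re-encoding.  All randomness is fixed by the spec seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb

from .errors import GenerationError, ParameterError
from .plate_io import LUMA_WEIGHTS, PlateImage, make_plate_image

__all__ = [
    "ColorClass",
    "PlateSpec",
    "ColonyTruth",
    "GroundTruth",
    "generate_plate",
    "degrade",
    "main",
]


@dataclass(frozen=True)
class ColorClass:
    """Rendering parameters of one colony color class."""

    hue: float  # degrees
    saturation: float  # 0-1
    rim_luma: float  # gray level at the colony rim (pre-noise)


#: Blue colonies are saturated around 240 deg; white colonies are a faint
#: warm tint (saturation kept above JPEG chroma-quantization noise so the
#: encoded hue survives lossy re-encoding).  Both share the same luminance
#: profile so a single grayscale binarization covers both classes; they
#: separate by hue downstream.
DEFAULT_COLORS = {
    "blue": ColorClass(hue=240.0, saturation=0.45, rim_luma=150.0),
    "white": ColorClass(hue=60.0, saturation=0.12, rim_luma=150.0),
}

SURROUND_LUMA = 28.0
DISH_LUMA = 215.0
DISH_HUE, DISH_SAT = 36.0, 0.04
RIM_LUMA = 200.0  # slightly darker ring at the dish edge
RIM_WIDTH = 4.0


@dataclass
class PlateSpec:
    """Full parameterization of one synthetic plate."""

    width: int = 1000
    height: int = 1000
    dish_center: tuple[float, float] | None = None  # defaults to image center
    dish_radius: float | None = None  # defaults to 0.46 * min(width, height)
    counts: dict[str, int] = field(default_factory=lambda: {"white": 50})
    radius_mean: float = 10.0
    radius_sd: float = 1.2
    center_depth: float = 60.0  # gray levels darker at colony center than rim
    profile_exponent: float = 2.0  # luma = rim - depth * (1 - (d/r)^2) ** exponent
    overlap_pairs: int = 0
    border_count: int = 0
    illumination_amplitude: float = 0.0  # fractional linear ramp across x
    noise_sd: float = 2.0
    downscale: float = 1.0
    jpeg_quality: int = 95  # used only when downscale < 1
    min_gap: float = 4.0  # clearance between non-partner colonies
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        return self.dish_center or (self.width / 2.0, self.height / 2.0)

    def resolved_radius(self) -> float:
        return self.dish_radius or 0.46 * min(self.width, self.height)


@dataclass
class ColonyTruth:
    center: tuple[float, float]  # (x, y)
    radius: float
    label: str
    border: bool = False
    overlap_partner: int | None = None  # index into GroundTruth.colonies


@dataclass
class GroundTruth:
    colonies: list[ColonyTruth]
    dish_center: tuple[float, float] = (0.0, 0.0)
    dish_radius: float = 0.0

    def __len__(self) -> int:
        return len(self.colonies)

    def rescale(self, factor: float) -> "GroundTruth":
        return GroundTruth(
            colonies=[
                ColonyTruth(
                    center=(c.center[0] * factor, c.center[1] * factor),
                    radius=c.radius * factor,
                    label=c.label,
                    border=c.border,
                    overlap_partner=c.overlap_partner,
                )
                for c in self.colonies
            ],
            dish_center=(self.dish_center[0] * factor, self.dish_center[1] * factor),
            dish_radius=self.dish_radius * factor,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


def _unit_rgb(hue_deg: float, sat: float) -> np.ndarray:
    """RGB of the given hue/saturation at value 1, as a length-3 float array."""
    return hsv2rgb(np.array([[[hue_deg / 360.0, sat, 1.0]]], dtype=float))[0, 0]


def _tinted(luma: np.ndarray, hue_deg: float, sat: float) -> np.ndarray:
    """RGB stack whose BT.601 luma equals ``luma``, at fixed hue/saturation."""
    u = _unit_rgb(hue_deg, sat)
    y1 = float(u @ LUMA_WEIGHTS)
    return np.clip(luma[..., None] / y1 * u, 0.0, 255.0)


def _sample_positions(spec: PlateSpec, rng: np.random.Generator) -> list[ColonyTruth]:
    cx, cy = spec.resolved_center()
    R = spec.resolved_radius()
    total = sum(spec.counts.values())
    if total == 0:
        return []
    if spec.overlap_pairs * 2 + spec.border_count > total:
        raise ParameterError("overlap and border assignments exceed the total colony count")
    # quick feasibility screen: footprint of separation disks vs dish area
    foot = (2 * spec.radius_mean + spec.min_gap) ** 2 * np.sqrt(3) / 2
    if total * foot > 0.62 * np.pi * R**2:
        raise GenerationError(
            f"{total} colonies of mean radius {spec.radius_mean} cannot be packed "
            f"into a dish of radius {R:.0f}"
        )

    labels: list[str] = []
    for lab in sorted(spec.counts):
        labels.extend([lab] * spec.counts[lab])
    rng.shuffle(labels)

    placed: list[ColonyTruth] = []

    def ok(x, y, r, partner_idx=None):
        for i, c in enumerate(placed):
            if partner_idx is not None and i == partner_idx:
                continue
            if np.hypot(x - c.center[0], y - c.center[1]) < r + c.radius + spec.min_gap:
                return False
        return True

    def draw_radius():
        return float(max(3.0, rng.normal(spec.radius_mean, spec.radius_sd)))

    li = 0  # next label index

    # border colonies: centers at R - 0.6 r so each crosses the dish edge
    for _ in range(spec.border_count):
        r = draw_radius()
        for _attempt in range(400):
            theta = rng.uniform(0, 2 * np.pi)
            d = R - 0.6 * r
            x, y = cx + d * np.cos(theta), cy + d * np.sin(theta)
            if ok(x, y, r):
                placed.append(ColonyTruth((x, y), r, labels[li], border=True))
                li += 1
                break
        else:
            raise GenerationError("could not place a border colony; reduce the density")

    def interior_point(r):
        for _attempt in range(600):
            ang = rng.uniform(0, 2 * np.pi)
            rad = (R - r - spec.min_gap) * np.sqrt(rng.uniform())
            x, y = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            if ok(x, y, r):
                return x, y
        raise GenerationError("could not place an interior colony; reduce the density")

    # overlapping pairs: partner at 60-80% of the summed radii
    for _ in range(spec.overlap_pairs):
        r1, r2 = draw_radius(), draw_radius()
        for _attempt in range(600):
            x1, y1 = interior_point(r1 + r2)  # leave room for the partner
            frac = rng.uniform(0.6, 0.8)
            theta = rng.uniform(0, 2 * np.pi)
            x2 = x1 + frac * (r1 + r2) * np.cos(theta)
            y2 = y1 + frac * (r1 + r2) * np.sin(theta)
            if np.hypot(x2 - cx, y2 - cy) <= R - r2 - spec.min_gap and ok(x2, y2, r2, len(placed)):
                i1 = len(placed)
                placed.append(ColonyTruth((x1, y1), r1, labels[li], overlap_partner=i1 + 1))
                placed.append(ColonyTruth((x2, y2), r2, labels[li + 1], overlap_partner=i1))
                li += 2
                break
        else:
            raise GenerationError("could not place an overlapping pair; reduce the density")

    while li < total:
        r = draw_radius()
        x, y = interior_point(r)
        placed.append(ColonyTruth((x, y), r, labels[li]))
        li += 1
    return placed


def generate_plate(spec: PlateSpec) -> tuple[PlateImage, GroundTruth]:
    """Render a plate image and its exact ground truth, deterministically."""
    if spec.width <= 0 or spec.height <= 0 or spec.resolved_radius() <= 0:
        raise ParameterError("image dimensions and dish radius must be positive")
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.resolved_center()
    R = spec.resolved_radius()
    H, W = spec.height, spec.width

    colonies = _sample_positions(spec, rng)

    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    dish_d = np.hypot(xx - cx, yy - cy)
    dish_mask = dish_d <= R

    luma = np.full((H, W), SURROUND_LUMA)
    luma[dish_mask] = DISH_LUMA
    ring = dish_mask & (dish_d >= R - RIM_WIDTH)
    luma[ring] = RIM_LUMA
    rgb = _tinted(luma, DISH_HUE, DISH_SAT)
    rgb[~dish_mask] = SURROUND_LUMA  # neutral dark surround

    for c in colonies:
        color = DEFAULT_COLORS.get(c.label)
        if color is None:
            raise ParameterError(
                f"no color class defined for label {c.label!r}; known: {sorted(DEFAULT_COLORS)}"
            )
        x0 = max(int(c.center[0] - c.radius) - 2, 0)
        x1 = min(int(c.center[0] + c.radius) + 3, W)
        y0 = max(int(c.center[1] - c.radius) - 2, 0)
        y1 = min(int(c.center[1] + c.radius) + 3, H)
        if x0 >= x1 or y0 >= y1:
            continue
        d = np.hypot(xx[y0:y1, x0:x1] - c.center[0], yy[y0:y1, x0:x1] - c.center[1])
        u2 = np.clip(d / c.radius, 0.0, 1.0) ** 2
        col_luma = color.rim_luma - spec.center_depth * (1.0 - u2) ** spec.profile_exponent
        col_rgb = _tinted(col_luma, color.hue, color.saturation)
        alpha = np.clip(c.radius - d, 0.0, 1.0)[..., None]  # 1-px anti-aliased edge
        patch = rgb[y0:y1, x0:x1]
        blended = alpha * col_rgb + (1.0 - alpha) * patch
        # colonies only exist on the agar: clip to the dish; darker pixel wins
        # where colonies overlap so each center keeps its luminance minimum
        inside = dish_mask[y0:y1, x0:x1] & (d < c.radius)
        darker = (blended @ LUMA_WEIGHTS) < (patch @ LUMA_WEIGHTS)
        sel = inside & darker
        patch[sel] = blended[sel]

    if spec.illumination_amplitude:
        ramp = 1.0 + spec.illumination_amplitude * (xx / max(W - 1, 1) - 0.5) * 2.0
        rgb *= ramp[..., None]

    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, rgb.shape)

    image = make_plate_image(np.clip(np.rint(rgb), 0, 255).astype(np.uint8))
    truth = GroundTruth(colonies=colonies, dish_center=(cx, cy), dish_radius=R)
    if spec.downscale < 1.0:
        image = degrade(image, spec.downscale, spec.jpeg_quality)
        truth = truth.rescale(spec.downscale)
    return image, truth


def degrade(image: PlateImage, scale: float, quality: int = 95) -> PlateImage:
    """Bilinear downscale then lossy JPEG re-encode at the given quality.

    ``quality >= 100`` skips the lossy step; ``scale == 1`` with lossless
    quality is the identity.
    """
    if not 0 < scale <= 1:
        raise ParameterError(f"scale must be in (0, 1], got {scale}")
    im = Image.fromarray(image.rgb)
    if scale < 1.0:
        w = max(1, round(image.width * scale))
        h = max(1, round(image.height * scale))
        im = im.resize((w, h), Image.BILINEAR)
    if quality < 100:
        buf = io.BytesIO()
        im.save(buf, format="JPEG", quality=int(quality))
        buf.seek(0)
        im = Image.open(buf).convert("RGB")
    return make_plate_image(np.asarray(im, dtype=np.uint8), source_path=image.source_path)


def main(argv=None) -> int:
    """``cfu-synth``: render a plate from a JSON spec into an output directory."""
    import argparse
    from pathlib import Path

    parser = argparse.ArgumentParser(
        prog="cfu-synth", description="Generate an annotated synthetic plate image."
    )
    parser.add_argument("--spec", type=Path, help="JSON file of PlateSpec fields")
    parser.add_argument("--out", type=Path, required=True, help="output directory")
    parser.add_argument("--seed", type=int, default=None, help="override the spec seed")
    args = parser.parse_args(argv)

    fields = {}
    if args.spec is not None:
        with open(args.spec, encoding="utf-8") as fh:
            fields = json.load(fh)
    if args.seed is not None:
        fields["seed"] = args.seed
    if "dish_center" in fields and fields["dish_center"] is not None:
        fields["dish_center"] = tuple(fields["dish_center"])
    spec = PlateSpec(**fields)
    image, truth = generate_plate(spec)
    args.out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image.rgb).save(args.out / "plate.png")
    truth.to_json(args.out / "truth.json")
    print(f"wrote {args.out / 'plate.png'} with {len(truth)} colonies")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
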