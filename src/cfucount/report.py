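"""Color-group assignment, count summaries, overlays, and tabular reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .errors import ParameterError
from .plate_io import PlateImage, circular_hue_distance

__all__ = [
    "ColonyDetection",
    "CountReport",
    "assign_color_groups",
    "summarize",
    "render_overlay",
    "write_report",
    "read_report",
    "write_detections_csv",
]

#: Per-label stroke colors for overlays (Fig-style: white -> green, blue -> blue).
DEFAULT_PALETTE = {
    "white": (0, 200, 0),
    "blue": (40, 80, 255),
}
FALLBACK_COLORS = [(255, 128, 0), (255, 0, 255), (0, 220, 220), (255, 255, 0)]


@dataclass
class ColonyDetection:
    """One accepted colony."""

    centroid: tuple[float, float]  # (x, y) px
    contour: np.ndarray = field(repr=False)  # (N, 2) polygon, (x, y)
    area: float = 0.0  # px^2
    mean_hue: float = 0.0  # degrees
    color_label: str = ""
    provenance: str = "single"  # "single" | "watershed"


@dataclass
class CountReport:
    """Counts per color label plus the parameters that produced them."""

    per_label: dict[str, int]
    total: int
    parameters: dict = field(default_factory=dict)
    image_id: str = ""

    def to_dict(self) -> dict:
        return {
            "per_label": dict(self.per_label),
            "total": self.total,
            "parameters": self.parameters,
            "image_id": self.image_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CountReport":
        return cls(
            per_label={str(k): int(v) for k, v in d["per_label"].items()},
            total=int(d["total"]),
            parameters=d.get("parameters", {}),
            image_id=d.get("image_id", ""),
        )


def assign_color_groups(detections, prototypes, label_masks=None):
    """Attach a color label to each detection.

    When per-label binary masks are given, a detection inherits the label of
    the mask that covers most of its pixels (mask inheritance is primary
    because the per-color masks were built independently); otherwise — or
    when no mask covers it — the prototype with minimum circular hue
    distance wins.
    """
    if not prototypes:
        raise ParameterError("at least one prototype is required")
    for det in detections:
        label = None
        if label_masks:
            x, y = int(round(det.centroid[0])), int(round(det.centroid[1]))
            best_overlap = 0
            for lab, m in label_masks.items():
                h, w = m.shape
                if 0 <= y < h and 0 <= x < w and m[y, x]:
                    # centroid containment as a cheap overlap proxy
                    best_overlap += 1
                    label = lab
            if best_overlap != 1:
                label = None
        if label is None:
            label = min(
                prototypes, key=lambda p: circular_hue_distance(det.mean_hue, p.mean_hue)
            ).color_label
        det.color_label = label
    return detections


def summarize(detections, parameters: dict | None = None, image_id: str = "") -> CountReport:
    """Counts per label and total, with a parameter echo for reproducibility."""
    per_label: dict[str, int] = {}
    for det in detections:
        per_label[det.color_label] = per_label.get(det.color_label, 0) + 1
    return CountReport(
        per_label=per_label,
        total=len(detections),
        parameters=parameters or {},
        image_id=image_id,
    )


def _label_color(label: str, used: dict) -> tuple[int, int, int]:
    if label in DEFAULT_PALETTE:
        return DEFAULT_PALETTE[label]
    if label not in used:
        used[label] = FALLBACK_COLORS[len(used) % len(FALLBACK_COLORS)]
    return used[label]


def render_overlay(image: PlateImage, detections, path=None, stroke_width: int = 2) -> np.ndarray:
    """Draw each detection's enclosing circle in its label's color.

    Pure rendering: the input image and the detections are not modified.
    Writes a PNG when a path is given and returns the annotated raster.
    """
    im = Image.fromarray(image.rgb.copy())
    draw = ImageDraw.Draw(im)
    used: dict = {}
    for det in detections:
        poly = np.asarray(det.contour, dtype=float)
        cx, cy = det.centroid
        r = float(np.hypot(poly[:, 0] - cx, poly[:, 1] - cy).max()) + 2.0
        color = _label_color(det.color_label, used)
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], outline=color, width=stroke_width)
    out = np.asarray(im)
    if path is not None:
        try:
            im.save(path, format="PNG")
        except OSError as exc:
            raise OSError(f"cannot write overlay to {path}: {exc}") from exc
    return out


def write_report(report: CountReport, path, format: str = "json") -> None:
    """Write the count report as JSON (full, lossless) or CSV (summary rows)."""
    if format not in ("json", "csv"):
        raise ParameterError(f"format must be 'csv' or 'json', got {format!r}")
    try:
        if format == "json":
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(report.to_dict(), fh, indent=2)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("label,count\n")
                for lab in sorted(report.per_label):
                    fh.write(f"{lab},{report.per_label[lab]}\n")
                fh.write(f"# total,{report.total}\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> CountReport:
    """Parse a JSON report written by :func:`write_report` (round-trip)."""
    with open(path, encoding="utf-8") as fh:
        return CountReport.from_dict(json.load(fh))


def write_detections_csv(detections, path) -> None:
    """One row per detection plus a summary footer (comma, UTF-8, '.' decimal)."""
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id,x,y,area_px2,mean_hue_deg,label,provenance\n")
            for i, det in enumerate(detections):
                fh.write(
                    f"{i},{det.centroid[0]:.2f},{det.centroid[1]:.2f},"
                    f"{det.area:.2f},{det.mean_hue:.2f},{det.color_label},{det.provenance}\n"
                )
            fh.write(f"# total,{len(detections)}\n")
    except OSError as exc:
        raise OSError(f"cannot write detections to {path}: {exc}") from exc
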