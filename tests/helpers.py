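"""Shared fixture helpers: seeds from ground truth, detection matching."""

from __future__ import annotations

import numpy as np

from cfucount.cli import RunConfig


def fixture_config(**overrides) -> RunConfig:
    """Run configuration tuned for the synthetic fixtures.

    The flood tolerance must exceed the rendered center-darkening depth
    (60 gray levels) so a seed at a colony center fills the whole colony.
    """
    cfg = RunConfig(flood_tolerance=80.0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def seed_for(truth, label: str) -> tuple[int, int, str]:
    """An isolated, interior colony center of the given label, as a seed."""
    for c in truth.colonies:
        if c.label == label and not c.border and c.overlap_partner is None:
            return (int(round(c.center[0])), int(round(c.center[1])), label)
    raise AssertionError(f"no isolated interior colony with label {label!r} in the truth")


def match_detections(detections, truth):
    """Greedy centroid matching of detections to ground-truth colonies.

    Returns (per-colony list of matched detection indices, unmatched
    detection indices).  A detection matches the nearest truth colony whose
    center is within that colony's radius + 3 px.
    """
    matched = [[] for _ in truth.colonies]
    unmatched = []
    centers = np.array([c.center for c in truth.colonies])
    radii = np.array([c.radius for c in truth.colonies])
    for i, det in enumerate(detections):
        d = np.hypot(centers[:, 0] - det.centroid[0], centers[:, 1] - det.centroid[1])
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= radii[j] + 3.0:
            matched[j].append(i)
        else:
            unmatched.append(i)
    return matched, unmatched
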