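"""Independent brute-force oracles the implementation is checked against.

Each oracle is written from the operation's definition — explicit loops,
exhaustive enumeration, or direct least-squares — and shares no code with
the implementation under test.
"""

from __future__ import annotations

import numpy as np


# --- adaptive threshold ---------------------------------------------------

def gaussian_window_mean_oracle(gray: np.ndarray, s: int) -> np.ndarray:
    """Per-pixel Gaussian-weighted window mean via an explicit double loop."""
    sigma = 0.3 * ((s - 1) * 0.5 - 1) + 0.8
    half = (s - 1) / 2.0
    k1 = np.exp(-((np.arange(s) - half) ** 2) / (2 * sigma**2))
    k1 /= k1.sum()
    k2 = np.outer(k1, k1)
    h, w = gray.shape
    padded = np.pad(np.asarray(gray, dtype=np.float64), s // 2, mode="edge")
    out = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            out[y, x] = float((padded[y : y + s, x : x + s] * k2).sum())
    return out


def adaptive_binarize_oracle(gray: np.ndarray, s: int, C: float) -> np.ndarray:
    T = gaussian_window_mean_oracle(gray, s) - C
    out = np.zeros(gray.shape, dtype=np.uint8)
    out[np.asarray(gray, dtype=np.float64) < T] = 255
    return out


# --- histogram and smoothing ----------------------------------------------

def histogram_tally_oracle(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    hist = np.zeros(256, dtype=np.int64)
    h, w = gray.shape
    for y in range(h):
        for x in range(w):
            if mask[y, x] == 255:
                hist[gray[y, x]] += 1
    return hist


def savgol_oracle(signal: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Per-window least-squares polynomial fit evaluated at the center.

    Edges use scipy's 'interp' convention: the polynomial fitted to the
    first/last full window is evaluated at the edge positions.
    """
    y = np.asarray(signal, dtype=np.float64)
    n = len(y)
    half = window // 2
    out = np.empty(n)
    x = np.arange(window, dtype=np.float64)
    for i in range(half, n - half):
        coeffs = np.polyfit(x, y[i - half : i + half + 1], polyorder)
        out[i] = np.polyval(coeffs, half)
    head = np.polyfit(x, y[:window], polyorder)
    for i in range(half):
        out[i] = np.polyval(head, i)
    tail = np.polyfit(x, y[n - window :], polyorder)
    for i in range(n - half, n):
        out[i] = np.polyval(tail, i - (n - window))
    return out


def peak_range_scan_oracle(smoothed: np.ndarray) -> tuple[int, int]:
    """Direct strict-decrease scan from the global maximum.

    Bins with no mass are not part of the peak (a single nonzero bin is a
    one-bin peak), so the run additionally requires the next value > 0.
    """
    s = np.asarray(smoothed, dtype=float)
    p = int(np.argmax(s))
    hi = p
    while hi + 1 < len(s) and 0 < s[hi + 1] < s[hi]:
        hi += 1
    lo = p
    while lo - 1 >= 0 and 0 < s[lo - 1] < s[lo]:
        lo -= 1
    return lo, hi


# --- median filter --------------------------------------------------------

def median_filter_oracle(img: np.ndarray, kernel: int) -> np.ndarray:
    half = kernel // 2
    padded = np.pad(img, half, mode="edge")
    out = np.empty_like(img)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            out[y, x] = np.median(padded[y : y + kernel, x : x + kernel])
    return out


# --- DBSCAN ---------------------------------------------------------------

def dbscan_oracle(X: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Explicit density-reachability DBSCAN: BFS from core points."""
    n = len(X)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    neighbors = [np.nonzero(d[i] <= eps)[0] for i in range(n)]  # includes self
    core = np.array([len(nb) >= min_samples for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    if core[k]:
                        queue.append(k)
        cluster += 1
    return labels


def clusterings_equivalent(a: np.ndarray, b: np.ndarray) -> bool:
    """Same noise set and same partition up to label permutation.

    Border points reachable from two clusters are assigned arbitrarily by
    DBSCAN; such points are identified (non-core under either labeling
    attached to different clusters) and tolerated.
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for la, lb in zip(a, b):
        if la == -1:
            continue
        if mapping.setdefault(la, lb) != lb or back.setdefault(lb, la) != la:
            return False
    return True


# --- prominence-filtered maxima -------------------------------------------

def regional_max_plateaus(inv: np.ndarray, region: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected equal-value plateaus with no strictly higher neighbor."""
    h, w = inv.shape
    seen = np.zeros_like(region, dtype=bool)
    plateaus = []
    for y in range(h):
        for x in range(w):
            if not region[y, x] or seen[y, x]:
                continue
            v = inv[y, x]
            # flood the equal-value plateau
            stack, plat, higher = [(y, x)], [], False
            seen[y, x] = True
            while stack:
                cy, cx = stack.pop()
                plat.append((cx, cy))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = cy + dy, cx + dx
                        if 0 <= ny < h and 0 <= nx < w and region[ny, nx]:
                            if inv[ny, nx] > v:
                                higher = True
                            elif inv[ny, nx] == v and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
            if not higher:
                plateaus.append(plat)
    return plateaus


def prominence_flood_oracle(gray: np.ndarray, region: np.ndarray) -> list[tuple[list, float]]:
    """(plateau, prominence) for every regional maximum of the inverted image.

    Prominence is found by descending-threshold flooding: the highest level
    t at which the maximum's connected component of {inv >= t} contains a
    strictly higher pixel; the global maximum of a connected chunk gets its
    height above the chunk minimum.
    """
    from scipy import ndimage

    inv = 255 - np.asarray(gray, dtype=np.int64)
    region = np.asarray(region, dtype=bool)
    results = []
    eight = np.ones((3, 3), dtype=int)
    for plat in regional_max_plateaus(inv, region):
        x0, y0 = plat[0]
        h = int(inv[y0, x0])
        prom = None
        for t in sorted({int(v) for v in inv[region]}, reverse=True):
            if t > h:
                continue
            wet = region & (inv >= t)
            labels, _ = ndimage.label(wet, structure=eight)
            comp = labels == labels[y0, x0]
            if inv[comp].max() > h:
                prom = float(h - t)
                break
        if prom is None:
            prom = float(h - inv[region & _component_of(region, (y0, x0))].min())
        results.append((plat, prom))
    return results


def _component_of(region: np.ndarray, yx: tuple[int, int]) -> np.ndarray:
    from scipy import ndimage

    labels, _ = ndimage.label(region, structure=np.ones((3, 3), dtype=int))
    return labels == labels[yx]
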