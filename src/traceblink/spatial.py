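"""Spatial organisation of cell identities and cross-session ROI matching.

Whether conditioning- or extinction-responsive cells cluster anatomically
is tested by comparing, around each labeled cell, the percentage of
neighbours within a 100 µm radius (76 pixels at 1.312 µm/pixel) that
share the label, against a bootstrap null in which the same number of
labels is reassigned at random.  Cells recorded in two sessions of the
same imaging day are matched greedily after translation registration:
candidate pairs must have centroids within 50 pixels and at least 50%
pixel overlap, and closer pairs are matched first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiMap", "MatchResult", "neighbor_identity_fraction",
           "bootstrap_identity", "register_translation", "coregister",
           "discs_to_roi_map"]


@dataclass
class RoiMap:
    """Per-cell pixel sets and centroids on the imaging field."""

    centroids: np.ndarray  # (n, 2) pixel coordinates
    pixels: list[set[tuple[int, int]]]
    px_um: float = 1.312
    fov_px: int = 1024

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.pixels) != len(self.centroids):
            raise ValueError("pixel sets and centroids disagree in length")
        if any(len(p) == 0 for p in self.pixels):
            raise ValueError("every ROI needs a non-empty pixel set")

    @property
    def n_cells(self) -> int:
        return len(self.pixels)

    def shifted(self, dx: int, dy: int) -> "RoiMap":
        return RoiMap(
            centroids=self.centroids + np.array([dx, dy], dtype=float),
            pixels=[{(x + dx, y + dy) for x, y in p} for p in self.pixels],
            px_um=self.px_um, fov_px=self.fov_px)


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]
    max_centroid_dist_px: float = 50.0
    min_pixel_overlap: float = 0.5
    matched1: set[int] = field(init=False)
    matched2: set[int] = field(init=False)

    def __post_init__(self) -> None:
        self.matched1 = {a for a, _ in self.pairs}
        self.matched2 = {b for _, b in self.pairs}
        if len(self.matched1) != len(self.pairs) or \
                len(self.matched2) != len(self.pairs):
            raise ValueError("matching must be one-to-one")


def discs_to_roi_map(centroids: np.ndarray, radii: np.ndarray,
                     px_um: float = 1.312, fov_px: int = 1024) -> RoiMap:
    """Build an ROI map of rasterised discs, the shape the synthetic
    generator uses for cell bodies."""
    pixels = []
    for (cx, cy), r in zip(np.asarray(centroids, dtype=float), radii):
        rr = int(np.ceil(r))
        xs = np.arange(int(np.floor(cx)) - rr, int(np.ceil(cx)) + rr + 1)
        ys = np.arange(int(np.floor(cy)) - rr, int(np.ceil(cy)) + rr + 1)
        gx, gy = np.meshgrid(xs, ys)
        inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r ** 2
        pixels.append({(int(x), int(y)) for x, y in zip(gx[inside], gy[inside])})
    return RoiMap(centroids=np.asarray(centroids, dtype=float),
                  pixels=pixels, px_um=px_um, fov_px=fov_px)


def neighbor_identity_fraction(roi_map: RoiMap, labels: set[int],
                               radius_um: float = 100.0) -> float:
    """Mean over labeled cells of the percentage of other cells within
    ``radius_um`` that share the label; labeled cells with no neighbour
    inside the radius are skipped."""
    if not labels:
        raise ValueError("need at least one labeled cell")
    radius_px = radius_um / roi_map.px_um
    pts = roi_map.centroids
    labeled = np.array(sorted(labels), dtype=int)
    is_labeled = np.zeros(roi_map.n_cells, dtype=bool)
    is_labeled[labeled] = True
    pcts = []
    for i in labeled:
        d = np.linalg.norm(pts - pts[i], axis=1)
        neigh = np.flatnonzero((d <= radius_px) & (np.arange(len(pts)) != i))
        if len(neigh) == 0:
            continue
        pcts.append(100.0 * is_labeled[neigh].mean())
    return float(np.mean(pcts)) if pcts else float("nan")


def bootstrap_identity(roi_map: RoiMap, observed_labels: set[int],
                       n_boot: int = 1000, radius_um: float = 100.0,
                       seed: int = 0) -> tuple[float, np.ndarray, float]:
    """Two-tailed bootstrap test of spatial clustering of a cell identity.

    Each bootstrap reassigns |labels| identities uniformly at random and
    recomputes the neighbour-identity fraction.  Returns
    (observed_fraction, null_distribution, two_tailed_p) with the
    empirical p floored at 1/n_boot.
    """
    rng = np.random.default_rng(seed)
    observed = neighbor_identity_fraction(roi_map, observed_labels, radius_um)
    n_labeled = len(observed_labels)
    null = np.empty(n_boot)
    for b in range(n_boot):
        fake = set(rng.choice(roi_map.n_cells, size=n_labeled,
                              replace=False).tolist())
        null[b] = neighbor_identity_fraction(roi_map, fake, radius_um)
    finite = null[np.isfinite(null)]
    hi = np.mean(finite >= observed)
    lo = np.mean(finite <= observed)
    p = float(min(1.0, 2.0 * min(hi, lo)))
    return observed, null, max(p, 1.0 / n_boot)


def register_translation(map1: RoiMap, map2: RoiMap) -> tuple[int, int]:
    """Integer (dx, dy) aligning map2 to map1 by maximising the 2-D
    cross-correlation of the binarised ROI masks (rotation not modeled)."""
    from scipy.signal import fftconvolve

    def rasterise(m: RoiMap) -> np.ndarray:
        img = np.zeros((m.fov_px, m.fov_px))
        for pset in m.pixels:
            for x, y in pset:
                if 0 <= x < m.fov_px and 0 <= y < m.fov_px:
                    img[y, x] = 1.0
        return img

    a, b = rasterise(map1), rasterise(map2)
    corr = fftconvolve(a, b[::-1, ::-1], mode="same")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    dy = int(peak[0] - a.shape[0] // 2)
    dx = int(peak[1] - a.shape[1] // 2)
    return dx, dy


def coregister(map1: RoiMap, map2: RoiMap,
               max_centroid_dist_px: float = 50.0,
               min_pixel_overlap: float = 0.5,
               overlap_denominator: str = "smaller",
               pre_register: bool = False) -> MatchResult:
    """Greedy one-to-one ROI matching between two sessions.

    Candidate pairs must have centroids within ``max_centroid_dist_px``
    and pixel overlap of at least ``min_pixel_overlap`` relative to the
    ``overlap_denominator`` ("smaller", "first" or "second" ROI's pixel
    count).  Candidates are accepted in order of ascending centroid
    distance, skipping pairs with an already-matched member.  With
    ``pre_register`` a translation estimated from the ROI masks is
    applied to map2 first (continuous recordings need none).
    """
    if pre_register:
        dx, dy = register_translation(map1, map2)
        map2 = map2.shifted(dx, dy)
    denoms = {"smaller": lambda p1, p2: min(len(p1), len(p2)),
              "first": lambda p1, p2: len(p1),
              "second": lambda p1, p2: len(p2)}
    if overlap_denominator not in denoms:
        raise ValueError(f"overlap_denominator must be one of {sorted(denoms)}")
    denom = denoms[overlap_denominator]
    c1, c2 = map1.centroids, map2.centroids
    d = np.linalg.norm(c1[:, None, :] - c2[None, :, :], axis=2)
    cand = np.argwhere(d <= max_centroid_dist_px)
    scored = []
    for i, j in cand:
        p1, p2 = map1.pixels[i], map2.pixels[j]
        ov = len(p1 & p2) / denom(p1, p2)
        if ov >= min_pixel_overlap:
            scored.append((d[i, j], int(i), int(j)))
    scored.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    pairs = []
    for _, i, j in scored:
        if i in used1 or j in used2:
            continue
        pairs.append((i, j))
        used1.add(i)
        used2.add(j)
    return MatchResult(pairs=pairs, max_centroid_dist_px=max_centroid_dist_px,
                       min_pixel_overlap=min_pixel_overlap)
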