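"""Vessel skeletons and the relative vessel density map.

The preprocessed MAP angiogram is binarized by hysteresis thresholding and
thinned to one-pixel-wide centerlines.  Centerlines are broken into
independent vessels at junction points (skeleton pixels with three or more
8-connected skeleton neighbors); segments shorter than three pixels are
discarded as noise.  The relative vessel density at a pixel is the number of
distinct independent vessels intersecting a window centered there, divided
by the (border-clipped) window area — "relative" because the value depends
on the window size, which defaults to 2 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import apply_hysteresis_threshold
from skimage.morphology import skeletonize

from .preprocess import MapImage

__all__ = [
    "SkeletonGraph",
    "DensityMap",
    "extract_skeleton",
    "split_and_filter",
    "density_map",
    "highlight_regions",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SkeletonGraph:
    """Vessel centerlines as labeled independent segments.

    ``segment_labels`` assigns 0 to non-skeleton pixels and a positive
    segment id elsewhere (junction pixels are id 0 once split).  ``segments``
    maps each id to its (n, 2) pixel index array.
    """

    skeleton: np.ndarray
    junctions: np.ndarray
    segment_labels: np.ndarray
    segments: dict[int, np.ndarray] = field(default_factory=dict)
    pixel_size_mm: float = 0.1
    split_done: bool = False

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Number of 8-connected skeleton neighbors of each skeleton pixel."""
    counts = ndimage.convolve(skel.astype(int), _EIGHT, mode="constant") - skel.astype(int)
    return np.where(skel, counts, 0)


def extract_skeleton(
    map_image: MapImage,
    binarize_quantile: float = 0.995,
    high_fraction: float = 0.5,
    low_fraction: float = 0.2,
) -> SkeletonGraph:
    """Binarize a MAP and thin it to centerlines with junctions marked.

    Hysteresis thresholds are fractions of the ``binarize_quantile``
    intensity quantile, which makes the skeleton invariant to global
    intensity scaling.  An all-zero map yields an empty skeleton.
    """
    px = map_image.pixels
    ref = float(np.quantile(px, binarize_quantile))
    if ref <= 0:
        binary = np.zeros(px.shape, dtype=bool)
    else:
        binary = apply_hysteresis_threshold(px, low_fraction * ref, high_fraction * ref)
    skel = skeletonize(binary)
    junctions = _neighbor_counts(skel) >= 3
    labels, _ = ndimage.label(skel, structure=_EIGHT)
    return SkeletonGraph(
        skeleton=skel,
        junctions=junctions,
        segment_labels=labels,
        segments={},
        pixel_size_mm=map_image.pixel_size_mm,
        split_done=False,
    )


def split_and_filter(graph: SkeletonGraph, min_length_px: int = 3) -> SkeletonGraph:
    """Break the skeleton at junctions and drop segments under ``min_length_px``.

    Junction pixels are removed; each remaining 8-connected component is one
    independent vessel.  Segment pixel chains are stored for export and
    counting.
    """
    chains = graph.skeleton & ~graph.junctions
    labels, n = ndimage.label(chains, structure=_EIGHT)
    segments: dict[int, np.ndarray] = {}
    out_labels = np.zeros_like(labels)
    next_id = 1
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sel = labels[sl] == lab
        npix = int(sel.sum())
        if npix < min_length_px:
            continue
        ii, jj = np.nonzero(sel)
        coords = np.stack([ii + sl[0].start, jj + sl[1].start], axis=1)
        segments[next_id] = _order_chain(coords)
        out_labels[coords[:, 0], coords[:, 1]] = next_id
        next_id += 1
    return SkeletonGraph(
        skeleton=graph.skeleton,
        junctions=graph.junctions,
        segment_labels=out_labels,
        segments=segments,
        pixel_size_mm=graph.pixel_size_mm,
        split_done=True,
    )


def _order_chain(coords: np.ndarray) -> np.ndarray:
    """Order segment pixels into a traversal chain (greedy nearest neighbor).

    Thinned junction-free segments are simple chains, so a walk from an
    endpoint visits pixels in order; small deviations only affect export,
    never counting.
    """
    if len(coords) <= 2:
        return coords
    pts = {tuple(p) for p in coords}
    # endpoint: pixel with a single chain neighbor, else arbitrary start
    def nbrs(p):
        return [
            (p[0] + di, p[1] + dj)
            for di in (-1, 0, 1)
            for dj in (-1, 0, 1)
            if (di or dj) and (p[0] + di, p[1] + dj) in pts
        ]

    start = next((tuple(p) for p in coords if len(nbrs(tuple(p))) == 1),
                 tuple(coords[0]))
    order = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [q for q in nbrs(cur) if q not in visited]
        if not nxt:
            break
        # prefer 4-connected continuation for smoother chains
        nxt.sort(key=lambda q: abs(q[0] - cur[0]) + abs(q[1] - cur[1]))
        cur = nxt[0]
        visited.add(cur)
        order.append(cur)
    if len(order) < len(coords):  # fallback: append any stragglers
        order.extend(tuple(p) for p in coords if tuple(p) not in visited)
    return np.array(order)


@dataclass
class DensityMap:
    """Per-pixel relative vessel density (vessels per mm^2)."""

    density: np.ndarray
    window_mm: float
    pixel_size_mm: float


def _clipped_window_extent(n: int, w: int) -> np.ndarray:
    """Length of a centered size-``w`` window clipped to [0, n), per index."""
    left = w // 2
    right = w - 1 - left
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (hi - lo + 1).astype(float)


def density_map(graph: SkeletonGraph, window_mm: float = 2.0) -> DensityMap:
    """Count distinct vessels intersecting a sliding window at every pixel.

    A segment intersects the window centered at a pixel iff any of its
    pixels lies within the window; this is evaluated for all centers at once
    by dilating each segment's mask with the window footprint.  Windows are
    clipped at the borders and the area term uses the clipped area.
    """
    if not graph.split_done:
        raise ValueError("density_map requires a split-and-filtered skeleton")
    h = graph.pixel_size_mm
    w = int(round(window_mm / h))
    if w < 3:
        raise ValueError("density window must span at least 3 pixels")
    shape = graph.segment_labels.shape
    counts = np.zeros(shape, dtype=np.int32)
    left = w // 2
    right = w - 1 - left
    for seg_id, coords in graph.segments.items():
        # bounding box of window centers that can see this segment
        i0 = max(int(coords[:, 0].min()) - right, 0)
        i1 = min(int(coords[:, 0].max()) + left, shape[0] - 1)
        j0 = max(int(coords[:, 1].min()) - right, 0)
        j1 = min(int(coords[:, 1].max()) + left, shape[1] - 1)
        sub = np.zeros((i1 - i0 + 1, j1 - j0 + 1), dtype=bool)
        sub[coords[:, 0] - i0, coords[:, 1] - j0] = True
        hit = ndimage.maximum_filter(sub, size=w, mode="constant")
        counts[i0:i1 + 1, j0:j1 + 1] += hit
    area = np.outer(_clipped_window_extent(shape[0], w),
                    _clipped_window_extent(shape[1], w)) * h * h
    return DensityMap(counts / area, window_mm, h)


def highlight_regions(
    density: DensityMap, threshold_per_mm2: float = 2.5, min_area_mm2: float = 4.0
) -> np.ndarray:
    """Mask of contiguous high-density regions above a minimum area.

    Regions are 8-connected components of pixels whose density exceeds
    ``threshold_per_mm2``; components smaller than ``min_area_mm2`` are
    rejected as likely artifacts.
    """
    above = density.density > threshold_per_mm2
    labels, n = ndimage.label(above, structure=_EIGHT)
    if n == 0:
        return above
    px_area = density.pixel_size_mm**2
    min_px = min_area_mm2 / px_area
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = {lab for lab, a in zip(range(1, n + 1), areas) if a >= min_px}
    return np.isin(labels, list(keep)) if keep else np.zeros_like(above)
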