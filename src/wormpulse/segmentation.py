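"""Worm silhouette extraction from grayscale video frames.

Two imaging modes are supported, mirroring the two ways the stimulation
platform is used:

* **solid media** — one freely crawling worm, dark on a bright brightfield
  background.  Segmentation starts from the global Otsu threshold and
  gradually decrements it until the worm silhouette's area stabilizes in a
  plausible band, then raises a minimum-area cutoff until only the worm
  remains (``segment_worm_solid``).
* **liquid media** — a grid of agarose wells, one swimming worm per well.
  Each well is cropped (``split_wells``), a temporal-median background is
  subtracted, the result is median filtered, inverted so the worm is
  bright, and thresholded at a high percentile of the well's pixel values
  (``segment_worm_well``; default 98.75th percentile).

Both modes end by skeletonizing the silhouette and resolving a head/tail
endpoint pair, the inputs for the posture metrics.

Conventions: images are row-major with (row, col) 0-based coordinates and
a top-left origin; connected components and skeleton neighborhoods use
8-connectivity; crop windows are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.stats import skew
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

__all__ = [
    "SegmentationError",
    "NoWormFoundError",
    "AmbiguousSceneError",
    "GeometryError",
    "WellGrid",
    "WormMask",
    "SolidSettings",
    "segment_worm_solid",
    "split_wells",
    "estimate_well_background",
    "segment_worm_well",
    "skeletonize_mask",
    "skeleton_graph",
    "geodesic_length",
]


class SegmentationError(ValueError):
    """Base class for segmentation failures."""


class NoWormFoundError(SegmentationError):
    """No component ever reached a plausible worm size."""


class AmbiguousSceneError(SegmentationError):
    """Multiple components of comparable size could not be separated."""


class GeometryError(ValueError):
    """A grid or crop does not fit inside the frame."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class WellGrid:
    """Rectangular grid of equally sized wells inside a frame.

    ``origin`` is the (row, col) pixel of the grid's top-left corner;
    wells tile from there in row-major order.
    """

    origin: tuple[int, int] = (0, 0)
    well_height: int = 150
    well_width: int = 150
    n_rows: int = 1
    n_cols: int = 1

    def __post_init__(self) -> None:
        if min(self.well_height, self.well_width, self.n_rows, self.n_cols) < 1:
            raise ValueError("grid dimensions must be positive integers")
        if min(self.origin) < 0:
            raise ValueError("grid origin must be non-negative")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def well_slices(self, index: int) -> tuple[slice, slice]:
        """Half-open (row, col) slices of well ``index`` (row-major)."""
        r, c = divmod(index, self.n_cols)
        r0 = self.origin[0] + r * self.well_height
        c0 = self.origin[1] + c * self.well_width
        return slice(r0, r0 + self.well_height), slice(c0, c0 + self.well_width)


@dataclass
class WormMask:
    """A single-worm silhouette for one frame, with its skeleton."""

    mask: np.ndarray
    skeleton: np.ndarray
    endpoints: list[tuple[int, int]]
    frame_index: int = 0
    area_px: int = 0

    def __post_init__(self) -> None:
        if self.area_px == 0:
            self.area_px = int(np.count_nonzero(self.mask))

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


# ----------------------------------------------------------------------
# skeleton graph utilities
# ----------------------------------------------------------------------
_SQRT2 = float(np.sqrt(2.0))
_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def skeleton_graph(skeleton: np.ndarray):
    """Weighted pixel-adjacency graph of a binary skeleton.

    Returns ``(coords, adjacency)`` where ``coords`` is an (N, 2) array of
    skeleton pixel (row, col) positions and ``adjacency`` a sparse CSR
    matrix with weight 1 for axial and sqrt(2) for diagonal neighbor pairs.
    """
    coords = np.argwhere(skeleton)
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    rows, cols, w = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr, dc in _NBRS:
            j = index.get((int(r) + dr, int(c) + dc))
            if j is not None and j > i:
                weight = _SQRT2 if dr and dc else 1.0
                rows += [i, j]
                cols += [j, i]
                w += [weight, weight]
    adj = sparse.csr_matrix(
        (w, (rows, cols)), shape=(len(coords), len(coords))
    )
    return coords, adj


def geodesic_length(
    skeleton: np.ndarray, p0: tuple[int, int], p1: tuple[int, int]
) -> float:
    """Shortest along-skeleton path length between two skeleton pixels.

    Axial steps count 1, diagonal steps sqrt(2) (chain-code arc length).
    Raises ``ValueError`` if the pixels are not connected on the skeleton.
    """
    coords, adj = skeleton_graph(skeleton)
    lookup = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    try:
        i0, i1 = lookup[tuple(map(int, p0))], lookup[tuple(map(int, p1))]
    except KeyError as exc:
        raise ValueError(f"point {exc} is not on the skeleton") from None
    if i0 == i1:
        return 0.0
    dist = dijkstra(adj, directed=False, indices=i0, min_only=False)
    d = float(dist[i1])
    if not np.isfinite(d):
        raise ValueError("endpoints are not connected along the skeleton")
    return d


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def _endpoint_pixels(skel: np.ndarray) -> list[tuple[int, int]]:
    nb = _neighbor_counts(skel)
    pts = np.argwhere(skel & (nb == 1))
    return [tuple(map(int, p)) for p in pts]


def _walk_branch(skel: np.ndarray, start: tuple[int, int]):
    """Follow the skeleton from an endpoint to the first junction.

    Returns (pixels of the branch excluding the junction, branch length).
    """
    nb = _neighbor_counts(skel)
    path = [start]
    length = 0.0
    prev = None
    cur = start
    for _ in range(int(skel.sum()) + 1):
        nbrs = [
            ((cur[0] + dr, cur[1] + dc), _SQRT2 if dr and dc else 1.0)
            for dr, dc in _NBRS
            if 0 <= cur[0] + dr < skel.shape[0]
            and 0 <= cur[1] + dc < skel.shape[1]
            and skel[cur[0] + dr, cur[1] + dc]
            and (cur[0] + dr, cur[1] + dc) != prev
        ]
        if not nbrs:
            break  # isolated segment: whole thing is the branch
        (nxt, w) = nbrs[0] if len(nbrs) == 1 else min(nbrs, key=lambda x: x[1])
        if nb[nxt] >= 3:  # junction: stop before it
            length += w
            break
        if len(nbrs) > 1:
            break  # ambiguous local cluster; treat as junction
        path.append(nxt)
        length += w
        prev, cur = cur, nxt
    return path, length


def _prune_spurs(skel: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Iteratively remove side branches shorter than ``fraction`` of the
    skeleton's total pixel length, preserving the two longest arms."""
    skel = skel.copy()
    total = float(skel.sum())
    for _ in range(64):
        eps = _endpoint_pixels(skel)
        if len(eps) <= 2:
            break
        branches = [_walk_branch(skel, ep) for ep in eps]
        branches.sort(key=lambda b: b[1])
        path, length = branches[0]
        if length >= fraction * total or len(path) >= skel.sum() - 1:
            break
        for r, c in path:
            skel[r, c] = False
        skel = skeletonize(skel)  # re-thin around the removed stub
    return skel


def _resolve_endpoints(skel: np.ndarray) -> list[tuple[int, int]]:
    """Head/tail pair: the two endpoints at maximal geodesic separation.

    Degenerate skeletons (loops, single pixels) fall back to the pixel
    pair at maximal Euclidean separation; a one-pixel skeleton returns
    that pixel twice.
    """
    coords = np.argwhere(skel)
    if len(coords) == 0:
        raise ValueError("empty skeleton")
    if len(coords) == 1:
        p = tuple(map(int, coords[0]))
        return [p, p]
    eps = _endpoint_pixels(skel)
    if len(eps) == 2:
        return eps
    if len(eps) > 2:
        pts, adj = skeleton_graph(skel)
        lookup = {(int(r), int(c)): i for i, (r, c) in enumerate(pts)}
        idx = [lookup[e] for e in eps]
        dist = dijkstra(adj, directed=False, indices=idx)
        best, pair = -1.0, (eps[0], eps[1])
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = dist[a, idx[b]]
                if np.isfinite(d) and d > best:
                    best, pair = d, (eps[a], eps[b])
        return list(pair)
    # no degree-1 pixels: closed loop or blob remnant
    d2 = (
        (coords[:, None, 0] - coords[None, :, 0]) ** 2
        + (coords[:, None, 1] - coords[None, :, 1]) ** 2
    )
    a, b = np.unravel_index(np.argmax(d2), d2.shape)
    return [tuple(map(int, coords[a])), tuple(map(int, coords[b]))]


def skeletonize_mask(
    mask: np.ndarray, spur_fraction: float = 0.1
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Topological skeleton of a single-component mask plus endpoints.

    Side branches shorter than ``spur_fraction`` of the skeleton length
    are pruned; if more than two endpoints survive, the retained head/tail
    pair maximizes geodesic distance along the skeleton.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = skeletonize(mask)
    if not skel.any():  # tiny masks can thin away entirely
        r, c = np.argwhere(mask)[0]
        skel = np.zeros_like(mask)
        skel[r, c] = True
    skel = _prune_spurs(skel, spur_fraction)
    endpoints = _resolve_endpoints(skel)
    return skel, endpoints


# ----------------------------------------------------------------------
# solid-media (single crawling worm) segmentation
# ----------------------------------------------------------------------
@dataclass
class SolidSettings:
    """Parameters of the Otsu-decrement segmentation.

    ``otsu_step`` is the threshold decrement on [0, 1]-normalized
    intensities; the loop stops when the largest dark component's area
    lies in ``[min_worm_area, max_worm_area]`` px and has changed by less
    than ``stability_tol`` over two consecutive steps.  The minimum-area
    cutoff then grows from ``min_area_start`` in ``min_area_step``
    increments (capped at half the largest component) until one component
    remains.
    """

    otsu_step: float = 0.01
    min_worm_area: int = 200
    max_worm_area: int = 20000
    stability_tol: float = 0.05
    min_area_start: int = 10
    min_area_step: int = 10
    spur_fraction: float = 0.1


def _largest_component(bw: np.ndarray):
    """(labels, sizes, index-of-largest) with deterministic tie-breaking
    by topmost-then-leftmost centroid."""
    lbl, n = label(bw, connectivity=2, return_num=True)
    if n == 0:
        return lbl, np.array([]), 0
    sizes = np.bincount(lbl.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) == 1:
        return lbl, sizes, int(best[0])
    cents = ndimage.center_of_mass(bw, lbl, best)
    order = sorted(range(len(best)), key=lambda i: cents[i])
    return lbl, sizes, int(best[order[0]])


def segment_worm_solid(
    frame: np.ndarray,
    settings: SolidSettings | None = None,
    frame_index: int = 0,
) -> WormMask:
    """Segment one dark crawling worm from a bright-field frame.

    The frame is min-max normalized (so results are invariant to adding a
    constant), thresholded below a gradually decremented Otsu level until
    the largest dark object's area stabilizes in a plausible-worm band,
    and cleaned with an increasing minimum-area cutoff until exactly one
    component remains.
    """
    settings = settings or SolidSettings()
    f = np.asarray(frame, dtype=float)
    lo, hi = float(f.min()), float(f.max())
    if hi - lo <= 0:
        raise NoWormFoundError("frame has no contrast")
    f = (f - lo) / (hi - lo)

    t = float(threshold_otsu(f))
    history: list[int] = []
    in_band: list[float] = []
    chosen = None
    while t > 0:
        bw = f < t
        _, sizes, best = _largest_component(bw)
        area = int(sizes[best - 1]) if len(sizes) else 0
        history.append(area)
        if settings.min_worm_area <= area <= settings.max_worm_area:
            in_band.append(t)
            if len(history) >= 3 and history[-2] > 0 and history[-3] > 0:
                d1 = abs(history[-1] - history[-2]) / history[-2]
                d2 = abs(history[-2] - history[-3]) / history[-3]
                if d1 < settings.stability_tol and d2 < settings.stability_tol:
                    chosen = t
                    break
        t -= settings.otsu_step
    if chosen is None:
        if not in_band:
            raise NoWormFoundError(
                "no threshold produced a component in the plausible-worm "
                f"area band [{settings.min_worm_area}, {settings.max_worm_area}]"
            )
        chosen = in_band[-1]

    bw = f < chosen
    lbl, sizes, best = _largest_component(bw)
    largest = int(sizes[best - 1])
    min_area = settings.min_area_start
    cap = 0.5 * largest
    while True:
        keep = np.flatnonzero(sizes >= min_area) + 1
        if len(keep) <= 1 or min_area + settings.min_area_step > cap:
            break
        min_area += settings.min_area_step
    if len(keep) == 0:
        raise NoWormFoundError("minimum-area filtering removed every component")
    if len(keep) > 1:
        raise AmbiguousSceneError(
            f"{len(keep)} components of comparable size remain at the "
            "maximum area cutoff"
        )
    mask = lbl == keep[0]
    skel, endpoints = skeletonize_mask(mask, settings.spur_fraction)
    return WormMask(mask=mask, skeleton=skel, endpoints=endpoints,
                    frame_index=frame_index)


# ----------------------------------------------------------------------
# liquid-media (multi-well) segmentation
# ----------------------------------------------------------------------
def split_wells(frame: np.ndarray, grid: WellGrid) -> list[np.ndarray]:
    """Crop a frame into row-major well sub-images.

    The wells tile contiguously from ``grid.origin``; re-assembling the
    returned sub-images reproduces the cropped frame region pixel-exactly.
    """
    frame = np.asarray(frame)
    r_end = grid.origin[0] + grid.n_rows * grid.well_height
    c_end = grid.origin[1] + grid.n_cols * grid.well_width
    if r_end > frame.shape[0] or c_end > frame.shape[1]:
        raise GeometryError(
            f"grid footprint ({r_end} x {c_end}) exceeds frame "
            f"{frame.shape[0]} x {frame.shape[1]}"
        )
    return [frame[grid.well_slices(i)] for i in range(grid.n_wells)]


def estimate_well_background(well_stack) -> np.ndarray:
    """Per-pixel temporal median of a well's frames.

    A worm sweeping through a pixel in fewer than half the frames leaves
    the background value as the median, so the estimate is exact wherever
    occupancy is below 50%.
    """
    stack = np.asarray(well_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("background estimation needs at least 3 frames")
    return np.median(stack, axis=0)


def segment_worm_well(
    well_image: np.ndarray,
    background: np.ndarray,
    percentile: float = 98.75,
    invert: str = "auto",
    min_area: int = 30,
    median_size: int = 3,
    spur_fraction: float = 0.1,
    frame_index: int = 0,
) -> WormMask | None:
    """Segment the worm in one well frame; ``None`` signals an empty well.

    Pipeline: subtract the background estimate, 3x3 median filter, invert
    so the worm is the bright tail of the distribution (``invert='auto'``
    decides from the skewness sign of the residual; worms darker than
    background give negative skew), threshold at ``percentile`` of the
    processed well's pixel values, keep the largest connected component,
    skeletonize.  A largest component below ``min_area`` px is treated as
    noise, i.e. an unoccupied well.
    """
    well = np.asarray(well_image, dtype=float)
    bg = np.asarray(background, dtype=float)
    if well.shape != bg.shape:
        raise ValueError("well image and background must share dimensions")
    if not 50 < percentile < 100:
        raise ValueError("percentile must lie in (50, 100)")
    proc = ndimage.median_filter(well - bg, size=median_size)
    if invert == "auto":
        flip = skew(proc.ravel()) < 0
    elif invert in ("on", True):
        flip = True
    elif invert in ("off", False):
        flip = False
    else:
        raise ValueError(f"invert must be 'auto', 'on' or 'off', got {invert!r}")
    if flip:
        proc = -proc
    thr = np.percentile(proc, percentile, method="lower")
    bw = proc > thr
    if not bw.any():
        return None
    lbl, sizes, best = _largest_component(bw)
    if len(sizes) == 0 or sizes[best - 1] < min_area:
        return None
    mask = lbl == best
    skel, endpoints = skeletonize_mask(mask, spur_fraction)
    return WormMask(mask=mask, skeleton=skel, endpoints=endpoints,
                    frame_index=frame_index)
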