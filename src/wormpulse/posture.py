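"""Per-frame worm posture metrics and trace assembly.

Two scalar summaries of body posture are computed from each segmented
frame:

* **eccentricity** — of the ellipse with the same second central moments
  as the worm's pixel set: focal distance over major-axis length, i.e.
  ``sqrt(1 - (b/a)^2)``.  1 for a perfectly straight worm, 0 for a
  perfectly circular one; light-evoked whole-body contraction shows up as
  a transient dip.
* **HTOL** (head-to-tail over length) — the Euclidean head-to-tail
  distance divided by the along-skeleton arc length.  1 when straight,
  near 0 when coiled.  The two metrics range differently but move
  together during a contraction.

``compute_trace`` runs segmentation over a whole video and assembles a
:class:`PostureTrace` (per-well traces in liquid mode), flagging frames
where segmentation fails as invalid rather than aborting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import segmentation as seg
from .protocols import LightSchedule

__all__ = [
    "eccentricity_from_moments",
    "eccentricity",
    "straight_segment_eccentricity",
    "htol",
    "worm_length",
    "PostureTrace",
    "TraceSettings",
    "compute_trace",
]


def eccentricity_from_moments(mu20: float, mu02: float, mu11: float) -> float:
    """Eccentricity of the ellipse with the given second central moments.

    The moment matrix ``[[mu20, mu11], [mu11, mu02]]`` has eigenvalues
    proportional to the squared semi-axes (a^2, b^2); the eccentricity is
    ``sqrt(1 - b^2/a^2)`` = focal distance / major-axis length.  An ideal
    zero-width straight segment (``mu02 = mu11 = 0``) gives exactly 1.
    """
    tr = mu20 + mu02
    if tr <= 0:
        raise ValueError("degenerate (single-point) region has no ellipse")
    disc = math.sqrt((mu20 - mu02) ** 2 + 4.0 * mu11**2)
    lam_max = (tr + disc) / 2.0
    lam_min = (tr - disc) / 2.0
    ratio = max(lam_min, 0.0) / lam_max
    return math.sqrt(max(0.0, 1.0 - ratio))


def eccentricity(region: np.ndarray) -> float:
    """Moment-ellipse eccentricity of a binary region (mask or skeleton).

    Uses the discrete pixel-center model: each true pixel contributes a
    unit point mass at its integer coordinates.  By symmetry a rasterized
    disk gives exactly 0.
    """
    region = np.asarray(region, dtype=bool)
    rr, cc = np.nonzero(region)
    if len(rr) == 0:
        raise ValueError("empty region")
    r = rr - rr.mean()
    c = cc - cc.mean()
    mu20 = float(np.dot(r, r)) / len(rr)
    mu02 = float(np.dot(c, c)) / len(rr)
    mu11 = float(np.dot(r, c)) / len(rr)
    return eccentricity_from_moments(mu20, mu02, mu11)


def straight_segment_eccentricity(length: float = 1.0) -> float:
    """Eccentricity of an ideal zero-width straight segment.

    Computed from the continuous second moments of a uniform line segment
    of the given length: the moment along the segment is L^2/12, the
    transverse moment exactly 0, so the result is exactly 1.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    return eccentricity_from_moments(length**2 / 12.0, 0.0, 0.0)


def htol(skeleton: np.ndarray, endpoints) -> float:
    """Head-to-tail Euclidean distance over along-skeleton arc length.

    Diagonal skeleton steps are weighted sqrt(2).  The result is clipped
    into (0, 1]; a straight skeleton gives exactly 1.
    """
    length = worm_length(skeleton, endpoints)
    (r0, c0), (r1, c1) = endpoints[0], endpoints[1]
    chord = math.hypot(r1 - r0, c1 - c0)
    if length <= 0:
        raise ValueError("zero-length skeleton path")
    return min(1.0, max(chord / length, np.finfo(float).tiny))


def worm_length(skeleton: np.ndarray, endpoints) -> float:
    """Geodesic skeleton path length between the two endpoints, in px."""
    if endpoints is None or len(endpoints) < 2:
        raise ValueError("two resolved endpoints are required")
    p0, p1 = endpoints[0], endpoints[1]
    if tuple(p0) == tuple(p1):
        raise ValueError("endpoints coincide (degenerate skeleton)")
    return seg.geodesic_length(skeleton, p0, p1)


# ----------------------------------------------------------------------
# traces
# ----------------------------------------------------------------------
@dataclass
class PostureTrace:
    """Per-frame posture metrics over one video (or one well of one).

    Invalid frames (segmentation failure, empty well) carry NaN metric
    values with ``valid = False``; they are never interpolated.
    """

    times: np.ndarray
    eccentricity: np.ndarray
    htol: np.ndarray
    length_px: np.ndarray
    centroid_row: np.ndarray
    centroid_col: np.ndarray
    valid: np.ndarray
    light_on: np.ndarray
    frame_rate: float = 1.0
    well_index: int | None = None

    def __len__(self) -> int:
        return len(self.times)

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid)) if len(self.valid) else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.times)),
                "time_s": self.times,
                "eccentricity": self.eccentricity,
                "htol": self.htol,
                "length_px": self.length_px,
                "centroid_row": self.centroid_row,
                "centroid_col": self.centroid_col,
                "valid": self.valid.astype(int),
                "light_on": self.light_on.astype(int),
            }
        )

    def to_csv(self, destination) -> None:
        self.to_dataframe().to_csv(destination, index=False)

    @classmethod
    def from_csv(cls, source, frame_rate: float | None = None) -> "PostureTrace":
        df = pd.read_csv(source)
        times = df["time_s"].to_numpy(float)
        if frame_rate is None:
            frame_rate = (
                1.0 / float(np.median(np.diff(times))) if len(times) > 1 else 1.0
            )
        return cls(
            times=times,
            eccentricity=df["eccentricity"].to_numpy(float),
            htol=df["htol"].to_numpy(float),
            length_px=df["length_px"].to_numpy(float),
            centroid_row=df["centroid_row"].to_numpy(float),
            centroid_col=df["centroid_col"].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
            light_on=df["light_on"].to_numpy(bool),
            frame_rate=frame_rate,
        )


@dataclass
class TraceSettings:
    """Knobs of :func:`compute_trace`.

    ``eccentricity_on`` selects whether the moment ellipse is fitted to
    the filled mask (default) or to the skeleton; both track contraction
    with the same trend, but the mask is far less sensitive to
    pixel-level segmentation jitter, which matters when the contraction
    threshold sits one control SD below the mean.
    ``compute_htol=False`` skips the geodesic computation when only
    eccentricity is needed.
    """

    eccentricity_on: str = "mask"
    compute_htol: bool = True
    percentile: float = 98.75
    invert: str = "auto"
    well_min_area: int = 30
    grid: seg.WellGrid | None = None
    solid: seg.SolidSettings = field(default_factory=seg.SolidSettings)


def _measure(worm: seg.WormMask, settings: TraceSettings):
    target = worm.skeleton if settings.eccentricity_on == "skeleton" else worm.mask
    ecc = eccentricity(target)
    if settings.compute_htol and tuple(worm.endpoints[0]) != tuple(worm.endpoints[1]):
        length = worm_length(worm.skeleton, worm.endpoints)
        h = htol(worm.skeleton, worm.endpoints)
    else:
        length = h = np.nan
    r, c = worm.centroid
    return ecc, h, length, r, c


def _empty_trace(n: int, times, light, frame_rate, well_index=None) -> PostureTrace:
    nan = np.full(n, np.nan)
    return PostureTrace(
        times=times,
        eccentricity=nan.copy(),
        htol=nan.copy(),
        length_px=nan.copy(),
        centroid_row=nan.copy(),
        centroid_col=nan.copy(),
        valid=np.zeros(n, dtype=bool),
        light_on=light,
        frame_rate=frame_rate,
        well_index=well_index,
    )


def compute_trace(
    video,
    mode: str = "solid",
    schedule: LightSchedule | None = None,
    settings: TraceSettings | None = None,
):
    """Segment every frame of a video and assemble posture trace(s).

    Parameters
    ----------
    video :
        A ``VideoFrames`` (or any object with ``frames`` (T, H, W) and
        ``frame_rate``).
    mode :
        ``'solid'`` (one crawling worm per frame; returns one
        :class:`PostureTrace`) or ``'liquid'`` (well grid required in
        ``settings.grid``; returns a list of per-well traces in row-major
        well order).
    schedule :
        Optional :class:`LightSchedule`; ``light_on`` is evaluated at each
        frame's midpoint time (False everywhere if absent).
    """
    settings = settings or TraceSettings()
    frames = np.asarray(video.frames, dtype=float)
    fps = float(video.frame_rate)
    n = frames.shape[0]
    times = np.arange(n) / fps

    def light_at(t: float) -> bool:
        if schedule is None:
            return False
        tm = min(t + 0.5 / fps, schedule.total_duration)
        return schedule.light_state(tm)

    light = np.array([light_at(t) for t in times])

    if mode == "solid":
        trace = _empty_trace(n, times, light, fps)
        for i in range(n):
            try:
                worm = seg.segment_worm_solid(frames[i], settings.solid, i)
            except seg.SegmentationError:
                continue
            _fill(trace, i, worm, settings)
        return trace

    if mode != "liquid":
        raise ValueError(f"mode must be 'solid' or 'liquid', got {mode!r}")
    if settings.grid is None:
        raise ValueError("liquid mode requires settings.grid")
    grid = settings.grid
    traces = []
    for w in range(grid.n_wells):
        sl = grid.well_slices(w)
        stack = frames[:, sl[0], sl[1]]
        bg = seg.estimate_well_background(stack)
        trace = _empty_trace(n, times, light, fps, well_index=w)
        for i in range(n):
            worm = seg.segment_worm_well(
                stack[i],
                bg,
                percentile=settings.percentile,
                invert=settings.invert,
                min_area=settings.well_min_area,
                frame_index=i,
            )
            if worm is None:
                continue
            _fill(trace, i, worm, settings)
        traces.append(trace)
    return traces


def trace_from_masks(
    masks,
    frame_rate: float,
    schedule: LightSchedule | None = None,
    eccentricity_on: str = "mask",
) -> PostureTrace:
    """Posture trace straight from known (e.g. simulator ground-truth) masks.

    Skips segmentation entirely; useful for validating the posture/event
    stages in isolation, or wherever exact silhouettes are already
    available.  HTOL/length are computed only when ``eccentricity_on`` is
    ``'skeleton'`` (they need the skeleton anyway); otherwise the trace
    carries eccentricity, centroid and validity.
    """
    masks = np.asarray(masks, dtype=bool)
    n = masks.shape[0]
    times = np.arange(n) / frame_rate
    if schedule is None:
        light = np.zeros(n, dtype=bool)
    else:
        light = np.array(
            [
                schedule.light_state(
                    min(t + 0.5 / frame_rate, schedule.total_duration)
                )
                for t in times
            ]
        )
    trace = _empty_trace(n, times, light, frame_rate)
    settings = TraceSettings(
        eccentricity_on=eccentricity_on,
        compute_htol=(eccentricity_on == "skeleton"),
    )
    for i in range(n):
        if not masks[i].any():
            continue
        if settings.eccentricity_on == "skeleton" :
            skel, endpoints = seg.skeletonize_mask(masks[i])
            worm = seg.WormMask(masks[i], skel, endpoints, frame_index=i)
        else:
            worm = seg.WormMask(
                masks[i], masks[i], [(0, 0), (0, 0)], frame_index=i
            )
        _fill(trace, i, worm, settings)
    return trace


def _fill(trace: PostureTrace, i: int, worm: seg.WormMask, settings: TraceSettings):
    try:
        ecc, h, length, r, c = _measure(worm, settings)
    except ValueError:
        return
    trace.eccentricity[i] = ecc
    trace.htol[i] = h
    trace.length_px[i] = length
    trace.centroid_row[i] = r
    trace.centroid_col[i] = c
    trace.valid[i] = True
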