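"""Synthetic worm videos with ground truth.

Every downstream stage (segmentation, posture, event calling) is testable
without recorded data by simulating what the platform's camera sees: a
sinusoidally undulating worm silhouette, darker than the background, one
per frame (solid mode) or one per well on a grid (liquid mode), with
seeded imaging noise.

The worm is a fixed-arc-length midline whose tangent angle is

    theta(s) = heading + alpha * sin(2*pi*n_waves*s/L + phase) + curl*(s/L - 1/2)

so ``curl`` adds uniform curvature (total body turning in radians) on top
of the undulation; increasing curl monotonically lowers the rendered
body's moment-ellipse eccentricity, emulating contraction.  A responsive
("ATR-fed") worm answers each light onset with a curl transient: a short
latency (default 50 ms, matching the platform's observed <100 ms
response), a fast rise, and relaxation back to baseline over ~3 s, with
peak curl scaled by ``habituation_factor**stimulus_index`` to emulate
declining responses on successive stimuli.  Spontaneous bends occur as a
seeded Poisson process regardless of light, as real control animals show.

All outputs are pure functions of (parameters, seed); per-well random
substreams are derived from ``(seed, well_index)`` so adding wells never
perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import VideoFrames
from .protocols import LightSchedule
from .segmentation import WellGrid

__all__ = [
    "WormModel",
    "ContractionModel",
    "PlacementError",
    "swim_preset",
    "crawl_preset",
    "worm_midline",
    "render_frame",
    "GroundTruthEvent",
    "SimulatedVideo",
    "simulate_video",
    "PlateSimulation",
    "simulate_well_plate",
]


class PlacementError(ValueError):
    """A worm does not fit in the frame or overlaps another."""


@dataclass(frozen=True)
class WormModel:
    """Geometry and photometry of one synthetic worm.

    Lengths are in pixels; ``intensity_contrast`` is the fractional
    intensity difference of the worm body relative to the background
    (positive = darker worm, the brightfield case).
    """

    midline_length: float = 60.0
    body_width: float = 6.0
    undulation_amplitude: float = 2.5
    undulation_frequency: float = 2.0
    intensity_contrast: float = 0.35
    position: tuple[float, float] = (75.0, 75.0)
    heading: float = 0.0
    #: body waves along the midline; an integer count keeps the
    #: undulation turning-neutral, so total body turning equals ``curl``
    n_waves: float = 2.0

    def __post_init__(self) -> None:
        if self.midline_length <= 4 * self.body_width:
            raise ValueError("midline_length must exceed 4 * body_width")
        if self.intensity_contrast == 0:
            raise ValueError("intensity_contrast must be nonzero")
        if self.undulation_frequency < 0 or self.undulation_amplitude < 0:
            raise ValueError("undulation parameters must be non-negative")


@dataclass(frozen=True)
class ContractionModel:
    """Light-response kinetics of one synthetic worm."""

    responsive: bool = True
    latency: float = 0.05
    rise_time: float = 0.1
    contraction_duration: float = 3.0
    curl_gain: float = 4.0
    habituation_factor: float = 0.8
    spontaneous_bend_rate: float = 1.0  # bends per minute

    def __post_init__(self) -> None:
        if self.latency < 0:
            raise ValueError("latency must be non-negative")
        if self.contraction_duration <= 0:
            raise ValueError("contraction_duration must be positive")
        if not 0 < self.habituation_factor <= 1:
            raise ValueError("habituation_factor must lie in (0, 1]")
        if self.rise_time <= 0 or self.rise_time >= self.contraction_duration:
            raise ValueError("rise_time must lie in (0, contraction_duration)")
        if self.spontaneous_bend_rate < 0:
            raise ValueError("spontaneous_bend_rate must be non-negative")


def swim_preset(**overrides) -> WormModel:
    """Swimming in a liquid well: fast undulation.

    The undulation amplitude is kept shallow so the baseline
    moment-ellipse eccentricity sits high (near the straight-worm
    regime the mean-minus-one-SD contraction threshold was designed
    around) and rendered eccentricity decreases monotonically over the
    whole curl working range.  The body covers ~1% of a 150x150 well,
    below the 1.25% of pixels kept by the default 98.75th-percentile
    well threshold, so the silhouette segments whole.
    """
    params = dict(
        midline_length=54.0,
        body_width=5.0,
        undulation_amplitude=2.5,
        undulation_frequency=2.0,
        position=(75.0, 75.0),
    )
    params.update(overrides)
    return WormModel(**params)


def crawl_preset(**overrides) -> WormModel:
    """Crawling on agar: slower undulation, larger animal and field."""
    params = dict(
        midline_length=120.0,
        body_width=10.0,
        undulation_amplitude=5.0,
        undulation_frequency=0.5,
        position=(150.0, 150.0),
    )
    params.update(overrides)
    return WormModel(**params)


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------
def worm_midline(
    model: WormModel,
    phase: float = 0.0,
    curl: float = 0.0,
    n_points: int | None = None,
) -> np.ndarray:
    """Midline (row, col) coordinates of fixed arc length.

    The midline is integrated from the tangent-angle model, so its arc
    length equals ``model.midline_length`` for every phase and curl; the
    centroid sits at ``model.position``.
    """
    L = model.midline_length
    if n_points is None:
        n_points = max(64, int(2 * L))
    s = np.linspace(0.0, L, n_points)
    s_mid = 0.5 * (s[:-1] + s[1:])
    if model.undulation_amplitude > 0:
        alpha = 2 * math.pi * model.n_waves * model.undulation_amplitude / L
    else:
        alpha = 0.0
    theta = (
        model.heading
        + alpha * np.sin(2 * math.pi * model.n_waves * s_mid / L + phase)
        + curl * (s_mid / L - 0.5)
    )
    ds = np.diff(s)
    rows = np.concatenate([[0.0], np.cumsum(np.sin(theta) * ds)])
    cols = np.concatenate([[0.0], np.cumsum(np.cos(theta) * ds)])
    rows += model.position[0] - rows.mean()
    cols += model.position[1] - cols.mean()
    return np.column_stack([rows, cols])


def _body_radii(model: WormModel, n_points: int) -> np.ndarray:
    """Tapered tube radius along the body (elliptic taper, blunt tips)."""
    u = np.linspace(-1.0, 1.0, n_points)
    return np.maximum(0.5 * model.body_width * np.sqrt(1 - u**2), 0.75)


def _paint_body(
    mask: np.ndarray, midline: np.ndarray, radii: np.ndarray
) -> None:
    h, w = mask.shape
    for (r0, c0), rad in zip(midline, radii):
        rlo, rhi = int(math.floor(r0 - rad)), int(math.ceil(r0 + rad)) + 1
        clo, chi = int(math.floor(c0 - rad)), int(math.ceil(c0 + rad)) + 1
        if rlo < 0 or clo < 0 or rhi > h or chi > w:
            raise PlacementError("worm body extends outside the frame")
        rr = np.arange(rlo, rhi)[:, None] - r0
        cc = np.arange(clo, chi)[None, :] - c0
        mask[rlo:rhi, clo:chi] |= (rr**2 + cc**2) <= rad**2


def render_frame(
    midlines,
    models,
    image_size: tuple[int, int],
    noise_sd: float = 0.02,
    background_level: float = 0.6,
    rng=None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Draw worm bodies over a uniform background with Gaussian noise.

    Returns the noisy grayscale image (float, clipped to [0, 1]) and the
    exact noiseless boolean mask of each worm.  Overlapping worms raise
    :class:`PlacementError` (the assay isolates one worm per well/frame).
    """
    rng = np.random.default_rng(rng)
    img = np.full(image_size, float(background_level))
    masks: list[np.ndarray] = []
    occupied = np.zeros(image_size, dtype=bool)
    for midline, model in zip(midlines, models):
        mask = np.zeros(image_size, dtype=bool)
        _paint_body(mask, midline, _body_radii(model, len(midline)))
        if (mask & occupied).any():
            raise PlacementError("worms overlap")
        occupied |= mask
        img[mask] = background_level * (1.0 - model.intensity_contrast)
        masks.append(mask)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, image_size)
    return np.clip(img, 0.0, 1.0), masks


# ----------------------------------------------------------------------
# dynamics
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected light-triggered contraction."""

    stimulus_index: int
    onset_time: float  # light onset + latency
    peak_time: float
    magnitude: float  # peak curl, radians


@dataclass
class SimulatedVideo:
    """A rendered video plus everything the renderer knew."""

    video: VideoFrames
    masks: np.ndarray  # (T, H, W) bool, noiseless ground truth
    events: list[GroundTruthEvent]
    curl: np.ndarray  # per-frame total curl actually rendered
    model: WormModel
    contraction: ContractionModel
    schedule: LightSchedule | None


def _transient(tau: float, peak: float, rise: float, total: float) -> float:
    """Fast-rise / linear-relaxation curl transient."""
    if tau < 0 or tau >= total:
        return 0.0
    if tau < rise:
        return peak * tau / rise
    return peak * (1.0 - (tau - rise) / (total - rise))


def simulate_video(
    worm: WormModel,
    contraction: ContractionModel,
    schedule: LightSchedule | None,
    frame_rate: float,
    duration: float,
    seed,
    image_size: tuple[int, int] = (150, 150),
    noise_sd: float = 0.02,
    background_level: float = 0.6,
    drift_sd: float = 1.5,
    heading_sd: float = 0.08,
) -> SimulatedVideo:
    """Simulate one worm in one frame/well over ``duration`` seconds.

    The worm undulates at its preset frequency, wanders as a confined
    random walk (``drift_sd`` px/frame, ``heading_sd`` rad/frame), and —
    if responsive — answers every schedule interval onset with a curl
    transient whose peak is ``curl_gain * habituation_factor**k`` for the
    k-th stimulus.  Spontaneous bends of comparable shape occur at
    ``spontaneous_bend_rate`` per minute, light or no light.
    """
    if frame_rate < 2 * worm.undulation_frequency:
        raise ValueError(
            "frame_rate must be at least twice the undulation frequency"
        )
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * frame_rate))
    times = np.arange(n_frames) / frame_rate

    # --- stimulus-locked transients & ground truth -------------------
    events: list[GroundTruthEvent] = []
    stim: list[tuple[float, float]] = []  # (response start, peak curl)
    if contraction.responsive and schedule is not None:
        for k, t_on in enumerate(schedule.onsets):
            peak = contraction.curl_gain * contraction.habituation_factor**k
            start = t_on + contraction.latency
            stim.append((start, peak))
            events.append(
                GroundTruthEvent(
                    stimulus_index=k,
                    onset_time=start,
                    peak_time=start + contraction.rise_time,
                    magnitude=peak,
                )
            )

    # --- spontaneous bends (Poisson, light-independent) --------------
    n_bends = rng.poisson(contraction.spontaneous_bend_rate * duration / 60.0)
    bend_t = np.sort(rng.uniform(0.0, duration, n_bends))
    bend_peak = contraction.curl_gain * rng.uniform(0.6, 1.0, n_bends)
    bend_sign = rng.choice([-1.0, 1.0], n_bends)
    bend_dur = contraction.contraction_duration * rng.uniform(0.7, 1.3, n_bends)

    # --- confined random walk ----------------------------------------
    margin = 0.5 * worm.midline_length + worm.body_width + 2.0
    lo_r, hi_r = margin, image_size[0] - margin
    lo_c, hi_c = margin, image_size[1] - margin
    if lo_r > hi_r or lo_c > hi_c:
        raise PlacementError("worm is too large for the frame")
    steps = rng.normal(0.0, drift_sd, (n_frames, 2))
    pos = np.empty((n_frames, 2))
    cur = np.array(
        [
            min(max(worm.position[0], lo_r), hi_r),
            min(max(worm.position[1], lo_c), hi_c),
        ]
    )
    for i in range(n_frames):
        cur = cur + steps[i]
        cur[0] = min(max(cur[0], lo_r), hi_r)
        cur[1] = min(max(cur[1], lo_c), hi_c)
        pos[i] = cur
    headings = worm.heading + np.cumsum(rng.normal(0.0, heading_sd, n_frames))

    # --- render -------------------------------------------------------
    frames = np.empty((n_frames,) + tuple(image_size))
    masks = np.empty((n_frames,) + tuple(image_size), dtype=bool)
    curls = np.empty(n_frames)
    for i, t in enumerate(times):
        curl = 0.0
        for start, peak in stim:
            curl += _transient(
                t - start, peak, contraction.rise_time,
                contraction.contraction_duration,
            )
        for j in range(n_bends):
            curl += bend_sign[j] * _transient(
                t - bend_t[j], bend_peak[j], contraction.rise_time, bend_dur[j]
            )
        curls[i] = curl
        frame_model = replace(
            worm, position=(pos[i, 0], pos[i, 1]), heading=float(headings[i])
        )
        midline = worm_midline(
            frame_model, phase=2 * math.pi * worm.undulation_frequency * t,
            curl=curl,
        )
        frames[i], (masks[i],) = render_frame(
            [midline], [frame_model], image_size,
            noise_sd=noise_sd, background_level=background_level, rng=rng,
        )
    return SimulatedVideo(
        video=VideoFrames(frames=frames, frame_rate=frame_rate),
        masks=masks,
        events=events,
        curl=curls,
        model=worm,
        contraction=contraction,
        schedule=schedule,
    )


@dataclass
class PlateSimulation:
    """A multi-well composite video plus per-well ground truth."""

    video: VideoFrames
    grid: WellGrid
    wells: dict[int, SimulatedVideo]  # occupied wells only
    occupancy: np.ndarray  # (n_wells,) bool


def simulate_well_plate(
    n_rows: int,
    n_cols: int,
    per_well_models: dict,
    schedule: LightSchedule | None,
    frame_rate: float,
    duration: float,
    seed: int,
    well_size: tuple[int, int] = (150, 150),
    noise_sd: float = 0.02,
    background_level: float = 0.6,
) -> PlateSimulation:
    """Composite independent per-well simulations onto a well grid.

    ``per_well_models`` maps row-major well index to a
    ``(WormModel, ContractionModel)`` pair; unmapped wells stay empty
    (background + noise).  Each well draws from its own random substream
    seeded by ``(seed, well_index)``, so outputs are bit-reproducible and
    independent of which other wells are occupied.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must contain at least one well")
    grid = WellGrid(
        origin=(0, 0), well_height=well_size[0], well_width=well_size[1],
        n_rows=n_rows, n_cols=n_cols,
    )
    for idx in per_well_models:
        if not 0 <= idx < grid.n_wells:
            raise ValueError(f"well index {idx} outside the {n_rows}x{n_cols} grid")
    height = n_rows * well_size[0]
    width = n_cols * well_size[1]
    n_frames = int(round(duration * frame_rate))
    frames = np.empty((n_frames, height, width))
    wells: dict[int, SimulatedVideo] = {}
    occupancy = np.zeros(grid.n_wells, dtype=bool)
    for w in range(grid.n_wells):
        sub_seed = np.random.SeedSequence([int(seed), w])
        sl = grid.well_slices(w)
        if w in per_well_models:
            model, cmodel = per_well_models[w]
            sim = simulate_video(
                model, cmodel, schedule, frame_rate, duration, sub_seed,
                image_size=well_size, noise_sd=noise_sd,
                background_level=background_level,
            )
            frames[:, sl[0], sl[1]] = sim.video.frames
            wells[w] = sim
            occupancy[w] = True
        else:
            rng = np.random.default_rng(sub_seed)
            noise = rng.normal(0.0, noise_sd, (n_frames,) + tuple(well_size))
            frames[:, sl[0], sl[1]] = np.clip(background_level + noise, 0, 1)
    return PlateSimulation(
        video=VideoFrames(frames=frames, frame_rate=frame_rate),
        grid=grid,
        wells=wells,
        occupancy=occupancy,
    )
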