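"""Contraction-event calling from eccentricity traces.

A contraction is a trough in the eccentricity trace that falls more than
one standard deviation below the mean eccentricity of unstimulated
control animals (for the control statistics reported for crawling
animals, mean 0.978 and SD 0.022, that threshold is 0.956).  The
threshold is always derived from control data (or supplied explicitly),
never hard-coded.

Events are maximal runs of sub-threshold valid frames; nearby runs are
merged so that brief segmentation dropouts or single-frame recoveries do
not split one physical contraction.  Events can then be attributed to
light stimuli (the platform shows <100 ms latency between light onset and
contraction, with relaxation back to neutral posture over ~3 s), and the
per-stimulus magnitude sequence quantifies habituation — the decline of
contraction strength over successive stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .posture import PostureTrace
from .protocols import LightSchedule

__all__ = [
    "BaselineStats",
    "ContractionEvent",
    "InsufficientDataError",
    "baseline_stats",
    "call_contractions",
    "attribute_to_stimuli",
    "HabituationResult",
    "habituation_metrics",
    "chance_attribution_rate",
    "overlay_silhouettes",
]


class InsufficientDataError(ValueError):
    """Not enough events/frames for the requested statistic."""


@dataclass(frozen=True)
class BaselineStats:
    """Control eccentricity statistics and the derived event threshold."""

    mean_ecc: float
    sd_ecc: float
    n_worms: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= self.mean_ecc <= 1:
            raise ValueError(
                f"invalid baseline: mean={self.mean_ecc}, sd={self.sd_ecc}"
            )
        if self.n_worms < 1:
            raise ValueError("n_worms must be >= 1")

    @property
    def threshold(self) -> float:
        """Contraction threshold: one SD below the control mean."""
        return self.mean_ecc - self.sd_ecc


def baseline_stats(control_traces, ddof: int = 1) -> BaselineStats:
    """Pool valid eccentricity samples across control traces.

    The threshold is ``mean - 1*SD`` of the pooled samples; SD uses the
    sample convention (``ddof=1``) by default, appropriate for the small
    control cohorts these assays use.
    """
    traces = list(control_traces)
    pooled = [t.eccentricity[t.valid] for t in traces]
    samples = np.concatenate(pooled) if pooled else np.array([])
    if samples.size == 0:
        raise InsufficientDataError("control traces contain no valid frames")
    sd = float(samples.std(ddof=ddof)) if samples.size > ddof else 0.0
    return BaselineStats(
        mean_ecc=float(samples.mean()), sd_ecc=sd, n_worms=len(traces)
    )


@dataclass(frozen=True)
class ContractionEvent:
    """One called contraction: a sub-threshold eccentricity trough."""

    onset_time: float
    trough_time: float
    trough_ecc: float
    magnitude: float
    duration: float
    stimulus_index: int | None = None
    latency: float | None = None


def call_contractions(
    trace: PostureTrace,
    baseline: BaselineStats,
    merge_window: float = 1.0,
) -> list[ContractionEvent]:
    """Call contraction events from an eccentricity trace.

    Maximal runs of valid frames with eccentricity below the baseline
    threshold become events.  Two runs separated by less than
    ``merge_window`` seconds (whether the gap holds supra-threshold or
    invalid frames) are merged into one event.  The trough is the run's
    minimum eccentricity (earliest frame on ties); magnitude is the drop
    from the control mean to the trough.
    """
    if not np.any(trace.valid):
        return []
    below = trace.valid & (trace.eccentricity < baseline.threshold)
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return []
    period = 1.0 / trace.frame_rate
    # group sub-threshold frames: a new run starts when the time gap
    # between consecutive sub-threshold frames reaches merge_window
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        gap = (int(i) - runs[-1][-1] - 1) * period
        if (int(i) - runs[-1][-1]) == 1 or gap < merge_window:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    events = []
    for run in runs:
        frames = np.array(run)
        eccs = trace.eccentricity[frames]
        trough_pos = int(frames[np.argmin(eccs)])  # argmin -> earliest tie
        events.append(
            ContractionEvent(
                onset_time=float(trace.times[frames[0]]),
                trough_time=float(trace.times[trough_pos]),
                trough_ecc=float(trace.eccentricity[trough_pos]),
                magnitude=float(baseline.mean_ecc - trace.eccentricity[trough_pos]),
                duration=(frames[-1] - frames[0] + 1) * period,
            )
        )
    return events


def attribute_to_stimuli(
    events,
    schedule: LightSchedule,
    max_latency: float = 0.1,
    response_window: float = 3.0,
) -> list[ContractionEvent]:
    """Attach each event to at most one light stimulus.

    An event qualifies for stimulus ``k`` (the k-th schedule interval,
    onset ``t_on``) if its onset lies in ``[t_on, t_on + max_latency]`` or
    its trough lies in ``[t_on, t_on + response_window]``.  The earliest
    eligible stimulus wins; latency is the onset delay after the light
    (clipped at 0 for troughs that qualify with an onset one frame early).
    """
    if max_latency < 0 or response_window < 0:
        raise ValueError("attribution windows must be non-negative")
    onsets = schedule.onsets
    out = []
    for ev in events:
        attributed = None
        for k, t_on in enumerate(onsets):
            if (t_on <= ev.onset_time <= t_on + max_latency) or (
                t_on <= ev.trough_time <= t_on + response_window
            ):
                attributed = k
                break
        if attributed is None:
            out.append(replace(ev, stimulus_index=None, latency=None))
        else:
            out.append(
                replace(
                    ev,
                    stimulus_index=attributed,
                    latency=max(0.0, ev.onset_time - onsets[attributed]),
                )
            )
    return out


@dataclass(frozen=True)
class HabituationResult:
    """Per-stimulus contraction magnitudes and their linear trend."""

    stimulus_indices: tuple[int, ...]
    magnitudes: tuple[float, ...]
    slope: float  # magnitude change per stimulus; negative = habituation


def habituation_metrics(attributed_events) -> HabituationResult:
    """Least-squares slope of contraction magnitude vs stimulus index.

    Uses only attributed events, ordered by stimulus index.  When several
    events attach to one stimulus, the earliest (the light-locked evoked
    response) provides the magnitude — later events inside the response
    window are typically spontaneous behavior, not the evoked
    contraction.  A negative slope indicates habituation.
    """
    by_stim: dict[int, float] = {}
    for ev in attributed_events:
        if ev.stimulus_index is None:
            continue
        by_stim.setdefault(ev.stimulus_index, ev.magnitude)
    if len(by_stim) < 2:
        raise InsufficientDataError(
            "habituation needs >= 2 events attributed to distinct stimuli"
        )
    ks = sorted(by_stim)
    mags = [by_stim[k] for k in ks]
    slope = float(np.polyfit(ks, mags, 1)[0])
    return HabituationResult(tuple(ks), tuple(mags), slope)


def chance_attribution_rate(
    events,
    schedule: LightSchedule,
    n_shifts: int = 20,
    max_latency: float = 0.1,
    response_window: float = 3.0,
) -> float:
    """Chance level of event/stimulus coincidence by circular shifting.

    The schedule is circularly shifted by ``n_shifts`` evenly spaced
    offsets (excluding zero) and the mean attributed-event fraction over
    the shifted schedules is returned.  Events genuinely driven by the
    light exceed this rate; spontaneous behavior does not.
    """
    events = list(events)
    if not events or schedule.total_ticks == 0:
        return 0.0
    total = schedule.total_duration
    rates = []
    for s in range(1, n_shifts + 1):
        shifted = schedule.shifted(total * s / (n_shifts + 1))
        attributed = attribute_to_stimuli(
            events, shifted, max_latency, response_window
        )
        rates.append(
            sum(ev.stimulus_index is not None for ev in attributed) / len(events)
        )
    return float(np.mean(rates))


def overlay_silhouettes(frames_or_masks, n_overlay: int = 11) -> np.ndarray:
    """Composite linearly spaced silhouettes with a dark-red-to-white ramp.

    ``n_overlay`` frame indices are chosen linearly spaced across the clip
    (first and last included).  Early silhouettes are drawn dark red,
    transitioning through light yellow to white for the final frame; later
    frames are drawn on top.  Inputs are binary masks (nonzero = worm);
    the return value is an (H, W, 3) float RGB image on a black
    background.
    """
    stack = np.asarray(frames_or_masks)
    if n_overlay < 2:
        raise ValueError("n_overlay must be at least 2")
    if stack.shape[0] < n_overlay:
        raise ValueError(
            f"need at least {n_overlay} frames, got {stack.shape[0]}"
        )
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "contraction", [(0.4, 0.0, 0.0), (1.0, 1.0, 0.6), (1.0, 1.0, 1.0)]
    )
    indices = np.round(np.linspace(0, stack.shape[0] - 1, n_overlay)).astype(int)
    out = np.zeros(stack.shape[1:3] + (3,), dtype=float)
    for pos, i in enumerate(indices):
        mask = stack[i] > 0
        color = np.array(cmap(pos / (n_overlay - 1))[:3])
        out[mask] = color
    return out
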