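"""Independent reference implementations used as test oracles.

Everything here is deliberately written the dumbest possible way —
explicit enumeration and per-event-time tables — and stays independent of
the package code paths it checks.
"""

from __future__ import annotations

import numpy as np


def enumerate_pulse_times(
    pulse_width: float,
    frequency: float,
    burst_duration: float,
    burst_period: float,
    total_duration: float,
):
    """All (t_on, t_off) pulses of a burst regimen, by float enumeration."""
    pulses = []
    k = 0
    while k * burst_period < total_duration - 1e-9:
        burst_start = k * burst_period
        window_end = min(burst_start + burst_duration, total_duration)
        j = 0
        while True:
            t_on = burst_start + j / frequency
            if t_on >= window_end - 1e-9:
                break
            pulses.append((t_on, min(t_on + pulse_width, window_end)))
            j += 1
        k += 1
    return pulses


def enumerate_interval_onsets(on_time, off_time, total_duration):
    """Exposure onset times of a periodic on/off protocol."""
    onsets = []
    t = 0.0
    while t < total_duration - 1e-9:
        onsets.append(t)
        t += on_time + off_time
    return onsets


def scan_contraction_runs(ecc, valid, times, threshold, merge_window, frame_rate):
    """Brute-force run scanner over an eccentricity trace.

    Walks the trace frame by frame collecting maximal sub-threshold runs,
    then merges runs whose separating gap is shorter than merge_window.
    Returns a list of dicts with onset/trough/magnitude-relevant indices.
    """
    below_frames = [
        i
        for i in range(len(ecc))
        if valid[i] and not np.isnan(ecc[i]) and ecc[i] < threshold
    ]
    if not below_frames:
        return []
    groups = [[below_frames[0]]]
    period = 1.0 / frame_rate
    for f in below_frames[1:]:
        n_between = f - groups[-1][-1] - 1
        if n_between * period < merge_window or n_between == 0:
            groups[-1].append(f)
        else:
            groups.append([f])
    out = []
    for g in groups:
        trough = g[0]
        for f in g:
            if ecc[f] < ecc[trough]:
                trough = f
        out.append(
            {
                "onset_frame": g[0],
                "end_frame": g[-1],
                "trough_frame": trough,
                "trough_ecc": ecc[trough],
            }
        )
    return out


def logrank_by_hand(times_a, times_b):
    """Textbook two-group logrank statistic with tied-event correction.

    Builds the 2x2 table at every distinct event time: with n_j at risk
    (n_aj in group A) and d_j total events (d_aj in A), accumulates
    O - E = sum(d_aj - d_j * n_aj / n_j) and the hypergeometric variance
    sum(d_j * (n_aj/n_j) * (1 - n_aj/n_j) * (n_j - d_j) / (n_j - 1)).
    No censoring (the assay runs until all animals are paralyzed).
    """
    times_a = np.asarray(times_a, float)
    times_b = np.asarray(times_b, float)
    event_times = np.unique(np.concatenate([times_a, times_b]))
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = np.sum(times_a >= t)
        n_b = np.sum(times_b >= t)
        n = n_a + n_b
        d_a = np.sum(times_a == t)
        d_b = np.sum(times_b == t)
        d = d_a + d_b
        if n < 1 or d < 1:
            continue
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var
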