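"""Linear-track sessions: place-tuned spikes with linear phase precession."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrackUnitSpec:
    """Ground-truth spatial tuning and precession of one simulated unit.

    The spatial rate is baseline + peak * Gaussian(center, width); the
    field nominally spans center +/- 2*width.  In-field spike phases
    follow onset + 2*pi*slope*(x - field_start) plus von Mises noise of
    concentration ``kappa``; out-of-field spikes get uniform phases.
    """

    center_cm: float
    width_cm: float
    peak_hz: float
    baseline_hz: float = 0.1
    slope_cyc_per_cm: float = -0.02
    onset_phase: float = np.pi
    kappa: float = 4.0

    @property
    def field_start_cm(self) -> float:
        return self.center_cm - 2.0 * self.width_cm

    @property
    def field_end_cm(self) -> float:
        return self.center_cm + 2.0 * self.width_cm


@dataclass
class TrackGroundTruth:
    units: list[TrackUnitSpec]
    track_len_cm: float
    n_trials: int
    speed_cm_s: float
    theta_hz: float


def synth_track_session(
    track_len: float = 150.0,
    n_trials: int = 80,
    speed: float = 15.0,
    units: list[TrackUnitSpec] = (),
    theta_hz: float = 8.0,
    fs_beh: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, np.ndarray], dict[int, np.ndarray], TrackGroundTruth]:
    """Back-and-forth constant-speed runs with place-field spiking.

    Returns (behavior, spike_times, spike_phases, ground_truth).  The
    behavior table has columns t, x, direction (+1 rightward), speed,
    sampled at ``fs_beh`` Hz.  Spikes are drawn per unit from an
    inhomogeneous Poisson process with Gaussian spatial tuning (thinning
    of a homogeneous process at the peak rate); each spike carries a
    theta phase built from the linear precession model.
    """
    if track_len <= 0:
        raise ValueError("track length must be positive")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    for u in units:
        if not 0 < u.width_cm < track_len:
            raise ValueError("field width must be within the track")
    rng = np.random.default_rng(seed)
    trial_dur = track_len / speed
    total = n_trials * trial_dur
    t = np.arange(int(total * fs_beh)) / fs_beh
    trial_idx = np.minimum((t / trial_dur).astype(int), n_trials - 1)
    frac = t / trial_dur - trial_idx
    direction = np.where(trial_idx % 2 == 0, 1, -1)
    x = np.where(direction > 0, frac * track_len, (1 - frac) * track_len)
    behavior = pd.DataFrame(
        {"t": t, "x": x, "direction": direction, "speed": np.full(t.size, float(speed))}
    )

    spike_times: dict[int, np.ndarray] = {}
    spike_phases: dict[int, np.ndarray] = {}
    for uid, u in enumerate(units):
        rmax = u.baseline_hz + u.peak_hz
        if rmax <= 0:
            spike_times[uid] = np.array([])
            spike_phases[uid] = np.array([])
            continue
        n_cand = rng.poisson(rmax * total)
        tc = np.sort(rng.uniform(0.0, total, size=n_cand))
        xc = np.interp(tc, t, x)
        rate = u.baseline_hz + u.peak_hz * np.exp(-0.5 * ((xc - u.center_cm) / u.width_cm) ** 2)
        keep = rng.random(n_cand) < rate / rmax
        st = tc[keep]
        sx = xc[keep]
        in_field = (sx >= u.field_start_cm) & (sx < u.field_end_cm)
        phases = rng.uniform(0, 2 * np.pi, size=st.size)
        n_in = int(in_field.sum())
        if n_in:
            mean = u.onset_phase + 2 * np.pi * u.slope_cyc_per_cm * (
                sx[in_field] - u.field_start_cm
            )
            phases[in_field] = mean + rng.vonmises(0.0, u.kappa, size=n_in)
        spike_times[uid] = st
        spike_phases[uid] = np.mod(phases, 2 * np.pi)
    gt = TrackGroundTruth(units=list(units), track_len_cm=track_len,
                          n_trials=n_trials, speed_cm_s=speed, theta_hz=theta_hz)
    return behavior, spike_times, spike_phases, gt
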