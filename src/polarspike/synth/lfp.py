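"""Synthetic LFP: pink noise + theta + embedded ripple bursts with a depth profile."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LfpGroundTruth:
    """True ripple intervals (s) and the layer-centre channel."""

    intervals: list[tuple[float, float]]
    centers: np.ndarray          # event centre times, s
    center_channel: int
    fs: float


def _pink_noise(n: int, rng) -> np.ndarray:
    """1/f-amplitude noise, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def synth_lfp_ripples(
    probe,
    duration: float,
    fs: float = 1250.0,
    theta_hz: float = 8.0,
    ripple_rate_per_min: float = 20.0,
    ripple_freq: float = 150.0,
    ripple_dur_ms: float = 60.0,
    center_channel: int = 0,
    snr: float = 10.0,
    seed: int = 0,
    noise_sd_uv: float = 30.0,
    theta_amp_uv: float = 60.0,
    depth_lambda_um: float = 60.0,
    amp_uv: float | None = None,
) -> tuple[np.ndarray, LfpGroundTruth]:
    """Multi-channel LFP (channels x samples, uV) with known ripple events.

    Each event is a Gaussian-windowed ``ripple_freq`` oscillation whose
    amplitude is maximal on ``center_channel`` and decays exponentially
    with vertical distance (length ``depth_lambda_um``).  The ripple
    amplitude is ``snr`` times the SD of the band-passed (80-250 Hz)
    background noise on the centre channel, so detectability is
    controlled directly (or set explicitly via ``amp_uv``).  Event count
    is Poisson; centres closer than twice the event duration to the
    previous kept event are thinned out, so stored intervals never
    overlap.
    """
    if not 80.0 <= ripple_freq <= 250.0:
        raise ValueError("ripple frequency must lie within 80-250 Hz")
    if fs < 1250.0:
        raise ValueError("sampling rate must be at least 1250 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    lfp = np.stack([_pink_noise(n, rng) * noise_sd_uv for _ in range(probe.n_channels)])
    lfp += theta_amp_uv * np.sin(2 * np.pi * theta_hz * t)[None, :]

    # calibrate ripple amplitude against in-band background noise
    from ..ripples import dog_bandpass

    if amp_uv is not None:
        amp = amp_uv
    else:
        center_row = probe._index(center_channel)
        band_sd = dog_bandpass(lfp[center_row], fs).std()
        amp = snr * band_sd

    n_events = rng.poisson(ripple_rate_per_min * duration / 60.0)
    dur = ripple_dur_ms * 1e-3
    margin = dur
    if duration <= 2 * margin and n_events > 0:
        raise ValueError("ripple duration leaves no room for events")
    centers = np.array([])
    if n_events > 0:
        # Poisson centres thinned to a 2*dur minimum separation (keep-first)
        c = np.sort(rng.uniform(margin, duration - margin, size=n_events))
        keep = []
        last = -np.inf
        for ci in c:
            if ci - last >= 2 * dur:
                keep.append(ci)
                last = ci
        centers = np.asarray(keep)

    sigma = dur / 6.0  # envelope truncated at +/-3 sigma == the event interval
    dy = np.abs(probe.y - probe.y_of(center_channel))
    profile = np.exp(-dy / depth_lambda_um)
    intervals = []
    for c in centers:
        i0, i1 = int((c - dur / 2) * fs), int((c + dur / 2) * fs)
        tt = t[i0:i1]
        burst = amp * np.exp(-0.5 * ((tt - c) / sigma) ** 2) * np.sin(
            2 * np.pi * ripple_freq * (tt - c) + rng.uniform(0, 2 * np.pi)
        )
        lfp[:, i0:i1] += profile[:, None] * burst[None, :]
        intervals.append((c - dur / 2, c + dur / 2))

    gt = LfpGroundTruth(intervals=intervals, centers=centers,
                        center_channel=center_channel, fs=fs)
    return lfp, gt
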