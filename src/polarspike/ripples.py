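"""Hippocampal ripple detection, layer localization, and phase locking.

Ripples are transient 80-250 Hz LFP oscillations of CA1 stratum
pyramidale.  Detection band-passes the wideband signal with a zero-lag
difference-of-Gaussians (DOG) FIR filter, forms a rectified low-passed
power envelope, and thresholds it: candidate events exceed 5 SDs above
the mean (both measured on a clipped copy of the envelope during
non-theta immobility), edges extend to 2 SDs, and each event is aligned
to the filtered-trace trough nearest the power peak.  The channel with
the strongest ripple-band envelope marks the pyramidal-layer centre of
each shank.  Per-unit engagement is quantified by the in-ripple /
baseline rate ratio (Poisson-tested) and by phase locking of in-ripple
spikes to the instantaneous Hilbert phase of the filtered signal
(Rayleigh-tested); phase 0 sits at the filtered signal's peak, pi at the
trough, increasing with time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.signal import hilbert

from .circstats import circ_mean_resultant, rayleigh_test


@dataclass(frozen=True)
class RippleEvent:
    onset: float
    trough_time: float
    offset: float
    peak_power: float  # SD units above baseline mean
    channel: int = -1

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PhaseLockResult:
    n_spikes: int
    mean_phase: float
    resultant: float
    rayleigh_p: float
    histogram: np.ndarray
    low_n: bool = False


@dataclass(frozen=True)
class EnvelopeStats:
    power: np.ndarray          # unclipped envelope (detection)
    clipped_power: np.ndarray  # clipped envelope (baseline statistics)
    mean: float
    sd: float


def _gaussian_lowpass_kernel(fs: float, cutoff_hz: float, n_sigma: float = 8.0) -> np.ndarray:
    """Unit-DC-gain Gaussian FIR low-pass with -3 dB at ``cutoff_hz``."""
    sigma_f = cutoff_hz / np.sqrt(np.log(2.0))
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = max(1, int(np.ceil(n_sigma * sigma_t * fs)))
    t = np.arange(-half, half + 1) / fs
    k = np.exp(-0.5 * (t / sigma_t) ** 2)
    return k / k.sum()


def dog_bandpass(lfp, fs: float, band: tuple[float, float] = (80.0, 250.0)) -> np.ndarray:
    """Zero-lag difference-of-Gaussians FIR band-pass filter.

    The kernel is the difference of two Gaussian low-pass kernels whose
    -3 dB points sit at the band edges, normalized to unit gain at the
    passband peak.  The kernel is symmetric (linear phase) and applied
    with 'same' convolution, so the output has zero lag.
    """
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi < fs / 2):
        raise ValueError("band edges must satisfy 0 < lo < hi < Nyquist")
    k_hi = _gaussian_lowpass_kernel(fs, f_hi)
    k_lo = _gaussian_lowpass_kernel(fs, f_lo)
    n = max(k_hi.size, k_lo.size)
    kernel = np.zeros(n)
    kernel[(n - k_hi.size) // 2 : (n - k_hi.size) // 2 + k_hi.size] += k_hi
    kernel[(n - k_lo.size) // 2 : (n - k_lo.size) // 2 + k_lo.size] -= k_lo
    # normalize to unit peak passband gain
    freqs = np.linspace(0, fs / 2, 2048)
    resp = np.abs(np.exp(-2j * np.pi * np.outer(freqs, np.arange(n) - n // 2) / fs) @ kernel)
    kernel /= resp.max()
    x = np.asarray(lfp, float)
    if x.ndim == 1:
        return np.convolve(x, kernel, mode="same")
    return np.stack([np.convolve(row, kernel, mode="same") for row in x])


def power_envelope(
    filtered,
    fs: float,
    clip_sd: float = 5.0,
    lp_cutoff: float = 55.0,
    baseline_mask=None,
) -> EnvelopeStats:
    """Rectified, low-passed power envelope with clipped baseline statistics.

    The clipped variant limits the filtered signal to ``clip_sd`` SDs
    before rectification so that the baseline mean/SD are robust to the
    events themselves; detection uses the unclipped envelope.  Statistics
    are computed over ``baseline_mask`` (non-theta immobility); an empty
    mask falls back to the whole signal with a warning.
    """
    x = np.asarray(filtered, float)
    if baseline_mask is None or not np.any(baseline_mask):
        if baseline_mask is not None:
            warnings.warn("empty baseline mask; using whole-signal statistics")
        baseline_mask = np.ones(x.size, dtype=bool)
    sd_raw = x[baseline_mask].std()
    clipped = np.clip(x, -clip_sd * sd_raw, clip_sd * sd_raw)
    k = _gaussian_lowpass_kernel(fs, lp_cutoff)
    power = np.convolve(np.abs(x), k, mode="same")
    clipped_power = np.convolve(np.abs(clipped), k, mode="same")
    mean = float(clipped_power[baseline_mask].mean())
    sd = float(clipped_power[baseline_mask].std())
    return EnvelopeStats(power=power, clipped_power=clipped_power, mean=mean, sd=sd)


def detect_ripples(
    env: EnvelopeStats,
    fs: float,
    hi: float = 5.0,
    lo: float = 2.0,
    filtered=None,
    min_dur_ms: float = 15.0,
    max_dur_ms: float = 400.0,
    channel: int = -1,
) -> list[RippleEvent]:
    """Threshold the power envelope into ripple events.

    Samples exceeding ``hi`` SDs seed events, edges extend until the power
    drops below ``lo`` SDs, overlapping events merge, and events outside
    the [min, max] duration bounds are dropped.  If the band-passed trace
    is supplied, each event is aligned to its trough nearest the power
    peak; otherwise the power peak itself is the alignment point.
    """
    if hi <= lo:
        raise ValueError("hi threshold must exceed lo")
    z = (env.power - env.mean) / env.sd
    above_lo = z > lo
    if not np.any(z > hi):
        return []
    # contiguous runs of above_lo containing at least one hi sample
    runs = []
    idx = np.flatnonzero(above_lo)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        seg_starts = np.r_[idx[0], idx[breaks + 1]]
        seg_ends = np.r_[idx[breaks], idx[-1]]
        for s, e in zip(seg_starts, seg_ends):
            if np.max(z[s : e + 1]) > hi:
                runs.append((int(s), int(e)))
    events = []
    min_n = min_dur_ms * 1e-3 * fs
    max_n = max_dur_ms * 1e-3 * fs
    for s, e in runs:
        if not (min_n <= e - s + 1 <= max_n):
            continue
        peak = s + int(np.argmax(z[s : e + 1]))
        if filtered is not None:
            seg = np.asarray(filtered, float)[s : e + 1]
            mins = np.flatnonzero((np.diff(np.sign(np.diff(seg))) > 0)) + 1
            trough = s + (mins[np.argmin(np.abs(mins - (peak - s)))] if mins.size else int(np.argmin(seg)))
        else:
            trough = peak
        events.append(
            RippleEvent(
                onset=s / fs,
                trough_time=trough / fs,
                offset=(e + 1) / fs,
                peak_power=float(z[peak]),
                channel=channel,
            )
        )
    return events


def layer_center(filtered_multichannel: np.ndarray, fs: float, events, probe=None) -> dict | int:
    """Channel with the maximal mean ripple-band envelope over events.

    ``filtered_multichannel`` is channels x samples of band-passed LFP.
    With a probe the winner is reported per shank (dict shank -> channel,
    ties to the lowest channel id); without, the single global winner.
    """
    if not events:
        warnings.warn("no ripple events; layer centre undefined")
        return {} if probe is not None else -1
    x = np.atleast_2d(np.asarray(filtered_multichannel, float))
    mask = np.zeros(x.shape[1], dtype=bool)
    for ev in events:
        mask[int(ev.onset * fs) : int(np.ceil(ev.offset * fs))] = True
    amp = np.abs(x[:, mask]).mean(axis=1)
    if probe is None:
        return int(np.argmax(amp))
    out = {}
    for shank in np.unique(probe.shank_ids):
        chans = probe.channels_on_shank(shank)
        out[int(shank)] = int(chans[np.argmax(amp[chans])])
    return out


def _time_in_intervals(t: np.ndarray, intervals) -> np.ndarray:
    """Boolean mask of which times fall inside any [start, stop) interval."""
    mask = np.zeros(t.size, dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def ripple_rate_gain(
    spike_times,
    events,
    baseline_intervals,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """In-ripple firing-rate gain of a unit, with a Poisson significance test.

    gain = (rate during ripple events) / (baseline rate during non-theta
    immobility); the upper-tail Poisson test asks whether the in-event
    spike count exceeds the expectation baseline_rate * total event time.
    Returns (gain, p).  A zero baseline rate yields (nan, nan).
    """
    t = np.asarray(spike_times, float)
    ev_iv = [(e.onset, e.offset) for e in events]
    t_ev = sum(b - a for a, b in ev_iv)
    if t_ev <= 0:
        raise ValueError("total event duration must be positive")
    t_base = sum(b - a for a, b in baseline_intervals)
    n_in = int(np.count_nonzero(_time_in_intervals(t, ev_iv)))
    n_base = int(np.count_nonzero(_time_in_intervals(t, baseline_intervals)))
    if t_base <= 0 or n_base == 0:
        warnings.warn("zero baseline rate; ripple gain undefined")
        return float("nan"), float("nan")
    base_rate = n_base / t_base
    gain = (n_in / t_ev) / base_rate
    p = float(sps.poisson.sf(n_in - 1, base_rate * t_ev))
    return float(gain), p


def instantaneous_phase(filtered) -> np.ndarray:
    """Hilbert phase of the band-passed signal in [0, 2*pi); 0 at the peak."""
    return np.mod(np.angle(hilbert(np.asarray(filtered, float))), 2 * np.pi)


def ripple_phase_locking(
    spike_times,
    filtered,
    fs: float,
    events,
    n_bins: int = 20,
    min_spikes: int = 10,
) -> PhaseLockResult:
    """Phase locking of a unit's in-ripple spikes to the ripple oscillation.

    Spikes inside events are assigned the instantaneous Hilbert phase of
    the DOG-filtered signal at their time of firing; the result carries
    the circular mean phase, resultant length R, Rayleigh uniformity
    p-value, and a phase histogram over ``n_bins`` equal bins.
    """
    if not events:
        raise ValueError("no ripple events")
    t = np.asarray(spike_times, float)
    phase = instantaneous_phase(filtered)
    in_ev = _time_in_intervals(t, [(e.onset, e.offset) for e in events])
    idx = np.clip(np.round(t[in_ev] * fs).astype(int), 0, phase.size - 1)
    sp_phase = phase[idx]
    hist = np.histogram(sp_phase, bins=np.linspace(0, 2 * np.pi, n_bins + 1))[0]
    if sp_phase.size == 0:
        return PhaseLockResult(0, float("nan"), float("nan"), float("nan"), hist, low_n=True)
    mu, r = circ_mean_resultant(sp_phase)
    p = rayleigh_test(sp_phase)
    return PhaseLockResult(
        n_spikes=int(sp_phase.size),
        mean_phase=mu,
        resultant=r,
        rayleigh_p=p,
        histogram=hist,
        low_n=sp_phase.size < min_spikes,
    )


def immobility_mask(speed: np.ndarray, theta_delta_ratio: np.ndarray | None = None,
                    speed_max: float = 1.0, ratio_max: float = 2.0) -> np.ndarray:
    """Non-theta immobility: speed below 1 cm/s and (if given) theta/delta < 2."""
    mask = np.asarray(speed, float) < speed_max
    if theta_delta_ratio is not None:
        mask &= np.asarray(theta_delta_ratio, float) < ratio_max
    return mask
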