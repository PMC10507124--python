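"""Analytic waveform templates with exact ground truth.

Each electrode waveform is a sum of Gaussian lobes, so the continuous
template is known in closed form and its extrema (looked up on a dense
1 us grid of the analytic expression, independent of the 20 kHz
sampling and of the analysis pipeline's spline upsampling) provide
exact ground-truth peak/trough times, amplitudes, and inter-channel
lags.

Archetypes (per-channel shapes; the 32-sample window is aligned so the
detection extremum of the main channel sits at 0-based sample 15):

* N: negative trough of amplitude A with a smaller positive rebound
  *after* it (0.3 A, 2 sigma later).  The rebound places the waveform's
  largest local maximum after the trough, which rules out the B
  category by lobe order, and shapes the spectrum so the dominant
  frequency scales as 1/sigma.
* P: mirror image in sign and time: positive peak with a negative dip
  *before* it, so the trough precedes the peak and B is again excluded.
* B: positive peak followed 3 sigma later by a larger negative trough
  (peak/trough ratio 0.6-0.9, hence BPI between about -0.25 and -0.05).

SM units repeat one archetype over a run of contiguous channels with
geometrically decaying amplitude; MM units carry the N archetype on the
main channel and a P- or B-template on a channel a configurable signed
number of sites away (positive = toward the brain surface), with a
configurable extremum lag of tens of us.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..waveforms import FS, N_SAMPLES, B, N, P

#: alignment: detection extremum at 0-based sample 15
ALIGN_SAMPLE = 15
ALIGN_T = ALIGN_SAMPLE / FS

#: rebound/dip amplitudes relative to the main lobe (N and P archetypes);
#: the dominant side fixes the lobe order, the near-equal opposite side
#: almost cancels the overlap-induced shift of the main extremum
REBOUND_REL = 0.3
REBOUND_REL_MINOR = 0.25
#: rebound/dip centre offset in units of sigma
REBOUND_OFFSET_SIGMA = 2.0
#: B-spike peak-to-trough lobe separation in units of sigma
B_SEP_SIGMA = 3.0
#: B-spike sigma relative to the unit's nominal sigma (B-spikes are narrower)
LOBE_SIGMA_REL = 0.7

_DENSE_DT = 1e-6  # 1 us ground-truth grid


def _lobes_n(amp: float, sigma: float, t0: float) -> list[tuple[float, float, float]]:
    d = REBOUND_OFFSET_SIGMA * sigma
    return [
        (-amp, t0, sigma),
        (REBOUND_REL * amp, t0 + d, sigma),        # dominant rebound after the trough
        (REBOUND_REL_MINOR * amp, t0 - d, sigma),
    ]


def _lobes_p(amp: float, sigma: float, t0: float) -> list[tuple[float, float, float]]:
    d = REBOUND_OFFSET_SIGMA * sigma
    return [
        (amp, t0, sigma),
        (-REBOUND_REL * amp, t0 - d, sigma),       # dominant dip before the peak
        (-REBOUND_REL_MINOR * amp, t0 + d, sigma),
    ]


def _lobes_b(amp: float, sigma: float, t0: float, ratio: float) -> list[tuple[float, float, float]]:
    s = LOBE_SIGMA_REL * sigma
    return [(-amp, t0, s), (ratio * amp, t0 - B_SEP_SIGMA * s, s)]


def eval_lobes(lobes, t) -> np.ndarray:
    """Evaluate a sum of Gaussian lobes (amp, centre s, sigma s) at times t."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    for a, c, s in lobes:
        out += a * np.exp(-0.5 * ((t - c) / s) ** 2)
    return out


def _dense_extrema(lobes, window_s: float = N_SAMPLES / FS) -> tuple[float, float, float, float]:
    """Ground-truth (peak_t, peak_v, trough_t, trough_v) on a 1 us grid."""
    t = np.arange(0.0, window_s, _DENSE_DT)
    v = eval_lobes(lobes, t)
    ip, iin = int(np.argmax(v)), int(np.argmin(v))
    return t[ip], float(v[ip]), t[iin], float(v[iin])


@dataclass
class UnitGroundTruth:
    """Generator manifest entry for one unit."""

    unit_id: int
    shank: int
    archetype: str                      # SM-N, SM-P, SM-B, MM-P, MM-B
    main_channel: int
    sigma_ms: float
    channel_category: dict[int, str] = field(default_factory=dict)
    channel_amp: dict[int, float] = field(default_factory=dict)
    peak_time: dict[int, float] = field(default_factory=dict)    # s, window-relative
    trough_time: dict[int, float] = field(default_factory=dict)
    channel_bpi: dict[int, float] = field(default_factory=dict)
    offset_sites: int | None = None
    lag_np_us: float | None = None      # P-peak minus N-trough
    lag_bt_us: float | None = None      # B-trough minus N-trough
    lag_bp_us: float | None = None      # B-peak minus N-trough


@dataclass
class TemplateSet:
    """Noise-free unit templates over the full probe (units x channels x 32)."""

    templates: dict[int, np.ndarray]            # unit -> (n_channels, 32) uV
    lobes: dict[int, dict[int, list]]           # unit -> channel -> lobes
    ground_truth: list[UnitGroundTruth]
    probe: object


def synth_unit_templates(
    probe,
    n_units: int,
    mix: tuple[float, float, float, float] = (0.4, 0.15, 0.15, 0.3),
    amp_range: tuple[float, float] = (40.0, 200.0),
    width_range: tuple[float, float] = (0.05, 0.11),
    lag_range: tuple[float, float] = (-100.0, 100.0),
    seed: int = 0,
    mm_kind: str = "both",
    mm_offset_sites: tuple[int, ...] = (-2, -1, 1, 2),
    mm_amp_rel: float = 0.5,
    span_sites: int = 1,
    decay: float = 0.6,
    b_ratio_range: tuple[float, float] = (0.6, 0.9),
) -> TemplateSet:
    """Generate per-unit, per-channel analytic waveform templates.

    ``mix`` gives the fractions of SM-N / SM-P / SM-B / MM archetypes
    (must sum to 1).  ``width_range`` is the Gaussian lobe sigma in ms,
    ``amp_range`` the main-lobe amplitude in uV, ``lag_range`` the MM
    extremum lag in us of the non-negative template relative to the
    N-trough.  SM units spread over ``span_sites`` neighbours on each
    side of the main channel with amplitude factor ``decay`` per site.
    """
    mix = np.asarray(mix, float)
    if not np.isclose(mix.sum(), 1.0):
        raise ValueError("mix fractions must sum to 1")
    if np.any(np.asarray(amp_range) <= 0) or np.any(np.asarray(width_range) <= 0):
        raise ValueError("ranges must be positive")
    if max(abs(lag_range[0]), abs(lag_range[1])) * 1e-6 >= N_SAMPLES / FS / 2:
        raise ValueError("lag exceeds the snippet window")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(4, size=n_units, p=mix)
    shanks = np.unique(probe.shank_ids)

    templates, all_lobes, gts = {}, {}, []
    t_grid = np.arange(N_SAMPLES) / FS
    for uid in range(n_units):
        kind = int(kinds[uid])
        shank = int(rng.choice(shanks))
        ladder = probe.channels_on_shank(shank)
        sigma = rng.uniform(*width_range) * 1e-3
        amp = rng.uniform(*amp_range)

        unit_lobes: dict[int, list] = {}
        if kind < 3:  # SM archetypes
            label = (N, P, B)[kind]
            arche = f"SM-{label}"
            pos = int(rng.integers(span_sites, ladder.size - span_sites)) if ladder.size > 2 * span_sites else ladder.size // 2
            main_ch = int(ladder[pos])
            ratio = rng.uniform(*b_ratio_range)
            for k in range(-span_sites, span_sites + 1):
                if not (0 <= pos + k < ladder.size):
                    continue
                ch = int(ladder[pos + k])
                a = amp * decay ** abs(k)
                if label == N:
                    unit_lobes[ch] = _lobes_n(a, sigma, ALIGN_T)
                elif label == P:
                    unit_lobes[ch] = _lobes_p(a, sigma, ALIGN_T)
                else:
                    unit_lobes[ch] = _lobes_b(a, sigma, ALIGN_T, ratio)
            offset = None
            lag_us = None
        else:  # MM: N on the main channel + P or B on an offset channel
            if mm_kind == "both":
                other_label = P if rng.random() < 0.5 else B
            else:
                other_label = {"P": P, "B": B}[mm_kind]
            arche = f"MM-{other_label}"
            offsets = [o for o in mm_offset_sites]
            pos = int(rng.integers(max(0, -min(offsets)), ladder.size - max(max(offsets), 0)))
            offset = int(rng.choice(offsets))
            main_ch = int(ladder[pos])
            other_ch = int(ladder[pos + offset])
            lag_us = float(rng.uniform(*lag_range))
            unit_lobes[main_ch] = _lobes_n(amp, sigma, ALIGN_T)
            t_other = ALIGN_T + lag_us * 1e-6
            if other_label == P:
                unit_lobes[other_ch] = _lobes_p(amp * mm_amp_rel, sigma, t_other)
            else:
                ratio = rng.uniform(*b_ratio_range)
                unit_lobes[other_ch] = _lobes_b(amp * mm_amp_rel, sigma, t_other, ratio)

        arr = np.zeros((probe.n_channels, N_SAMPLES))
        gt = UnitGroundTruth(
            unit_id=uid, shank=shank, archetype=arche, main_channel=main_ch,
            sigma_ms=sigma * 1e3, offset_sites=offset,
        )
        for ch, lobes in unit_lobes.items():
            arr[probe._index(ch)] = eval_lobes(lobes, t_grid)
            tp, vp, tn, vn = _dense_extrema(lobes)
            label = _true_label(lobes)
            gt.channel_category[ch] = label
            gt.channel_amp[ch] = float(max(vp, -vn))
            gt.peak_time[ch] = tp
            gt.trough_time[ch] = tn
            gt.channel_bpi[ch] = float((vp - abs(vn)) / (vp + abs(vn)))
        if arche.startswith("MM"):
            other_ch = next(c for c in unit_lobes if c != main_ch)
            t_ref = gt.trough_time[main_ch]
            if gt.channel_category[other_ch] == P:
                gt.lag_np_us = (gt.peak_time[other_ch] - t_ref) * 1e6
            else:
                gt.lag_bt_us = (gt.trough_time[other_ch] - t_ref) * 1e6
                gt.lag_bp_us = (gt.peak_time[other_ch] - t_ref) * 1e6
        templates[uid] = arr
        all_lobes[uid] = unit_lobes
        gts.append(gt)
    return TemplateSet(templates=templates, lobes=all_lobes, ground_truth=gts, probe=probe)


def _true_label(lobes) -> str:
    """Ground-truth category from the lobe construction."""
    tp, vp, tn, vn = _dense_extrema(lobes)
    if vp > 0 and -vn > 0 and tp < tn and -0.6 < (vp - abs(vn)) / (vp + abs(vn)) < 0.8:
        return B
    return P if vp > abs(vn) else N
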