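"""Same-unit extremum timing and signed electrode distances.

For multi-modal (MM) units that carry an N-spike on one electrode and a
P- or B-spike on another, the time lag between the N-spike trough and the
non-negative waveform's extrema measures propagation between cellular
compartments, and the signed vertical distance between the electrodes
localizes the non-negative waveform relative to the soma (positive =
closer to the brain surface).  Lags are measured between extrema of the
upsampled mean waveforms, so they live on a 12.5 us grid (80 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from . import waveforms as wf
from .circstats import perm_pvalue


@dataclass
class LagRecord:
    """Extremum lags (us) and signed distance (um) for one MM unit.

    ``lag_np``: P-peak minus N-trough time; ``lag_bt`` / ``lag_bp``:
    B-trough / B-peak minus N-trough time.  ``signed_distance`` is
    y(non-negative channel) - y(N channel): positive when the non-negative
    waveform sits closer to the brain surface.  Lags are None when the
    unit has no channel of that category.
    """

    unit_id: int
    n_channel: int
    other_channel: int | None
    lag_np: float | None = None
    lag_bt: float | None = None
    lag_bp: float | None = None
    signed_distance: float | None = None
    cross_shank: bool = False
    bpi: float | None = None


class NotApplicableError(ValueError):
    """Raised when a unit has no qualifying N + non-negative channel pair."""


def _upsampled(unit: wf.Unit, channel: int) -> wf.UpsampledWaveform:
    return wf.preprocess_waveform(unit.waveforms[channel])


def _best_channel(unit: wf.Unit, label: str) -> int | None:
    """Largest-magnitude channel carrying the given category, or None."""
    chans = unit.categorized_channels(label)
    if not chans:
        return None
    mags = [unit.waveforms[ch].magnitude for ch in chans]
    return chans[int(np.argmax(mags))]


def extremum_lags(unit: wf.Unit) -> LagRecord:
    """Extremum time lags of a MM unit's non-negative waveform vs its N-trough.

    The reference is the trough time of the largest-magnitude N-channel.
    If the unit has a B-channel, ``lag_bt``/``lag_bp`` are filled from the
    largest-magnitude B-channel; if it has a P-channel, ``lag_np`` from
    the largest-magnitude P-channel.  Raises
    :class:`NotApplicableError` for SM units or units lacking the pair.
    """
    if unit.modality != wf.MM:
        raise NotApplicableError("extremum lags require a multi-modal unit")
    n_ch = _best_channel(unit, wf.N)
    if n_ch is None:
        raise NotApplicableError("unit has no N-channel")
    p_ch = _best_channel(unit, wf.P)
    b_ch = _best_channel(unit, wf.B)
    if p_ch is None and b_ch is None:
        raise NotApplicableError("unit has no P- or B-channel")

    n_up = _upsampled(unit, n_ch)
    t_n_ref = wf.find_extrema(n_up).t_n
    dt_us = 1e6 / n_up.fs  # 12.5 us

    rec = LagRecord(unit_id=unit.unit_id, n_channel=n_ch, other_channel=b_ch or p_ch)
    if p_ch is not None:
        e = wf.find_extrema(_upsampled(unit, p_ch))
        rec.lag_np = (e.t_p - t_n_ref) * dt_us
        if b_ch is None:
            rec.other_channel = p_ch
            rec.bpi = unit.categories[p_ch].bpi
    if b_ch is not None:
        e = wf.find_extrema(_upsampled(unit, b_ch))
        rec.lag_bt = (e.t_n - t_n_ref) * dt_us
        rec.lag_bp = (e.t_p - t_n_ref) * dt_us
        rec.other_channel = b_ch
        rec.bpi = unit.categories[b_ch].bpi
    return rec


def signed_distance(unit: wf.Unit, probe, record: LagRecord | None = None) -> LagRecord:
    """Signed vertical distance from the N channel to the non-negative channel.

    Positive distances mean the non-negative waveform is closer to the
    brain surface (larger y).  Cross-shank pairs get ``cross_shank=True``
    and no distance (they are excluded from distance analyses).
    """
    rec = record or extremum_lags(unit)
    if rec.other_channel is None:
        return rec
    if probe.shank_of(rec.n_channel) != probe.shank_of(rec.other_channel):
        rec.cross_shank = True
        rec.signed_distance = None
    else:
        rec.signed_distance = probe.y_of(rec.other_channel) - probe.y_of(rec.n_channel)
    return rec


def median_with_ci(values, level: float = 0.95, seed: int = 0, n_boot: int = 10000):
    """Sample median with a distribution-free confidence interval.

    Uses the binomial order-statistic CI (the widest pair of order
    statistics whose coverage reaches ``level``); for n < 6 (where no such
    pair exists at 95%) falls back to a seeded bootstrap percentile CI.
    """
    v = np.sort(np.asarray(values, float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(v))
    if n >= 6:
        # [X_(l), X_(n+1-l)] covers the median with prob 1 - 2 P(Bin(n,1/2) <= l-1);
        # take the largest l keeping that probability >= level
        cdf = sps.binom.cdf(np.arange(n + 1), n, 0.5)
        alpha = (1.0 - level) / 2.0
        j = int(np.searchsorted(cdf, alpha, side="right"))  # count of k with P(Bin<=k) <= alpha
        if j >= 1:
            lo_idx = j - 1  # 0-based l-1
            hi_idx = n - j
            return med, float(v[lo_idx]), float(v[hi_idx])
    rng = np.random.default_rng(seed)
    boots = np.median(rng.choice(v, size=(n_boot, n), replace=True), axis=1)
    lo, hi = np.quantile(boots, [(1 - level) / 2, (1 + level) / 2])
    return med, float(lo), float(hi)


def test_median(values, null_value: float = 0.0, mode: str = "two-sided") -> float:
    """Wilcoxon signed-rank test of the sample median against a fixed value.

    ``mode='two-sided'`` tests median(values) == null_value;
    ``mode='abs-less-than'`` tests one-sidedly whether |values| are below
    the threshold ``null_value``.
    """
    v = np.asarray(values, float)
    if v.size < 5:
        raise ValueError("need n >= 5")
    if mode == "two-sided":
        d = v - null_value
        alternative = "two-sided"
    elif mode == "abs-less-than":
        d = np.abs(v) - null_value
        alternative = "less"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.all(d == 0):
        import warnings

        warnings.warn("all differences are zero; p = 1")
        return 1.0
    return float(sps.wilcoxon(d, alternative=alternative, zero_method="wilcox").pvalue)


def rank_cc_perm(x, y, n_perm: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided label-permutation p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need equal-length samples with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    cc = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    for i in range(n_perm):
        null[i] = np.corrcoef(rx, rng.permutation(ry))[0, 1]
    return cc, perm_pvalue(cc, null, two_sided=True)
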