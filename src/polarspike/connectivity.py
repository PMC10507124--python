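"""CCH-based monosynaptic connectivity and spike transmission gain.

A putative monosynaptic connection between two units leaves a short-latency
causal peak (excitatory) or trough (inhibitory) in their cross-correlation
histogram (CCH; 0.1 ms bins).  The pipeline follows four steps:

1. count CCH between reference (presynaptic) and target trains;
2. slow comodulation baseline by hollowed median filtering of the count CCH;
3. removal of presynaptic burst structure by regularized Fourier
   deconvolution of the CCH with the reference autocorrelation;
4. spike transmission gain (STG): the area under the transmission curve
   (deconvolved CCH minus baseline, scaled to spikes/s) in the monosynaptic
   region of interest (0 < t <= 5 ms), extended to the causal zero
   crossings.  STG estimates the number of postsynaptic spikes added (or,
   negative, removed) per presynaptic spike.

Detection uses a per-bin Poisson test of the deconvolved counts against the
baseline, Bonferroni-corrected over the ROI bins, requiring at least two
adjacent significant bins of the same sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

EXC, INH, NONE = "excitatory", "inhibitory", "none"


@dataclass
class CCH:
    """Count cross-correlogram with bin edges symmetric around zero lag."""

    counts: np.ndarray
    bin_ms: float
    half_window_ms: float
    ref_id: int = -1
    tgt_id: int = -1
    n_ref: int = 0

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def edges_ms(self) -> np.ndarray:
        half = self.n_bins // 2
        return (np.arange(self.n_bins + 1) - half) * self.bin_ms

    @property
    def centers_ms(self) -> np.ndarray:
        e = self.edges_ms
        return 0.5 * (e[:-1] + e[1:])

    def roi_slice(self, roi_ms: float = 5.0) -> slice:
        """Causal monosynaptic bins, centers in (0, roi_ms]."""
        half = self.n_bins // 2
        return slice(half, half + int(round(roi_ms / self.bin_ms)))


@dataclass
class ConnectionResult:
    ref_id: int
    tgt_id: int
    sign: str
    stg: float
    p_value: float
    lag_ms: float | None
    roi: tuple[int, int] | None
    transmission: np.ndarray | None = None
    baseline: np.ndarray | None = None


def compute_cch(
    ref_times,
    tgt_times,
    bin_ms: float = 0.1,
    half_window_ms: float = 50.0,
    auto: bool | None = None,
    ref_id: int = -1,
    tgt_id: int = -1,
) -> CCH:
    """Count CCH of target minus reference spike-time differences (times in s).

    ``auto=True`` (default when the same array is passed twice) excludes
    only the zero-lag same-spike pairs of an autocorrelogram.
    """
    ref = np.asarray(ref_times, float)
    tgt = np.asarray(tgt_times, float)
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    if auto is None:
        auto = ref is tgt_times or (ref.size == tgt.size and np.array_equal(ref, tgt))
    n_half = int(round(half_window_ms / bin_ms))
    n_bins = 2 * n_half
    counts = np.zeros(n_bins, dtype=np.int64)
    if ref.size == 0 or tgt.size == 0:
        warnings.warn("empty spike train: all-zero CCH")
        return CCH(counts, bin_ms, half_window_ms, ref_id, tgt_id, ref.size)
    hw_s = half_window_ms * 1e-3
    lo = np.searchsorted(tgt, ref - hw_s, side="left")
    hi = np.searchsorted(tgt, ref + hw_s, side="right")
    reps = hi - lo
    total = int(reps.sum())
    if total:
        starts = np.repeat(lo, reps)
        offs = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
        j = starts + offs
        i = np.repeat(np.arange(ref.size), reps)
        if auto:
            keep = j != i
            j, i = j[keep], i[keep]
        diffs_ms = (tgt[j] - ref[i]) * 1e3
        edges = (np.arange(n_bins + 1) - n_half) * bin_ms
        counts += np.histogram(diffs_ms, bins=edges)[0]
    return CCH(counts, bin_ms, half_window_ms, ref_id, tgt_id, ref.size)


def baseline_hollowed_median(
    cch: CCH, window_ms: float = 10.0, hollow_bins: int = 5
) -> np.ndarray:
    """Hollowed running-median baseline of a count CCH.

    At each bin the baseline is the median of counts within +/- window/2,
    excluding the evaluated bin and ``hollow_bins`` bins on each side of
    it.  Near the edges the window shrinks.
    """
    half = int(round(window_ms / 2.0 / cch.bin_ms))
    if half <= hollow_bins:
        raise ValueError("median window must exceed the hollowed extent")
    c = np.asarray(cch.counts, float)
    n = c.size
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        idx = np.r_[lo : max(lo, i - hollow_bins), min(hi, i + hollow_bins + 1) : hi]
        out[i] = np.median(c[idx]) if idx.size else c[i]
    return out


def _deconv_kernel(ach: CCH) -> np.ndarray:
    """Burst-structure kernel from a reference ACH: delta + excess ACH shape.

    The kernel lives on integer bin shifts.  Its zero-shift tap is 1 (every
    reference spike co-occurs with itself) and the off-centre taps are the
    ACH interpolated at integer multiples of the bin width, chance level
    (the mean of those values) subtracted, per reference spike.  The
    subtraction makes the kernel sum exactly 1, so deconvolution preserves
    count mass and is the identity for a flat (Poisson) ACH.
    """
    if ach.n_ref == 0:
        raise ValueError("reference ACH has no spikes")
    a = np.asarray(ach.counts, float)
    n = a.size
    half = n // 2
    # ACH value at shift m*bin = mean of the two bins adjacent to that edge
    shifts = np.arange(1, half)
    vals = 0.5 * (a[half + shifts - 1] + a[half + shifts])  # positive shifts
    vals_neg = 0.5 * (a[half - shifts] + a[half - shifts - 1])
    excess = np.concatenate([vals, vals_neg])
    chance = excess.mean()
    kernel = np.zeros(n)
    kernel[0] = 1.0
    kernel[shifts] = (vals - chance) / ach.n_ref
    kernel[-shifts] = (vals_neg - chance) / ach.n_ref
    return kernel


def deconvolve_cch(cch: CCH, ach_ref: CCH, mode: str = "regularized", eps_rel: float = 1e-3) -> CCH:
    """Remove presynaptic burst structure from a CCH by Fourier deconvolution.

    Tikhonov-regularized division by the burst kernel built from the
    reference unit's ACH (``eps_rel`` of the max kernel power).  Total
    count mass is preserved within a fraction ``eps_rel``.  ``mode='off'``
    returns the input unchanged.
    """
    if mode == "off":
        return cch
    if mode != "regularized":
        raise ValueError(f"unknown mode {mode!r}")
    if cch.n_bins != ach_ref.n_bins or cch.bin_ms != ach_ref.bin_ms:
        raise ValueError("CCH and ACH binning must match")
    kernel = _deconv_kernel(ach_ref)
    k = np.fft.rfft(kernel)
    c = np.fft.rfft(np.asarray(cch.counts, float))
    power = np.abs(k) ** 2
    eps = eps_rel * power.max()
    dc = np.fft.irfft(c * np.conj(k) / (power + eps), n=cch.n_bins)
    out = CCH(dc, cch.bin_ms, cch.half_window_ms, cch.ref_id, cch.tgt_id, cch.n_ref)
    return out


def transmission_curve(dccch: CCH, baseline: np.ndarray) -> np.ndarray:
    """Deconvolved CCH minus baseline, scaled to spikes/s."""
    if dccch.n_ref == 0:
        return np.zeros(dccch.n_bins)
    return (np.asarray(dccch.counts, float) - baseline) / (dccch.n_ref * dccch.bin_ms * 1e-3)


def stg_from_curve(
    diff_rate: np.ndarray,
    n_ref: int,
    bin_ms: float,
    roi_ms: float = 5.0,
    sign: str = "auto",
) -> tuple[float, tuple[int, int], float]:
    """Spike transmission gain from a transmission curve (spikes/s).

    Locates the extremum inside the causal ROI (0, roi_ms], extends the
    integration limits to the nearest zero crossings (never acausally, so
    the left limit stops at t = 0), and integrates.  Returns
    ``(stg, (lo, hi), lag_ms)`` where STG is in postsynaptic spikes per
    presynaptic spike (negative for troughs) and lag is the extremum bin
    centre.  ``sign`` picks the extremum: 'positive', 'negative', or
    'auto' (largest absolute deviation).
    """
    diff = np.asarray(diff_rate, float)
    n = diff.size
    half = n // 2
    n_roi = int(round(roi_ms / bin_ms))
    if n_roi < 1 or half + n_roi > n:
        raise ValueError("ROI outside the CCH window")
    roi = diff[half : half + n_roi]
    if sign == "positive":
        i_ext = half + int(np.argmax(roi))
    elif sign == "negative":
        i_ext = half + int(np.argmin(roi))
    else:
        i_ext = half + int(np.argmax(np.abs(roi)))
    s = 1.0 if diff[i_ext] >= 0 else -1.0
    lo = i_ext
    while lo > half and s * diff[lo - 1] > 0:
        lo -= 1
    hi = i_ext
    while hi < n - 1 and s * diff[hi + 1] > 0:
        hi += 1
    stg = float(diff[lo : hi + 1].sum() * bin_ms * 1e-3)
    lag_ms = (i_ext - half + 0.5) * bin_ms
    return stg, (lo, hi), lag_ms


def detect_connection(
    cch: CCH,
    ach_ref: CCH,
    alpha: float = 0.001,
    roi_ms: float = 5.0,
    deconv_mode: str = "regularized",
    baseline_window_ms: float = 10.0,
    hollow_bins: int = 5,
    min_adjacent: int = 2,
    baseline_floor: float = 0.1,
) -> ConnectionResult:
    """Full monosynaptic test for an ordered (reference -> target) pair.

    Per-bin Poisson tail probabilities of the deconvolved counts against
    the hollowed-median baseline of the count CCH, Bonferroni-corrected
    over the ROI bins; a connection requires >= ``min_adjacent`` adjacent
    significant bins of one sign.  Zero-baseline bins are tested against a
    floor of ``baseline_floor`` counts.
    """
    baseline = baseline_hollowed_median(cch, baseline_window_ms, hollow_bins)
    dc = deconvolve_cch(cch, ach_ref, mode=deconv_mode)
    roi = cch.roi_slice(roi_ms)
    obs = np.asarray(dc.counts, float)[roi]
    lam = np.maximum(baseline[roi], baseline_floor)
    n_roi = obs.size

    p_hi = sps.poisson.sf(np.ceil(obs) - 1, lam)  # P(X >= obs)
    p_lo = sps.poisson.cdf(np.floor(obs), lam)    # P(X <= obs)
    thr = alpha / n_roi

    def _consistent(p):
        sig = p < thr
        return np.any(sig[:-1] & sig[1:]) if min_adjacent == 2 else _run(sig, min_adjacent)

    curve = transmission_curve(dc, baseline)
    if _consistent(p_hi):
        sign = EXC
        stg, bounds, lag = stg_from_curve(curve, cch.n_ref, cch.bin_ms, roi_ms, "positive")
        p = float(min(1.0, p_hi.min() * n_roi))
    elif _consistent(p_lo):
        sign = INH
        stg, bounds, lag = stg_from_curve(curve, cch.n_ref, cch.bin_ms, roi_ms, "negative")
        p = float(min(1.0, p_lo.min() * n_roi))
    else:
        sign = NONE
        stg, bounds, lag = stg_from_curve(curve, cch.n_ref, cch.bin_ms, roi_ms, "auto")
        p = float(min(1.0, min(p_hi.min(), p_lo.min()) * n_roi))
    return ConnectionResult(
        ref_id=cch.ref_id,
        tgt_id=cch.tgt_id,
        sign=sign,
        stg=stg,
        p_value=p,
        lag_ms=lag,
        roi=bounds,
        transmission=curve,
        baseline=baseline,
    )


def _run(sig: np.ndarray, k: int) -> bool:
    run = 0
    for s in sig:
        run = run + 1 if s else 0
        if run >= k:
            return True
    return False


def session_fractions(units, connections, alpha: float = 0.001):
    """Per-session vINT -> BIP pair counts, fractions, and a Binomial test.

    vINTs are INT units verified inhibitory by participating as a
    reference in at least one CCH with a consistent trough.  The exact
    one-tailed Binomial test compares the number of connected vINT->BIP
    pairs against the chance level ``alpha`` (the detection threshold
    expressed as a probability).  Returns a dict; empty counts when the
    session has no vINT or no BIP.
    """
    import pandas as pd

    from . import waveforms as wf

    vints = {c.ref_id for c in connections if c.sign == INH}
    vints &= {u.unit_id for u in units if u.unit_type == wf.INT}
    bips = {u.unit_id for u in units if u.unit_type == wf.BIP}
    pairs = [(a, b) for a in vints for b in bips if a != b]
    by_pair = {(c.ref_id, c.tgt_id): c for c in connections}
    rows = []
    for a, b in pairs:
        c = by_pair.get((a, b))
        if c is not None and c.sign != NONE:
            rows.append({"ref": a, "tgt": b, "sign": c.sign, "lag_ms": c.lag_ms, "stg": c.stg})
    n_pairs = len(pairs)
    n_exc = sum(r["sign"] == EXC for r in rows)
    n_inh = sum(r["sign"] == INH for r in rows)
    n_conn = n_exc + n_inh
    p_binom = (
        sps.binomtest(n_conn, n_pairs, p=alpha, alternative="greater").pvalue
        if n_pairs
        else np.nan
    )
    return {
        "n_vint": len(vints),
        "n_bip": len(bips),
        "n_pairs": n_pairs,
        "n_excitatory": n_exc,
        "n_inhibitory": n_inh,
        "frac_excitatory": n_exc / n_pairs if n_pairs else np.nan,
        "frac_inhibitory": n_inh / n_pairs if n_pairs else np.nan,
        "p_binomial": p_binom,
        "pairs": pd.DataFrame(rows, columns=["ref", "tgt", "sign", "lag_ms", "stg"]),
    }
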