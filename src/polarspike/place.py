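"""Linear-track place coding: rate maps, place fields, and phase precession.

Runs on a linear track (150 cm, 2.5 cm bins by default) are split by
direction into trials; trials with mean running speed below 10 cm/s are
excluded.  Units must be *active* (>= 5 spikes in some spatial bin,
pooled over trials) and *stable* (rank-correlated trial-pair rate maps,
judged by the geometric mean of per-pair circular-shift permutation
p-values) before place fields are sought.  Fields are detected
recursively against a Poisson chance level, and fields with fewer than
30 spikes are dropped.  Within a field, theta phase precession is
quantified by a circular-linear regression (slope in cycles/cm) whose
goodness is the mean resultant length of the slope-corrected phases; the
effect size normalizes that goodness by the median of 300 fits to
permuted phase-position pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as sps

from .circstats import circ_mean_resultant

TRACK_LEN_CM = 150.0
BIN_CM = 2.5


@dataclass
class RateMap:
    """Per-trial spatial firing-rate map for one running direction."""

    rates: np.ndarray        # trials x bins, Hz
    counts: np.ndarray       # trials x bins, spikes
    occupancy: np.ndarray    # trials x bins, s
    direction: int
    bin_cm: float = BIN_CM
    unit_id: int = -1

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def pooled_occupancy(self) -> np.ndarray:
        return self.occupancy.sum(axis=0)

    @property
    def pooled_rate(self) -> np.ndarray:
        occ = self.pooled_occupancy
        return np.divide(self.pooled_counts, occ, out=np.zeros(self.n_bins), where=occ > 0)


@dataclass
class PlaceField:
    direction: int
    bin_start: int
    bin_end: int            # exclusive
    n_spikes: int
    bin_cm: float = BIN_CM
    gain: float = float("nan")
    gain_capped: bool = False
    slope: float | None = None          # cycles/cm
    onset_phase: float | None = None    # rad
    goodness: float | None = None
    effect_size: float | None = None
    significant: bool = False           # permutation criterion alone
    precessing: bool = False            # significant AND negative slope

    @property
    def start_cm(self) -> float:
        return self.bin_start * self.bin_cm

    @property
    def end_cm(self) -> float:
        return self.bin_end * self.bin_cm

    @property
    def size_cm(self) -> float:
        return (self.bin_end - self.bin_start) * self.bin_cm


def segment_trials(behavior) -> list[tuple[int, int, int]]:
    """Contiguous constant-direction runs of a behavior table.

    ``behavior`` needs columns t, x, direction, speed.  Returns a list of
    (start_row, stop_row, direction).
    """
    d = np.asarray(behavior["direction"], int)
    breaks = np.flatnonzero(np.diff(d) != 0)
    starts = np.r_[0, breaks + 1]
    stops = np.r_[breaks + 1, d.size]
    return [(int(a), int(b), int(d[a])) for a, b in zip(starts, stops)]


def rate_map(
    spike_times,
    behavior,
    direction: int,
    track_len: float = TRACK_LEN_CM,
    bin_cm: float = BIN_CM,
    speed_min: float = 10.0,
    unit_id: int = -1,
) -> RateMap:
    """Per-trial rate map for one direction; slow trials are excluded.

    Spike positions are interpolated from the behavior table.  A trial is
    excluded when its mean running speed is below ``speed_min`` cm/s.
    """
    t = np.asarray(behavior["t"], float)
    x = np.asarray(behavior["x"], float)
    speed = np.asarray(behavior["speed"], float)
    spikes = np.asarray(spike_times, float)
    n_bins = int(round(track_len / bin_cm))
    edges = np.linspace(0.0, track_len, n_bins + 1)
    dt = np.median(np.diff(t)) if t.size > 1 else 0.0

    counts_rows, occ_rows = [], []
    for a, b, d in segment_trials(behavior):
        if d != direction or b - a < 2:
            continue
        if np.mean(speed[a:b]) < speed_min:
            continue
        occ = np.histogram(x[a:b], bins=edges)[0] * dt
        in_trial = (spikes >= t[a]) & (spikes <= t[b - 1])
        sx = np.interp(spikes[in_trial], t[a:b], x[a:b])
        cnt = np.histogram(sx, bins=edges)[0]
        counts_rows.append(cnt)
        occ_rows.append(occ)
    if not counts_rows:
        import warnings

        warnings.warn("no valid trials for this direction")
        counts = np.zeros((0, n_bins))
        occ = np.zeros((0, n_bins))
    else:
        counts = np.asarray(counts_rows, float)
        occ = np.asarray(occ_rows, float)
    rates = np.divide(counts, occ, out=np.zeros_like(counts), where=occ > 0)
    return RateMap(rates=rates, counts=counts, occupancy=occ, direction=direction,
                   bin_cm=bin_cm, unit_id=unit_id)


def _pair_shift_pvalues(rates: np.ndarray, n_shuffle: int, rng) -> list[float]:
    """Permutation p for the Spearman cc of every trial pair.

    The null circularly shifts one trial's map (preserving its spatial
    autocorrelation); circular shifts of a vector shift its ranks, so all
    shift correlations come from one circular cross-correlation.
    """
    n_trials, n_bins = rates.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, rates)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    ps = []
    fft = np.fft.rfft(centered, axis=1)
    for i in range(n_trials):
        for j in range(i + 1, n_trials):
            if norms[i] == 0 or norms[j] == 0:
                continue  # constant map: correlation undefined
            # cc at every circular shift s of trial j
            cc_all = np.fft.irfft(fft[i] * np.conj(fft[j]), n=n_bins) / (norms[i] * norms[j])
            obs = cc_all[0]
            shifts = rng.integers(1, n_bins, size=n_shuffle)
            null = cc_all[shifts]
            ps.append(float((1 + np.sum(null >= obs)) / (n_shuffle + 1)))
    return ps


def filter_active_stable(
    maps: list[RateMap],
    n_shuffle: int = 200,
    seed: int = 0,
    min_bin_spikes: int = 5,
    alpha: float = 0.05,
) -> tuple[bool, bool, float]:
    """Active/stable screening of a unit from its per-direction rate maps.

    Active: some spatial bin holds >= ``min_bin_spikes`` spikes pooled
    over trials (any direction).  Stable: the geometric mean of trial-pair
    permutation p-values (circular-shift null, both directions) is below
    ``alpha``.  Returns (active, stable, combined_p).
    """
    active = any(m.n_trials > 0 and m.pooled_counts.max() >= min_bin_spikes for m in maps)
    rng = np.random.default_rng(seed)
    ps: list[float] = []
    for m in maps:
        if m.n_trials >= 2:
            ps.extend(_pair_shift_pvalues(m.rates, n_shuffle, rng))
    if not ps:
        return active, False, float("nan")
    combined = float(np.exp(np.mean(np.log(ps))))
    return active, combined < alpha, combined


def detect_fields(
    m: RateMap,
    alpha: float = 0.05,
    min_spikes: int = 30,
) -> list[PlaceField]:
    """Recursive Poisson place-field detection on the pooled rate map.

    Repeatedly: (1) the chance rate is the pooled rate over bins outside
    already-accepted fields; (2) a field seeds at the most significant bin
    whose pooled count exceeds the Poisson upper tail at
    Bonferroni-corrected ``alpha`` given chance_rate x occupancy; (3) the
    field extends over contiguous bins whose rate exceeds the chance
    rate; (4) the field is removed and the search repeats.  Fields with
    fewer than ``min_spikes`` spikes are discarded at the end.
    """
    counts = m.pooled_counts.astype(float)
    occ = m.pooled_occupancy
    n_bins = m.n_bins
    in_field = np.zeros(n_bins, dtype=bool)
    rate = np.divide(counts, occ, out=np.zeros(n_bins), where=occ > 0)
    fields: list[PlaceField] = []
    for _ in range(n_bins):
        out_mask = ~in_field & (occ > 0)
        if not np.any(out_mask) or occ[out_mask].sum() <= 0:
            break
        baseline = counts[out_mask].sum() / occ[out_mask].sum()
        lam = baseline * occ
        with np.errstate(divide="ignore"):
            p = np.where(out_mask, sps.poisson.sf(counts - 1, np.maximum(lam, 1e-12)), 1.0)
        thr = alpha / n_bins
        if p.min() >= thr:
            break
        seed_bin = int(np.argmin(p))
        lo = seed_bin
        while lo > 0 and not in_field[lo - 1] and rate[lo - 1] > baseline:
            lo -= 1
        hi = seed_bin
        while hi < n_bins - 1 and not in_field[hi + 1] and rate[hi + 1] > baseline:
            hi += 1
        in_field[lo : hi + 1] = True
        fields.append(
            PlaceField(
                direction=m.direction,
                bin_start=lo,
                bin_end=hi + 1,
                n_spikes=int(counts[lo : hi + 1].sum()),
                bin_cm=m.bin_cm,
            )
        )
    return [f for f in fields if f.n_spikes >= min_spikes]


def field_centroid(m: RateMap, f: PlaceField) -> float:
    """Rate-weighted centre of mass of a detected field, cm."""
    rate = m.pooled_rate[f.bin_start : f.bin_end]
    centers = (np.arange(f.bin_start, f.bin_end) + 0.5) * f.bin_cm
    return float((rate * centers).sum() / rate.sum())


def spatial_info(m: RateMap) -> float:
    """Skaggs spatial information rate, bits/s.

    I = sum_i p_i * lambda_i * log2(lambda_i / lambda_bar) with p_i the
    occupancy probability of bin i; 0 for flat or silent maps.
    """
    occ = m.pooled_occupancy
    if occ.sum() <= 0:
        raise ValueError("no occupancy")
    p = occ / occ.sum()
    lam = m.pooled_rate
    lbar = float((p * lam).sum())
    if lbar <= 0:
        return 0.0
    pos = lam > 0
    return float(np.sum(p[pos] * lam[pos] * np.log2(lam[pos] / lbar)))


def in_field_gain(m: RateMap, f: PlaceField, cap: float = 1e6) -> PlaceField:
    """Mean in-field rate over mean out-of-field rate (occupancy-weighted)."""
    occ = m.pooled_occupancy
    counts = m.pooled_counts
    sel = np.zeros(m.n_bins, dtype=bool)
    sel[f.bin_start : f.bin_end] = True
    occ_in, occ_out = occ[sel].sum(), occ[~sel].sum()
    if occ_in <= 0:
        f.gain = float("nan")
        return f
    rate_in = counts[sel].sum() / occ_in
    rate_out = counts[~sel].sum() / occ_out if occ_out > 0 else 0.0
    if rate_out <= 0:
        f.gain, f.gain_capped = cap, True
    else:
        f.gain = float(rate_in / rate_out)
    return f


def theta_phase(lfp, fs: float, band: tuple[float, float] = (5.0, 11.0)) -> np.ndarray:
    """Instantaneous theta phase of an LFP trace, 0 at the theta peak."""
    from .ripples import dog_bandpass, instantaneous_phase

    return instantaneous_phase(dog_bandpass(lfp, fs, band))


def _resultant_grid(positions: np.ndarray, phases: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    """|mean exp(i(phase - 2*pi*a*x))| for every candidate slope a."""
    z = np.exp(1j * phases)
    w = np.exp(-2j * np.pi * np.outer(positions, slopes))
    return np.abs(z @ w) / positions.size


def precession_fit(
    positions,
    phases,
    slope_bounds: tuple[float, float] = (-0.1, 0.1),
    grid_step: float = 1e-3,
    field_start: float | None = None,
) -> tuple[float, float, float]:
    """Circular-linear regression of spike theta phase on position.

    Maximizes the mean resultant length of (phase - 2*pi*slope*position)
    over a bounded slope grid, then refines around the grid optimum.
    Returns (slope cycles/cm, onset phase at the field start, goodness =
    resultant length at the optimum).
    """
    x = np.asarray(positions, float)
    ph = np.asarray(phases, float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("degenerate positions")
    slopes = np.arange(slope_bounds[0], slope_bounds[1] + grid_step / 2, grid_step)
    r = _resultant_grid(x, ph, slopes)
    i = int(np.argmax(r))
    lo = slopes[max(0, i - 1)]
    hi = slopes[min(slopes.size - 1, i + 1)]
    res = optimize.minimize_scalar(
        lambda a: -np.abs(np.exp(1j * (ph - 2 * np.pi * a * x)).mean()),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    slope = float(res.x)
    goodness = float(-res.fun)
    x0 = float(field_start) if field_start is not None else float(x.min())
    onset, _ = circ_mean_resultant(ph - 2 * np.pi * slope * (x - x0))
    return slope, onset, goodness


def precession_effect_size(
    positions,
    phases,
    n_perm: int = 300,
    seed: int = 0,
    alpha: float = 0.05,
    slope_bounds: tuple[float, float] = (-0.1, 0.1),
    grid_step: float = 1e-3,
    field_start: float | None = None,
) -> PlaceField | dict:
    """Precession fit plus permutation-normalized effect size.

    Effect size = observed goodness / median goodness of ``n_perm`` fits
    to randomly permuted phase-position pairings.  ``significant`` flags
    goodness above the permutation 95th percentile; ``precessing``
    additionally requires a negative slope.  Returns a dict with keys
    slope, onset, goodness, effect_size, significant, precessing.
    """
    x = np.asarray(positions, float)
    ph = np.asarray(phases, float)
    slope, onset, goodness = precession_fit(x, ph, slope_bounds, grid_step, field_start)
    rng = np.random.default_rng(seed)
    slopes = np.arange(slope_bounds[0], slope_bounds[1] + grid_step / 2, grid_step)
    w = np.exp(-2j * np.pi * np.outer(x, slopes))
    perm_good = np.empty(n_perm)
    z = np.exp(1j * ph)
    for k in range(n_perm):
        perm_good[k] = np.abs(rng.permutation(z) @ w).max() / x.size
    effect = float(goodness / np.median(perm_good))
    significant = bool(goodness > np.quantile(perm_good, 1 - alpha))
    return {
        "slope": slope,
        "onset": onset,
        "goodness": goodness,
        "effect_size": effect,
        "significant": significant,
        "precessing": significant and slope < 0,
    }


def analyze_field_precession(m: RateMap, f: PlaceField, spike_positions, spike_phases,
                             n_perm: int = 300, seed: int = 0) -> PlaceField:
    """Attach precession statistics to a place field from its in-field spikes."""
    x = np.asarray(spike_positions, float)
    ph = np.asarray(spike_phases, float)
    sel = (x >= f.start_cm) & (x < f.end_cm)
    if sel.sum() < 30:
        return f
    out = precession_effect_size(x[sel], ph[sel], n_perm=n_perm, seed=seed,
                                 field_start=f.start_cm)
    f.slope = out["slope"]
    f.onset_phase = out["onset"]
    f.goodness = out["goodness"]
    f.effect_size = out["effect_size"]
    f.significant = out["significant"]
    f.precessing = out["precessing"]
    return f
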