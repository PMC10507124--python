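"""Mean-waveform categorization and unit classification.

Extracellular mean spike waveforms recorded on a single electrode are
categorized by polarity into N-spikes (dominant negative trough), P-spikes
(dominant positive peak), B-spikes (biphasic: positive peak followed by a
negative trough), or left uncategorized.  The categorization is driven by
the biphasic index

    BPI = (p - |n|) / (p + |n|)

where ``p`` is the largest local maximum and ``n`` the smallest local
minimum of the baseline-corrected, 4x-upsampled mean waveform.  BPI is -1
for a pure N-spike, +1 for a pure P-spike and 0 for a symmetric B-spike.

Units (spike-sorted clusters observed on several electrodes of one shank)
are then classified by the category of their largest-magnitude electrode
(the main channel) into N-units, Punits, or BIPs, and as single-modal (SM,
all categorized electrodes agree) or multi-modal (MM).  N-units are further
split into putative pyramidal cells (PYR) and narrow-waveform interneurons
(INT) with a two-component Gaussian mixture on waveform features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

N_SAMPLES = 32
UPSAMPLE = 4
N_UPSAMPLED = N_SAMPLES * UPSAMPLE
FS = 20000.0
FS_UP = FS * UPSAMPLE
BASELINE_SAMPLES = 3  # first 0.15 ms at 20 kHz

#: labels a single-electrode waveform can receive
N, P, B, UNCATEGORIZED = "N", "P", "B", "uncategorized"
CATEGORIZED_LABELS = (N, P, B)


class NoExtremaError(ValueError):
    """Raised when a waveform has no usable local extrema (constant input)."""


class UndefinedBPIError(ValueError):
    """Raised when p + |n| = 0 so the biphasic index is undefined."""


@dataclass(frozen=True)
class MeanWaveform:
    """Per-sample mean and SD of one unit's spikes on one electrode (uV)."""

    mean: np.ndarray
    sd: np.ndarray
    fs: float = FS
    n_spikes: int = 1
    channel: int = 0

    def __post_init__(self):
        m, s = np.asarray(self.mean, float), np.asarray(self.sd, float)
        if m.shape != s.shape:
            raise ValueError("mean and sd must have equal length")
        if np.any(s < 0):
            raise ValueError("sd must be non-negative")
        if self.n_spikes < 1:
            raise ValueError("n_spikes must be >= 1")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "sd", s)

    @property
    def magnitude(self) -> float:
        """Trough-to-peak magnitude, max(mean) - min(mean), uV."""
        return float(self.mean.max() - self.mean.min())


@dataclass(frozen=True)
class UpsampledWaveform:
    """Baseline-corrected waveform upsampled 4x by cubic spline (128 samples)."""

    mean128: np.ndarray
    sd128: np.ndarray
    fs: float = FS_UP


@dataclass(frozen=True)
class ExtremaResult:
    """Extreme local extrema of an upsampled waveform.

    ``p``/``t_p`` are the value and sample index of the largest local
    maximum; ``n``/``t_n`` of the smallest local minimum.  Endpoint samples
    are eligible extrema, so ``p`` and ``n`` coincide with the global
    max/min of the vector.
    """

    p: float
    t_p: int
    n: float
    t_n: int


@dataclass(frozen=True)
class WaveformCategory:
    label: str
    bpi: float | None


@dataclass(frozen=True)
class CategoryThresholds:
    """SD multipliers and BPI bounds for the category decision rules.

    ``default``: B requires a peak before the trough, peak > 1.25 SD at the
    peak, |trough| > 1 SD at the trough and -0.6 < BPI < 0.8; P and N
    require 1.75 SD at their defining extremum.  ``alternate``: symmetric
    B rule (1 SD / 1 SD) and 2 SD for P and N.
    """

    b_peak_sd: float = 1.25
    b_trough_sd: float = 1.0
    bpi_low: float = -0.6
    bpi_high: float = 0.8
    pn_sd: float = 1.75

    @classmethod
    def preset(cls, name: str) -> "CategoryThresholds":
        if name == "default":
            return cls()
        if name == "alternate":
            return cls(b_peak_sd=1.0, b_trough_sd=1.0, pn_sd=2.0)
        raise ValueError(f"unknown preset {name!r}")


def summarize_waveforms(snippets: np.ndarray, fs: float = FS, channel: int = 0) -> MeanWaveform:
    """Average spike snippets (spikes x samples, uV) into a MeanWaveform.

    SD is the per-sample population SD over spikes (0 for a single spike).
    """
    snippets = np.asarray(snippets, float)
    if snippets.ndim == 1:
        snippets = snippets[None, :]
    if snippets.size == 0 or snippets.shape[0] < 1:
        raise ValueError("need at least one spike")
    mean = snippets.mean(axis=0)
    sd = snippets.std(axis=0) if snippets.shape[0] > 1 else np.zeros_like(mean)
    return MeanWaveform(mean=mean, sd=sd, fs=fs, n_spikes=snippets.shape[0], channel=channel)


def preprocess_waveform(w: MeanWaveform) -> UpsampledWaveform:
    """Baseline-subtract and 4x cubic-spline upsample mean and SD.

    The mean of the first 3 samples (0.15 ms) is subtracted from the mean
    waveform; both vectors are then upsampled four-fold in time with a
    cubic spline, yielding two 128-sample vectors at 80 kHz effective rate.
    Spline undershoot of the (non-negative) SD vector is clipped at zero.
    """
    if w.mean.size < BASELINE_SAMPLES:
        raise ValueError("waveform too short for baseline estimation")
    x = np.arange(w.mean.size)
    xi = np.arange(w.mean.size * UPSAMPLE) / UPSAMPLE
    detrended = w.mean - w.mean[:BASELINE_SAMPLES].mean()
    mean128 = CubicSpline(x, detrended)(xi)
    sd128 = np.clip(CubicSpline(x, w.sd)(xi), 0.0, None)
    return UpsampledWaveform(mean128=mean128, sd128=sd128, fs=w.fs * UPSAMPLE)


def find_extrema(u: UpsampledWaveform) -> ExtremaResult:
    """Locate the largest local maximum and smallest local minimum.

    Endpoints count as local extrema, so the selected peak and trough are
    the global extrema of the vector; indices are first occurrences.
    Raises :class:`NoExtremaError` on a constant vector.
    """
    v = np.asarray(u.mean128, float)
    if v.size < 2 or np.all(v == v[0]):
        raise NoExtremaError("constant waveform has no extrema")
    t_p = int(np.argmax(v))
    t_n = int(np.argmin(v))
    return ExtremaResult(p=float(v[t_p]), t_p=t_p, n=float(v[t_n]), t_n=t_n)


def compute_bpi(e: ExtremaResult) -> float:
    """Biphasic index (p - |n|)/(p + |n|), clamped to [-1, 1].

    The clamp only acts in the degenerate case where all local extrema
    share one sign (then the raw ratio can exceed the unit interval by a
    sliver); for any waveform with p >= 0 >= n the formula is already
    bounded.
    """
    denom = e.p + abs(e.n)
    if denom <= 0:
        raise UndefinedBPIError("p + |n| = 0: biphasic index undefined")
    return float(np.clip((e.p - abs(e.n)) / denom, -1.0, 1.0))


def categorize_waveform(
    u: UpsampledWaveform,
    thresholds: CategoryThresholds | None = None,
) -> WaveformCategory:
    """Assign exactly one of N / P / B / uncategorized to a waveform.

    Decision order (first match wins):

    1. B-spike: the peak precedes the trough, p exceeds ``b_peak_sd`` SDs at
       the peak sample, |n| exceeds ``b_trough_sd`` SDs at the trough
       sample, and BPI lies strictly inside (bpi_low, bpi_high).
    2. P-spike: p > |n| and p exceeds ``pn_sd`` SDs at the peak.
    3. N-spike: |n| > p and |n| exceeds ``pn_sd`` SDs at the trough.
    4. Otherwise uncategorized.

    With an all-zero SD vector the SD comparisons are vacuously true for
    any strictly positive deflection (``x > 0``), so noiseless waveforms
    are categorized by shape alone.
    """
    th = thresholds or CategoryThresholds()
    if np.allclose(u.mean128, 0.0):
        return WaveformCategory(label=UNCATEGORIZED, bpi=None)
    try:
        e = find_extrema(u)
        bpi = compute_bpi(e)
    except (NoExtremaError, UndefinedBPIError):
        return WaveformCategory(label=UNCATEGORIZED, bpi=None)
    sd_p = u.sd128[e.t_p]
    sd_n = u.sd128[e.t_n]
    an = abs(e.n)
    if (
        e.t_p < e.t_n
        and e.p > th.b_peak_sd * sd_p
        and an > th.b_trough_sd * sd_n
        and th.bpi_low < bpi < th.bpi_high
    ):
        return WaveformCategory(label=B, bpi=bpi)
    if e.p > an and e.p > th.pn_sd * sd_p:
        return WaveformCategory(label=P, bpi=bpi)
    if an > e.p and an > th.pn_sd * sd_n:
        return WaveformCategory(label=N, bpi=bpi)
    return WaveformCategory(label=UNCATEGORIZED, bpi=bpi)


# ------------------------------------------------------------------ units

SM, MM = "SM", "MM"
PYR, INT, PUNIT, BIP, NUNIT, UNCLASSIFIED = "PYR", "INT", "Punit", "BIP", "N-unit", "unclassified"


@dataclass
class Unit:
    """A sorted unit: spike times plus per-electrode mean waveforms.

    ``waveforms`` and ``categories`` are keyed by channel id.  ``unit_type``
    starts from the main-channel category (N-unit / Punit / BIP) and is
    refined to PYR or INT for N-units by :func:`classify_celltype`.
    """

    unit_id: int
    shank: int
    spike_times: np.ndarray
    waveforms: dict[int, MeanWaveform]
    categories: dict[int, WaveformCategory] = field(default_factory=dict)
    main_channel: int | None = None
    modality: str | None = None
    unit_type: str = UNCLASSIFIED

    @property
    def n_spikes(self) -> int:
        return int(np.asarray(self.spike_times).size)

    def categorized_channels(self, label: str | None = None) -> list[int]:
        out = []
        for ch, cat in self.categories.items():
            if cat.label in CATEGORIZED_LABELS and (label is None or cat.label == label):
                out.append(ch)
        return out


def categorize_unit_waveforms(
    unit: Unit, thresholds: CategoryThresholds | None = None
) -> dict[int, WaveformCategory]:
    """Categorize every electrode waveform of a unit (stored on the unit)."""
    unit.categories = {
        ch: categorize_waveform(preprocess_waveform(w), thresholds)
        for ch, w in unit.waveforms.items()
    }
    return unit.categories


def classify_unit(unit: Unit) -> Unit:
    """Set main channel, SM/MM modality, and waveform-based unit type.

    The main channel maximizes trough-to-peak magnitude of the mean
    waveform (ties broken by lowest channel id).  Unit type follows the
    main-channel category: B -> BIP, P -> Punit, N -> N-unit, otherwise
    unclassified.  The unit is SM iff all categorized electrodes share one
    label; units with no categorized electrode are unclassified.
    """
    if not unit.waveforms:
        raise ValueError("unit has no waveforms")
    if not unit.categories:
        categorize_unit_waveforms(unit)
    channels = sorted(unit.waveforms)
    mags = np.array([unit.waveforms[ch].magnitude for ch in channels])
    unit.main_channel = channels[int(np.argmax(mags))]

    labels = {unit.categories[ch].label for ch in unit.categorized_channels()}
    unit.modality = SM if len(labels) <= 1 else MM

    main_label = unit.categories.get(unit.main_channel, WaveformCategory(UNCATEGORIZED, None)).label
    if not labels:
        unit.unit_type = UNCLASSIFIED
    elif main_label == B:
        unit.unit_type = BIP
    elif main_label == P:
        unit.unit_type = PUNIT
    elif main_label == N:
        unit.unit_type = NUNIT
    else:
        unit.unit_type = UNCLASSIFIED
    return unit


def trough_to_peak_ms(u: UpsampledWaveform) -> float:
    """Time from the global trough to the subsequent maximum, ms."""
    v = u.mean128
    t_n = int(np.argmin(v))
    after = v[t_n:]
    t_p = t_n + int(np.argmax(after))
    return (t_p - t_n) / u.fs * 1e3


def spike_width(u: UpsampledWaveform, pad_to: int = 16384, band: tuple[float, float] = (100.0, 3000.0)) -> float:
    """Spike width as the inverse of the waveform's dominant frequency, ms.

    The 128-sample mean is zero-padded to ``pad_to`` samples (<= 5 Hz grid
    at 80 kHz) and the magnitude-spectrum argmax inside ``band`` (DC
    excluded by construction) defines the dominant frequency.
    """
    v = np.asarray(u.mean128, float)
    if np.allclose(v, 0):
        raise ValueError("spike width undefined for an all-zero waveform")
    spec = np.abs(np.fft.rfft(v, n=pad_to))
    freqs = np.fft.rfftfreq(pad_to, d=1.0 / u.fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    f_dom = freqs[in_band][int(np.argmax(spec[in_band]))]
    return 1e3 / f_dom


def spatial_span(unit: Unit, probe) -> float:
    """Longest vertically contiguous run of categorized electrodes x spacing, um.

    A single categorized electrode counts as one spacing.
    """
    cat = set(unit.categorized_channels())
    if not cat:
        return 0.0
    ladder = probe.channels_on_shank(unit.shank)
    best = run = 0
    for ch in ladder:
        run = run + 1 if ch in cat else 0
        best = max(best, run)
    return best * probe.vertical_spacing


def classify_celltype(
    units: list[Unit],
    features: np.ndarray | None = None,
    model=None,
    random_state: int = 0,
    width_threshold_ms: float = 0.4,
):
    """Split N-units into putative PYR and INT with a 2-component GMM.

    Default features are the main-channel trough-to-peak time and spike
    width (both ms); the mixture component with the narrower mean waveform
    is labeled INT.  Non-negative units (Punits, BIPs) are left untouched.
    Returns ``(labels, posteriors)`` aligned with the N-unit subset; with
    fewer than 2 N-units everything stays unclassified, and if the two
    fitted components are not separated the units are split by a
    trough-to-peak threshold instead (with a warning).
    """
    n_units = [u for u in units if u.unit_type in (NUNIT, PYR, INT)]
    if len(n_units) < 2:
        return {}, {}
    if features is None:
        feats = []
        for u in n_units:
            up = preprocess_waveform(u.waveforms[u.main_channel])
            feats.append([trough_to_peak_ms(up), spike_width(up)])
        features = np.asarray(feats)
    features = np.asarray(features, float)

    if model is None:
        from sklearn.mixture import GaussianMixture

        model = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    model.fit(features)
    post = model.predict_proba(features)
    comp = np.argmax(post, axis=1)
    means = model.means_
    # separation check on trough-to-peak: components closer than the pooled SD
    # indicate a single cluster
    sds = np.sqrt([np.atleast_2d(c)[0, 0] for c in getattr(model, "covariances_", np.ones((2, 1, 1)))])
    sep = abs(means[0, 0] - means[1, 0])
    if sep < 0.5 * float(np.mean(sds)):
        warnings.warn("cell-type mixture components overlap; falling back to width threshold")
        comp = (features[:, 0] >= width_threshold_ms).astype(int)  # 0 = narrow
        narrow_comp = 0
        post = np.stack([1.0 - comp, comp * 1.0], axis=1)
        int_comp = narrow_comp
    else:
        int_comp = int(np.argmin(means[:, 0]))

    labels, posteriors = {}, {}
    for u, c, pr in zip(n_units, comp, post):
        u.unit_type = INT if c == int_comp else PYR
        labels[u.unit_id] = u.unit_type
        posteriors[u.unit_id] = float(pr[int_comp])
    return labels, posteriors
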