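# polarspike

Analysis of **non-negative extracellular spike waveforms** and their
physiology, for electrophysiologists working with high-density silicon-probe
recordings (Klusta-style spike-sorted sessions at 20 kHz).

Extracellular action potentials near a soma appear as negative spikes
(N-spikes), but the same unit can project positive (P) or biphasic (B)
waveforms onto neighbouring electrodes — signatures of dendritic return
currents and axonal potentials.  `polarspike` implements the full
computational chain to find and interpret them:

1. **Waveform categorization** — each per-electrode mean waveform is
   baseline-corrected (mean of the first 0.15 ms), upsampled 4× by cubic
   spline to 128 samples, and scored by the biphasic index over its extreme
   local maximum *p* and minimum *n*:

   BPI = (p − |n|) / (p + |n|)

   BPI is −1 for a pure N-spike, +1 for a pure P-spike, 0 for a symmetric
   B-spike.  Waveforms are labelled B (peak before trough, peak > 1.25 SD,
   |trough| > 1 SD, −0.6 < BPI < 0.8), else P or N (extremum > 1.75 SD), else
   left uncategorized; an alternate symmetric preset (1/1 and 2/2 SD) is
   built in.
2. **Unit classification** — main channel (maximal trough-to-peak
   magnitude), single-modal vs multi-modal (SM/MM), unit type
   (N-unit/Punit/BIP), and PYR/INT cell typing of N-units by a pluggable
   two-component Gaussian mixture on waveform features.
3. **Extremum timing** — same-unit N-trough → P-peak / B-trough / B-peak
   lags on the 12.5 µs upsampled grid, signed vertical electrode distances
   (positive = toward the brain surface), order-statistic median CIs,
   Wilcoxon tests, and Spearman permutation correlations.
4. **Monosynaptic connectivity** — 0.1 ms count CCHs, hollowed-median
   baseline, regularized deconvolution by the reference ACH, Bonferroni
   Poisson detection in the causal 0–5 ms window, and **spike transmission
   gain** (STG): postsynaptic spikes added per presynaptic spike, the area
   under the transmission curve extended to its causal zero crossings.
5. **Ripples** — 80–250 Hz difference-of-Gaussians zero-lag band-pass,
   clipped power envelope, 5 SD detection / 2 SD edges, pyramidal-layer
   centre by ripple amplitude, per-unit rate gain (Poisson test) and phase
   locking (resultant length R, Rayleigh test).
6. **Place coding** — 2.5 cm rate maps on a 150 cm track, active/stable
   screening, recursive Poisson place-field detection, Skaggs spatial
   information, in-field gain, and circular–linear theta phase precession
   with a 300-permutation effect size.
7. **Synthetic data** (`polarspike.synth`) — analytic Gaussian-lobe waveform
   templates, coupled Poisson spike trains, noisy snippet recordings, LFP
   with embedded ripples, and linear-track sessions, all with exact
   machine-readable ground truth, so every stage is testable without
   external recordings.

## Worked example

```python
import numpy as np
from polarspike import make_probe, synth, waveforms as wf

probe = make_probe(2, 10, 20.0)                      # 2 shanks x 10 sites
tset = synth.synth_unit_templates(probe, 12, seed=42)
trains, _ = synth.synth_spike_trains(12, 5.0, 120.0, seed=43)
rows = {g.unit_id: np.array([probe._index(c) for c in probe.channels_on_shank(g.shank)])
        for g in tset.ground_truth}
snips = synth.synth_recording(tset.templates, trains, 5.0, seed=44, channels=rows)

for g in tset.ground_truth[:6]:
    chans = probe.channels_on_shank(g.shank)
    u = wf.Unit(unit_id=g.unit_id, shank=g.shank, spike_times=trains[g.unit_id],
                waveforms={ch: wf.summarize_waveforms(snips[g.unit_id][:, i, :], channel=ch)
                           for i, ch in enumerate(chans)})
    wf.classify_unit(u)
    up = wf.preprocess_waveform(u.waveforms[u.main_channel])
    cat = u.categories[u.main_channel]
    print(f"unit {u.unit_id}: {u.modality} {u.unit_type:7s} main ch {u.main_channel:2d} "
          f"BPI {cat.bpi:+.2f}  width {wf.spike_width(up):.2f} ms  "
          f"span {wf.spatial_span(u, probe):.0f} um   (truth: {g.archetype})")
```

prints

```
unit 0: MM N-unit  main ch 15 BPI -0.61  width 0.67 ms  span 20 um   (truth: MM-P)
unit 1: SM Punit   main ch 12 BPI +0.62  width 0.68 ms  span 60 um   (truth: SM-P)
unit 2: MM N-unit  main ch 16 BPI -0.61  width 0.74 ms  span 20 um   (truth: MM-B)
unit 3: SM BIP     main ch 12 BPI -0.06  width 0.54 ms  span 60 um   (truth: SM-B)
unit 4: SM N-unit  main ch  3 BPI -0.61  width 0.49 ms  span 60 um   (truth: SM-N)
unit 5: MM N-unit  main ch  2 BPI -0.62  width 0.54 ms  span 20 um   (truth: MM-B)
```

Each unit's main channel carries the expected polarity: N-units score BPI
near the negative end, the Punit near the positive end, the BIP near zero,
and MM units (an N-spike plus a non-negative waveform on another electrode)
are flagged multi-modal.  The spatial span is the length of the contiguous
categorized-electrode run times the 20 µm site spacing.

A shell workflow is available through the CLI:

```bash
polarspike simulate --out ses --seed 3 --n-units 8 --duration 120
polarspike classify --session ses --out units.tsv
polarspike timing --session ses --out lags.tsv
polarspike connectivity --session ses --out conn/
```

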