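"""Poisson spike trains with refractoriness and injected monosynaptic coupling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Coupling:
    """Monosynaptic coupling spec between two train indices.

    Excitatory: each presynaptic spike independently adds a postsynaptic
    spike at ``lag_ms`` (+ Gaussian jitter) with probability ``probability``.
    Inhibitory: each presynaptic spike independently deletes, with that
    probability, all postsynaptic spikes in the window
    (lag, lag + ``inh_window_ms``] after it.
    """

    pre: int
    post: int
    probability: float
    lag_ms: float = 1.0
    jitter_ms: float = 0.2
    sign: str = "excitatory"
    inh_window_ms: float = 3.0


@dataclass
class TrainsGroundTruth:
    couplings: list[Coupling]
    n_added: dict[int, int] = field(default_factory=dict)    # coupling index -> spikes added
    n_deleted: dict[int, int] = field(default_factory=dict)  # coupling index -> spikes deleted
    n_pre: dict[int, int] = field(default_factory=dict)      # coupling index -> presyn spikes


def _poisson_refractory(rate: float, duration: float, refractory_ms: float, rng) -> np.ndarray:
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    if refractory_ms <= 0 or t.size == 0:
        return t
    refr = refractory_ms * 1e-3
    keep = np.ones(t.size, dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t):
        if ti - last < refr:
            keep[i] = False
        else:
            last = ti
    return t[keep]


def synth_spike_trains(
    n_units: int,
    rates,
    duration: float,
    refractory_ms: float = 2.0,
    couplings: list[Coupling] = (),
    seed: int = 0,
) -> tuple[list[np.ndarray], TrainsGroundTruth]:
    """Homogeneous Poisson trains (thinned by a refractory period) with coupling.

    ``rates`` is a scalar or per-unit sequence in Hz.  Excitatory
    couplings add, inhibitory couplings delete, postsynaptic spikes as
    described on :class:`Coupling`; the realized added/deleted counts are
    recorded in the ground truth for calibration tests.  Fully
    reproducible under ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rates = np.broadcast_to(np.asarray(rates, float), (n_units,))
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    for c in couplings:
        if not 0.0 <= c.probability <= 1.0:
            raise ValueError("coupling probability must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_units + len(couplings))
    trains = [
        _poisson_refractory(rates[i], duration, refractory_ms, np.random.default_rng(child[i]))
        for i in range(n_units)
    ]
    gt = TrainsGroundTruth(couplings=list(couplings))
    for k, c in enumerate(couplings):
        rng = np.random.default_rng(child[n_units + k])
        pre = trains[c.pre]
        gt.n_pre[k] = pre.size
        if c.sign == "excitatory":
            hit = rng.random(pre.size) < c.probability
            added = pre[hit] + c.lag_ms * 1e-3
            if c.jitter_ms > 0:
                added = added + rng.normal(0.0, c.jitter_ms * 1e-3, size=added.size)
            added = added[(added >= 0) & (added < duration)]
            gt.n_added[k] = added.size
            trains[c.post] = np.sort(np.concatenate([trains[c.post], added]))
        elif c.sign == "inhibitory":
            hit = pre[rng.random(pre.size) < c.probability]
            post = trains[c.post]
            lo = np.searchsorted(post, hit + c.lag_ms * 1e-3, side="right")
            hi = np.searchsorted(post, hit + (c.lag_ms + c.inh_window_ms) * 1e-3, side="right")
            kill = np.zeros(post.size, dtype=bool)
            for a, b in zip(lo, hi):
                kill[a:b] = True
            gt.n_deleted[k] = int(kill.sum())
            trains[c.post] = post[~kill]
        else:
            raise ValueError(f"unknown coupling sign {c.sign!r}")
    return trains, gt
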