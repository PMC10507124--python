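"""Snippet recordings: templates plus per-sample Gaussian noise."""

from __future__ import annotations

import numpy as np


def unit_snippets(template: np.ndarray, n_spikes: int, noise_sd: float, rng) -> np.ndarray:
    """Snippets (spikes x channels x samples, uV) for one unit.

    Each snippet is the noise-free template plus independent Gaussian
    noise of SD ``noise_sd`` uV per sample; the mean over spikes
    converges to the template, and the alignment sample keeps the
    template's detection extremum.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    template = np.atleast_2d(np.asarray(template, float))
    out = np.broadcast_to(template, (n_spikes,) + template.shape).copy()
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out


def synth_recording(
    templates: dict[int, np.ndarray],
    trains,
    noise_sd: float,
    seed: int = 0,
    channels: dict[int, np.ndarray] | None = None,
) -> dict[int, np.ndarray]:
    """Snippet arrays for every unit, one snippet per spike time.

    ``templates`` maps unit id to (channels x samples); ``trains`` maps
    unit id to spike times (or is a sequence indexed by unit id).
    ``channels`` optionally restricts each unit to a channel-row subset
    (e.g. its own shank) to bound memory.  Seeded per unit via
    ``SeedSequence`` spawning, so results do not depend on dict order.
    """
    ids = sorted(templates)
    ss = np.random.SeedSequence(seed)
    child = {uid: s for uid, s in zip(ids, ss.spawn(len(ids)))}
    out = {}
    for uid in ids:
        tpl = templates[uid]
        if channels is not None:
            tpl = tpl[channels[uid]]
        n = len(trains[uid])
        out[uid] = unit_snippets(tpl, n, noise_sd, np.random.default_rng(child[uid]))
    return out
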