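"""Session reading/writing in a Klusta-style on-disk dialect.

A session directory holds, per shank ``s``:

* ``<name>.res.<s>`` — plain-text spike times as integer sample indices
  at the acquisition rate (20 kHz), one per line, non-decreasing;
* ``<name>.clu.<s>`` — plain-text cluster labels, first line = number of
  clusters, then one label per spike;
* ``<name>.spk.<s>`` — flat binary int16 waveform snippets, C-ordered
  spikes x channels x samples, scaled by ``uv_per_bit``;

plus ``probe.json`` (channel -> shank, x, y in um; larger y is closer to
the brain surface), ``session.json`` (rates, geometry, file map),
optional ``lfp.dat`` + ``lfp.json`` (flat int16, channel-major frames),
optional ``behavior.tsv`` (t, x, direction, speed) and
``groundtruth.json`` (generator manifest).  Spike times are stored as
integer sample indices for exactness and converted to seconds at the
API boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probe import ProbeGeometry
from .waveforms import FS, N_SAMPLES, MeanWaveform, Unit, summarize_waveforms

DEFAULT_UV_PER_BIT = 0.195


class SessionIntegrityError(RuntimeError):
    pass


@dataclass
class SessionBundle:
    session_id: str
    probe: ProbeGeometry
    fs: float
    units: dict[int, Unit]                      # unit id -> Unit (waveforms filled)
    snippets: dict[int, np.ndarray] = field(default_factory=dict)  # uV arrays
    shank_channels: dict[int, list[int]] = field(default_factory=dict)
    behavior: pd.DataFrame | None = None
    lfp: np.ndarray | None = None               # channels x samples, uV
    lfp_fs: float | None = None
    immobility: np.ndarray | None = None
    ground_truth: dict | None = None


def write_session(
    out_dir,
    probe: ProbeGeometry,
    spike_samples: dict[int, np.ndarray],
    unit_shank: dict[int, int],
    snippets: dict[int, np.ndarray],
    shank_channels: dict[int, list[int]],
    session_id: str = "synthetic",
    fs: float = FS,
    uv_per_bit: float = DEFAULT_UV_PER_BIT,
    lfp: np.ndarray | None = None,
    lfp_fs: float | None = None,
    behavior: pd.DataFrame | None = None,
    ground_truth: dict | None = None,
) -> Path:
    """Write a session in the dialect consumed by :func:`read_session`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "probe.json").write_text(
        json.dumps(
            {
                "vertical_spacing": probe.vertical_spacing,
                "dual_sided": probe.dual_sided,
                "channels": probe.to_records(),
            },
            indent=1,
        )
    )
    shanks = sorted(shank_channels)
    for s in shanks:
        uids = sorted(u for u, sh in unit_shank.items() if sh == s)
        res, clu = [], []
        spk_rows = []
        for u in uids:
            res.extend(int(x) for x in spike_samples[u])
            clu.extend([u] * len(spike_samples[u]))
            spk_rows.append(np.asarray(snippets[u]))
        order = np.argsort(np.asarray(res, dtype=np.int64), kind="stable")
        res_arr = np.asarray(res, dtype=np.int64)[order]
        clu_arr = np.asarray(clu, dtype=np.int64)[order]
        spk = (
            np.concatenate(spk_rows, axis=0)[order]
            if spk_rows
            else np.zeros((0, len(shank_channels[s]), N_SAMPLES))
        )
        np.savetxt(out / f"{session_id}.res.{s}", res_arr, fmt="%d")
        with open(out / f"{session_id}.clu.{s}", "w") as f:
            f.write(f"{len(set(clu_arr.tolist()))}\n")
            f.write("\n".join(str(c) for c in clu_arr))
            if clu_arr.size:
                f.write("\n")
        np.round(spk / uv_per_bit).astype("<i2").tofile(out / f"{session_id}.spk.{s}")
    cfg = {
        "session_id": session_id,
        "fs": fs,
        "uv_per_bit": uv_per_bit,
        "n_samples": N_SAMPLES,
        "shanks": {str(s): [int(c) for c in shank_channels[s]] for s in shanks},
        "clu_offset": 0,
    }
    if lfp is not None:
        np.round(np.asarray(lfp) / uv_per_bit).astype("<i2").T.tofile(out / "lfp.dat")
        (out / "lfp.json").write_text(
            json.dumps(
                {"fs": lfp_fs, "n_channels": int(np.asarray(lfp).shape[0]),
                 "uv_per_bit": uv_per_bit}
            )
        )
        cfg["lfp"] = "lfp.dat"
    if behavior is not None:
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
        cfg["behavior"] = "behavior.tsv"
    if ground_truth is not None:
        (out / "groundtruth.json").write_text(json.dumps(ground_truth, default=_jsonable))
    (out / "session.json").write_text(json.dumps(cfg, indent=1))
    return out


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    if hasattr(x, "__dict__"):
        return vars(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def read_session(session_dir) -> SessionBundle:
    """Read and validate a session directory into a :class:`SessionBundle`."""
    d = Path(session_dir)
    cfg_path = d / "session.json"
    if not cfg_path.exists():
        raise FileNotFoundError(f"missing session.json in {d}")
    cfg = json.loads(cfg_path.read_text())
    probe_cfg = json.loads((d / "probe.json").read_text())
    probe = ProbeGeometry.from_records(
        probe_cfg["channels"], probe_cfg["vertical_spacing"], probe_cfg.get("dual_sided", False)
    )
    fs = float(cfg["fs"])
    uv_per_bit = float(cfg["uv_per_bit"])
    n_samples = int(cfg["n_samples"])
    clu_offset = int(cfg.get("clu_offset", 0))
    sid = cfg["session_id"]

    units: dict[int, Unit] = {}
    snippets: dict[int, np.ndarray] = {}
    shank_channels = {int(s): list(map(int, chs)) for s, chs in cfg["shanks"].items()}
    for s, chans in shank_channels.items():
        res_f, clu_f, spk_f = (d / f"{sid}.res.{s}", d / f"{sid}.clu.{s}", d / f"{sid}.spk.{s}")
        for f in (res_f, clu_f, spk_f):
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name}")
        res = np.loadtxt(res_f, dtype=np.int64, ndmin=1)
        clu_lines = clu_f.read_text().split()
        clu = np.asarray(clu_lines[1:], dtype=np.int64) - clu_offset
        if res.size != clu.size:
            raise SessionIntegrityError(
                f"shank {s}: {res.size} spike times vs {clu.size} cluster labels"
            )
        if res.size > 1 and np.any(np.diff(res) < 0):
            bad = int(np.flatnonzero(np.diff(res) < 0)[0]) + 2
            raise SessionIntegrityError(f"shank {s}: spike samples decrease at line {bad}")
        raw = np.fromfile(spk_f, dtype="<i2")
        expected = res.size * len(chans) * n_samples
        if raw.size != expected:
            raise SessionIntegrityError(
                f"shank {s}: snippet file holds {raw.size} samples, expected {expected}"
            )
        spk = raw.reshape(res.size, len(chans), n_samples).astype(float) * uv_per_bit
        for uid in np.unique(clu):
            sel = clu == uid
            snip = spk[sel]
            waveforms = {
                ch: summarize_waveforms(snip[:, i, :], fs=fs, channel=ch)
                for i, ch in enumerate(chans)
            }
            units[int(uid)] = Unit(
                unit_id=int(uid),
                shank=int(s),
                spike_times=res[sel] / fs,
                waveforms=waveforms,
            )
            snippets[int(uid)] = snip

    behavior = None
    if "behavior" in cfg:
        behavior = pd.read_csv(d / cfg["behavior"], sep="\t")
    lfp = lfp_fs = None
    if "lfp" in cfg:
        lcfg = json.loads((d / "lfp.json").read_text())
        raw = np.fromfile(d / cfg["lfp"], dtype="<i2")
        nch = int(lcfg["n_channels"])
        lfp = raw.reshape(-1, nch).T.astype(float) * float(lcfg["uv_per_bit"])
        lfp_fs = float(lcfg["fs"])
    gt = None
    if (d / "groundtruth.json").exists():
        gt = json.loads((d / "groundtruth.json").read_text())
    return SessionBundle(
        session_id=sid, probe=probe, fs=fs, units=units, snippets=snippets,
        shank_channels=shank_channels, behavior=behavior, lfp=lfp, lfp_fs=lfp_fs,
        ground_truth=gt,
    )


def write_tables(tables: dict[str, pd.DataFrame], out_dir, manifest: dict | None = None) -> Path:
    """Write result DataFrames as TSV (UTF-8, '.' decimal) plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if manifest is not None:
        import polarspike

        manifest = {"version": polarspike.__version__, **manifest}
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=_jsonable))
    return out
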