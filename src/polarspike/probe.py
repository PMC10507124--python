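"""Silicon-probe geometry.

Multi-shank linear probes: shanks are spaced horizontally (200 um by
default) and recording sites on each shank form a vertical ladder with a
fixed spacing (15 or 20 um in the designs emulated here).  The y axis
points toward the brain surface: larger y means shallower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SHANK_PITCH_UM = 200.0


@dataclass(frozen=True)
class ProbeGeometry:
    """Channel map of a multi-shank probe.

    Parameters
    ----------
    channels
        Array of records ``(channel, shank, x, y)`` with coordinates in um.
        Larger ``y`` is closer to the brain surface.
    vertical_spacing
        Ladder pitch within a shank, um.
    dual_sided : bool
        Whether sites sit on both faces of each shank.
    """

    channel_ids: np.ndarray
    shank_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vertical_spacing: float
    dual_sided: bool = False

    def __post_init__(self) -> None:
        ids = np.asarray(self.channel_ids)
        if ids.size != np.unique(ids).size:
            raise ValueError("channel ids must be unique")
        if self.vertical_spacing <= 0:
            raise ValueError("vertical spacing must be positive")

    @property
    def n_channels(self) -> int:
        return int(np.asarray(self.channel_ids).size)

    def shank_of(self, channel: int) -> int:
        return int(self.shank_ids[self._index(channel)])

    def y_of(self, channel: int) -> float:
        return float(self.y[self._index(channel)])

    def channels_on_shank(self, shank: int) -> np.ndarray:
        """Channel ids on one shank, ordered from deep to superficial."""
        mask = self.shank_ids == shank
        order = np.argsort(self.y[mask], kind="stable")
        return self.channel_ids[mask][order]

    def _index(self, channel: int) -> int:
        hits = np.nonzero(self.channel_ids == channel)[0]
        if hits.size == 0:
            raise KeyError(f"unknown channel {channel}")
        return int(hits[0])

    def to_records(self) -> list[dict]:
        return [
            {
                "channel": int(c),
                "shank": int(s),
                "x": float(x),
                "y": float(y),
            }
            for c, s, x, y in zip(self.channel_ids, self.shank_ids, self.x, self.y)
        ]

    @classmethod
    def from_records(
        cls,
        records: list[dict],
        vertical_spacing: float,
        dual_sided: bool = False,
    ) -> "ProbeGeometry":
        return cls(
            channel_ids=np.array([r["channel"] for r in records], dtype=int),
            shank_ids=np.array([r["shank"] for r in records], dtype=int),
            x=np.array([r["x"] for r in records], dtype=float),
            y=np.array([r["y"] for r in records], dtype=float),
            vertical_spacing=float(vertical_spacing),
            dual_sided=dual_sided,
        )


def make_probe(
    n_shanks: int,
    sites_per_shank: int,
    spacing: float,
    dual_sided: bool = False,
    shank_pitch: float = DEFAULT_SHANK_PITCH_UM,
) -> ProbeGeometry:
    """Build a regular multi-shank probe.

    Site 0 of each shank is the deepest (smallest y); successive sites climb
    toward the brain surface in steps of ``spacing`` um.  Channel ids are
    assigned shank-major, deep to superficial.
    """
    if n_shanks < 1 or sites_per_shank < 1:
        raise ValueError("counts must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    chans, shanks, xs, ys = [], [], [], []
    cid = 0
    for s in range(n_shanks):
        for k in range(sites_per_shank):
            chans.append(cid)
            shanks.append(s)
            xs.append(s * shank_pitch)
            ys.append(k * spacing)
            cid += 1
    return ProbeGeometry(
        channel_ids=np.array(chans, dtype=int),
        shank_ids=np.array(shanks, dtype=int),
        x=np.array(xs, dtype=float),
        y=np.array(ys, dtype=float),
        vertical_spacing=float(spacing),
        dual_sided=dual_sided,
    )
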