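"""Biosemi-128 electrode montage and the analysis regions of interest.

The full 128-channel ABCD ring layout (labels A1–A32 … D1–D32) is pulled
from MNE's standard ``biosemi128`` montage, which places A1 at the vertex.
A reduced montage restricted to the ROI channels (plus one filler) is
provided for fast simulation and testing; every ROI used anywhere in the
analysis chain resolves in both montages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Channels entering each windowed-amplitude / spectral analysis.
ROI_CHANNELS: dict[str, tuple[str, ...]] = {
    # vertex (Cz = A1) plus five closest electrodes
    "vertex": ("A1", "A2", "B1", "C1", "D1", "D15"),
    # midline parietal (Pz = A19) plus four closest
    "parietal": ("A19", "A4", "A5", "A20", "A32"),
    # occipital (Oz = A23) plus four closest
    "occipital": ("A23", "A15", "A22", "A24", "A28"),
    # fronto-medial (Fz = C20) plus adjacent midline electrodes
    "fronto_medial": ("C19", "C20", "C21"),
}

_REDUCED_FILLER = ("B16",)


@dataclass(frozen=True)
class Montage:
    """Electrode labels with unit-sphere 3-D and azimuthal 2-D positions."""

    name: str
    labels: tuple[str, ...]
    pos3d: np.ndarray  # (n, 3), metres, head frame
    pos2d: np.ndarray  # (n, 2), azimuthal-equidistant projection (radians)
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "index", {lab: i for i, lab in enumerate(self.labels)}
        )
        if len(self.index) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def pick(self, labels) -> np.ndarray:
        """Indices of ``labels``; KeyError names the first missing label."""
        try:
            return np.array([self.index[l] for l in labels], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in montage {self.name!r}")

    def roi(self, name: str) -> np.ndarray:
        return self.pick(ROI_CHANNELS[name])


def _project_2d(pos3d: np.ndarray) -> np.ndarray:
    # azimuthal equidistant: radius = polar angle from vertex, angle = azimuth
    x, y, z = pos3d.T
    r = np.linalg.norm(pos3d, axis=1)
    theta = np.arccos(np.clip(z / np.where(r == 0, 1.0, r), -1.0, 1.0))
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


@lru_cache(maxsize=None)
def _biosemi128_positions() -> tuple[tuple[str, ...], bytes]:
    import mne

    mont = mne.channels.make_standard_montage("biosemi128")
    ch_pos = mont.get_positions()["ch_pos"]
    labels = tuple(ch_pos)
    pos = np.array([ch_pos[l] for l in labels], dtype=float)
    return labels, pos.tobytes()


def load_montage(name: str = "full") -> Montage:
    """Return the ``'full'`` 128-channel or ``'reduced'`` ROI-only montage."""
    labels, raw = _biosemi128_positions()
    pos3d = np.frombuffer(raw, dtype=float).reshape(-1, 3).copy()
    if name == "full":
        keep = labels
    elif name == "reduced":
        roi_all = [c for chans in ROI_CHANNELS.values() for c in chans]
        keep = tuple(dict.fromkeys(roi_all + list(_REDUCED_FILLER)))
    else:
        raise ValueError(f"unknown montage {name!r}; use 'full' or 'reduced'")
    idx = [labels.index(l) for l in keep]
    p3 = pos3d[idx]
    return Montage(name=name, labels=tuple(keep), pos3d=p3, pos2d=_project_2d(p3))
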