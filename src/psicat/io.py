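"""On-disk formats: events TSV, EEG container, stimuli, run configuration.

Events use a tab-separated, BIDS-events-style dialect (onset/duration in
seconds plus trial and condition columns).  The EEG session container is a
raw little-endian binary sample block (``<stem>.dat``, channels-major)
beside a JSON sidecar (``<stem>.json``) holding labels, sampling rate,
units and provenance, with events in ``<stem>_events.tsv``; float32 is the
default on-disk dtype (16-significant-bit precision is ample at µV scale)
and float64 is available for bit-exact round-trips.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geom
from .geometry import GeometryConfig
from .montage import load_montage
from .render import render
from .scheduler import EVENT_COLUMNS, TimingConfig
from .simulate import SessionData

__all__ = [
    "read_events",
    "write_events",
    "read_eeg",
    "write_eeg",
    "save_stimulus_set",
    "RunConfig",
]

_EVENT_DTYPES = {
    "onset": float, "duration": float, "event_type": str, "trial_index": "Int64",
    "block": "Int64", "congruency": str, "target_class": str,
    "n_vertices": "Int64", "stimulus_id": str, "response": str,
    "rt_ms": float, "correct": "boolean",
}


def write_events(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    out = events.reindex(columns=EVENT_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"events file {path} is empty")
        return pd.DataFrame(columns=EVENT_COLUMNS)
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"], dtype="object")
    except Exception as err:
        raise ValueError(f"cannot parse events table {path}: {err}") from err
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table {path} lacks columns {missing}")
    for col, dtype in _EVENT_DTYPES.items():
        try:
            if dtype is str:
                df[col] = df[col].astype("string").fillna("")
            elif dtype == "Int64":
                # mixed NaN rows force a float dialect on disk ('3.0')
                df[col] = pd.to_numeric(df[col], errors="raise").round().astype("Int64")
            elif dtype == "boolean":
                df[col] = df[col].map(
                    {"True": True, "False": False, True: True, False: False}
                ).astype("boolean")
            else:
                df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as err:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(
                f"events table {path}, column {col!r}, row {row}: {err}") from err
    return df[EVENT_COLUMNS]


def write_eeg(session: SessionData, stem, dtype: str = "float32") -> Path:
    """Write ``<stem>.dat`` + ``<stem>.json`` + ``<stem>_events.tsv``."""
    if dtype not in ("float32", "float64"):
        raise ValueError("dtype must be 'float32' or 'float64'")
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(session.data, dtype=np.dtype(dtype).newbyteorder("<"))
    data.tofile(stem.with_suffix(".dat"))
    sidecar = dict(
        format="psicat-raw-v1", dtype=dtype, byte_order="little",
        unit="uV", sfreq=session.sfreq, labels=list(session.labels),
        n_channels=session.data.shape[0], n_samples=session.data.shape[1],
        participant_id=session.participant_id, montage=session.montage_name,
        seed=session.seed,
    )
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    write_events(session.events, stem.parent / (stem.name + "_events.tsv"))
    return stem


def read_eeg(stem, montage: str = None) -> SessionData:
    """Read a session container; warns about labels absent from the montage."""
    stem = Path(stem)
    sidecar_path = stem.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    dt = np.dtype(meta["dtype"]).newbyteorder("<")
    data = np.fromfile(stem.with_suffix(".dat"), dtype=dt).astype(float)
    data = data.reshape(meta["n_channels"], meta["n_samples"])
    events = read_events(stem.parent / (stem.name + "_events.tsv"))
    labels = tuple(meta["labels"])
    if montage is not None:
        known = set(load_montage(montage).labels)
        unknown = [l for l in labels if l not in known]
        if unknown:
            warnings.warn(f"labels not in montage {montage!r}: {unknown}")
    resp = events[events.event_type == "response"].copy()
    resp["condition"] = resp.congruency.astype(str) + "." + resp.target_class.astype(str)
    return SessionData(
        data=data, sfreq=float(meta["sfreq"]), labels=labels, events=events,
        responses=resp.reset_index(drop=True),
        participant_id=meta.get("participant_id", ""),
        montage_name=meta.get("montage", ""), seed=meta.get("seed", -1),
    )


def save_stimulus_set(stimuli: dict, config: GeometryConfig, outdir,
                      pixels_per_degree: float = 32.0, seed: int = None) -> Path:
    """Render every stimulus to SVG + PNG and write a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for sid in sorted(stimuli):
        stim = stimuli[sid]
        art = render(stim, config, pixels_per_degree)
        (outdir / f"{sid}.svg").write_text(art.svg)
        art.image.save(outdir / f"{sid}.png")
        entry = dict(svg=f"{sid}.svg", png=f"{sid}.png")
        if isinstance(stim, geom.TargetStimulus):
            entry.update(kind="target", target_class=stim.target_class,
                         n_vertices=stim.polygon.n_vertices,
                         vertices=[list(v) for v in stim.polygon.vertices])
        else:
            entry.update(kind="primer", congruency=stim.congruency,
                         source_target=stim.source_target_id)
        manifest[sid] = entry
    meta = dict(seed=seed, pixels_per_degree=pixels_per_degree,
                config=dataclasses.asdict(config), stimuli=manifest)
    (outdir / "manifest.json").write_text(json.dumps(meta, indent=1))
    return outdir


@dataclasses.dataclass
class RunConfig:
    """Serializable description of one reproducible synthetic run."""

    seed: int = 0
    n_participants: int = 17
    montage: str = "reduced"
    outdir: str = "psicat-out"
    timing: TimingConfig = dataclasses.field(default_factory=TimingConfig)
    geometry: GeometryConfig = dataclasses.field(default_factory=GeometryConfig)
    n_perm: int = 500
    spectral_repeats: int = 10

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["geometry"]["interior_angle_bounds"] = {
            str(k): list(v) for k, v in self.geometry.interior_angle_bounds.items()
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        gd = d.pop("geometry", {})
        if "interior_angle_bounds" in gd:
            gd["interior_angle_bounds"] = {
                int(k): tuple(v) for k, v in gd["interior_angle_bounds"].items()
            }
        for key in ("nosci_rotation_bounds",):
            if key in gd:
                gd[key] = tuple(gd[key])
        td = d.pop("timing", {})
        return cls(timing=TimingConfig(**td), geometry=GeometryConfig(**gd), **d)
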