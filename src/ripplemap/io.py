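"""Flat-file session format: CSV spikes, HDF5 LFP, JSON epochs/truth.

A session directory contains:

* ``spikes.csv`` - columns unit_id, region, time_s
* ``lfp.h5`` - dataset ``lfp`` with attributes ``fs``, ``t0``, ``units``
* ``epochs.json`` - epoch list plus shock times
* ``position.csv`` (optional) - columns t, x, y
* ``truth.json`` (optional) - synthetic ground truth
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .core import Epoch, LfpTrace, PositionTrace, SessionBundle, SpikeData
from .synthetic import AssemblyTruth, RippleTruth


def save_session(bundle: SessionBundle, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for uid in bundle.spikes.unit_ids():
        region = bundle.spikes.regions[uid]
        for t in bundle.spikes.times[uid]:
            rows.append((uid, region, t))
    pd.DataFrame(rows, columns=["unit_id", "region", "time_s"]).to_csv(
        path / "spikes.csv", index=False
    )

    if bundle.lfp is not None:
        with h5py.File(path / "lfp.h5", "w") as f:
            d = f.create_dataset("lfp", data=bundle.lfp.samples)
            d.attrs["fs"] = bundle.lfp.fs
            d.attrs["t0"] = bundle.lfp.t0
            d.attrs["units"] = bundle.lfp.units

    meta = {
        "epochs": [
            {"name": e.name, "start_s": e.start_s, "end_s": e.end_s}
            for e in bundle.epochs
        ],
        "shock_times": np.asarray(bundle.shock_times).tolist(),
    }
    (path / "epochs.json").write_text(json.dumps(meta, indent=2))

    if bundle.position is not None:
        pd.DataFrame(
            {"t": bundle.position.t, "x": bundle.position.x, "y": bundle.position.y}
        ).to_csv(path / "position.csv", index=False)

    if bundle.truth is not None:
        (path / "truth.json").write_text(json.dumps(_truth_to_json(bundle.truth), indent=2))
    return path


def _truth_to_json(truth: dict) -> dict:
    out = {"memory_assembly_index": truth.get("memory_assembly_index")}
    out["ripples"] = [
        {
            "onset_s": r.onset_s,
            "peak_s": r.peak_s,
            "offset_s": r.offset_s,
            "amplitude_sd": r.amplitude_sd,
            "epoch": r.epoch,
        }
        for r in truth.get("ripples", [])
    ]
    out["assemblies"] = [
        {
            "member_ids": sorted(a.member_ids),
            "event_times": np.asarray(a.event_times).tolist(),
            "yoked_event_times": np.asarray(a.yoked_event_times).tolist(),
        }
        for a in truth.get("assemblies", [])
    ]
    return out


def load_session(path: str | Path) -> SessionBundle:
    """Load and validate a session directory.

    Raises with the offending file (and label/epoch) on schema violations:
    missing required files, unknown region labels, unsorted timestamps,
    overlapping epochs.
    """
    path = Path(path)
    spikes_file = path / "spikes.csv"
    epochs_file = path / "epochs.json"
    for req in (spikes_file, epochs_file):
        if not req.exists():
            raise FileNotFoundError(f"missing required session file: {req}")

    df = pd.read_csv(spikes_file)
    for col in ("unit_id", "region", "time_s"):
        if col not in df.columns:
            raise ValueError(f"{spikes_file}: missing column {col!r}")
    times, regions = {}, {}
    for uid, grp in df.groupby("unit_id"):
        labels = grp["region"].unique()
        if labels.size != 1:
            raise ValueError(f"{spikes_file}: unit {uid} has multiple region labels")
        ts = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            raise ValueError(f"{spikes_file}: unit {uid} timestamps are unsorted")
        times[int(uid)] = ts
        regions[int(uid)] = str(labels[0])
    try:
        spikes = SpikeData(times=times, regions=regions)
    except ValueError as err:
        raise ValueError(f"{spikes_file}: {err}") from err

    meta = json.loads(epochs_file.read_text())
    epochs = [Epoch(e["name"], float(e["start_s"]), float(e["end_s"])) for e in meta["epochs"]]
    shock_times = np.asarray(meta.get("shock_times", []), dtype=float)

    lfp: Optional[LfpTrace] = None
    if (path / "lfp.h5").exists():
        with h5py.File(path / "lfp.h5", "r") as f:
            d = f["lfp"]
            lfp = LfpTrace(
                samples=d[...],
                fs=float(d.attrs["fs"]),
                t0=float(d.attrs.get("t0", 0.0)),
                units=str(d.attrs.get("units", "uV")),
            )

    position: Optional[PositionTrace] = None
    if (path / "position.csv").exists():
        pdf = pd.read_csv(path / "position.csv")
        position = PositionTrace(
            t=pdf["t"].to_numpy(), x=pdf["x"].to_numpy(), y=pdf["y"].to_numpy()
        )

    truth: Optional[dict] = None
    if (path / "truth.json").exists():
        raw = json.loads((path / "truth.json").read_text())
        truth = {
            "memory_assembly_index": raw.get("memory_assembly_index"),
            "ripples": [
                RippleTruth(
                    onset_s=r["onset_s"],
                    peak_s=r["peak_s"],
                    offset_s=r["offset_s"],
                    amplitude_sd=r["amplitude_sd"],
                    epoch=r["epoch"],
                )
                for r in raw.get("ripples", [])
            ],
            "assemblies": [
                AssemblyTruth(
                    member_ids=frozenset(a["member_ids"]),
                    event_times=np.asarray(a["event_times"]),
                    yoked_event_times=np.asarray(a["yoked_event_times"]),
                    spec=None,
                )
                for a in raw.get("assemblies", [])
            ],
        }

    try:
        return SessionBundle(
            spikes=spikes,
            epochs=epochs,
            lfp=lfp,
            shock_times=shock_times,
            position=position,
            truth=truth,
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err
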