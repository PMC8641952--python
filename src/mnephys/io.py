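"""Sweep container I/O.

Native format is a self-describing HDF5 layout::

    /cells/<cell_id>/sweeps/<protocol>/<index>
        datasets: time_ms, recorded, command
        attrs:    mode, units_recorded, units_command, sample_rate_hz,
                  holding, drug, ground_truth (JSON), ...

plus per-sweep CSV (columns ``time_ms, recorded, command``) with a JSON
sidecar for metadata. Units are pipeline units (mV/pA/ms) on disk; CSV
sources in volts/amps are converted on load with a provenance note.
ABF/NWB reading requires optional acquisition-format dependencies and
raises a capability error when they are unavailable.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path

import h5py
import numpy as np

from .errors import CapabilityError, SweepIOError
from .sweep import Sweep
from .sim import ModelParams

_REQUIRED_DATASETS = ("time_ms", "recorded", "command")
_REQUIRED_ATTRS = ("mode", "sample_rate_hz")


def _meta_to_attrs(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if k == "ground_truth" and isinstance(v, ModelParams):
            out[k] = json.dumps(v.to_dict())
        elif isinstance(v, (str, int, float, np.integer, np.floating, bool)):
            out[k] = v
    return out


def _attrs_to_meta(attrs) -> dict:
    meta = {}
    for k, v in attrs.items():
        if k == "ground_truth":
            meta[k] = ModelParams.from_dict(json.loads(v))
        elif isinstance(v, bytes):
            meta[k] = v.decode()
        elif isinstance(v, np.generic):
            meta[k] = v.item()
        else:
            meta[k] = v
    return meta


def write_sweeps(path, cells: dict) -> None:
    """Write ``{cell_id: {protocol: [Sweep, ...]}}`` to the native HDF5
    container, overwriting any existing file."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "mnephys-sweeps-v1"
        root = fh.create_group("cells")
        for cell_id, protocols in cells.items():
            cgrp = root.create_group(str(cell_id)).create_group("sweeps")
            for protocol, sweeps in protocols.items():
                pgrp = cgrp.create_group(str(protocol))
                for idx, sw in enumerate(sweeps):
                    g = pgrp.create_group(str(idx))
                    g.create_dataset("time_ms", data=sw.time)
                    g.create_dataset("recorded", data=sw.recorded)
                    g.create_dataset("command", data=sw.command)
                    g.attrs["mode"] = sw.mode
                    g.attrs["units_recorded"] = (
                        "mV" if sw.mode == "current" else "pA")
                    g.attrs["units_command"] = (
                        "pA" if sw.mode == "current" else "mV")
                    g.attrs["sample_rate_hz"] = sw.sample_rate
                    for k, v in _meta_to_attrs(sw.meta).items():
                        g.attrs[k] = v


def read_sweeps(path, format: str | None = None) -> dict:
    """Read a sweep container back as ``{cell_id: {protocol: [Sweep]}}``.

    ``format`` is auto-detected from the extension when omitted
    (``native`` for .h5/.hdf5, ``csv`` for .csv; ``abf``/``nwb`` raise a
    capability error since no acquisition-format reader is installed).
    """
    path = Path(path)
    if not path.exists():
        raise SweepIOError(f"no such file: {path}")
    if format is None:
        ext = path.suffix.lower()
        format = {".h5": "native", ".hdf5": "native",
                  ".csv": "csv", ".abf": "abf", ".nwb": "nwb"}.get(ext)
        if format is None:
            raise SweepIOError(f"cannot infer format from extension {ext!r}")
    if format in ("abf", "nwb"):
        raise CapabilityError(
            f"{format.upper()} reading requires an optional acquisition-"
            "format dependency that is not installed; convert to the native "
            "HDF5 container or CSV instead")
    if format == "csv":
        sw = read_sweep_csv(path)
        return {sw.meta.get("cell_id", "cell0"):
                {sw.meta.get("protocol", "sweep"): [sw]}}
    if format != "native":
        raise CapabilityError(f"unsupported format {format!r}")

    out: dict = {}
    try:
        with h5py.File(path, "r") as fh:
            if "cells" not in fh:
                raise SweepIOError("missing /cells group (schema violation)")
            for cell_id, cgrp in fh["cells"].items():
                if "sweeps" not in cgrp:
                    raise SweepIOError(
                        f"cell {cell_id!r}: missing 'sweeps' group")
                out[cell_id] = {}
                for protocol, pgrp in cgrp["sweeps"].items():
                    sweeps = []
                    for idx in sorted(pgrp, key=int):
                        g = pgrp[idx]
                        for ds in _REQUIRED_DATASETS:
                            if ds not in g:
                                raise SweepIOError(
                                    f"sweep {cell_id}/{protocol}/{idx}: "
                                    f"missing dataset {ds!r}")
                        for attr in _REQUIRED_ATTRS:
                            if attr not in g.attrs:
                                raise SweepIOError(
                                    f"sweep {cell_id}/{protocol}/{idx}: "
                                    f"missing attribute {attr!r}")
                        meta = _attrs_to_meta(g.attrs)
                        mode = meta.pop("mode")
                        meta.pop("units_recorded", None)
                        meta.pop("units_command", None)
                        meta.pop("sample_rate_hz", None)
                        sweeps.append(Sweep(time=g["time_ms"][...],
                                            recorded=g["recorded"][...],
                                            command=g["command"][...],
                                            mode=mode, meta=meta))
                    out[cell_id][protocol] = sweeps
    except OSError as exc:
        raise SweepIOError(f"unreadable container {path}: {exc}") from exc
    return out


def write_sweep_csv(path, sweep: Sweep) -> None:
    """Write one sweep as CSV (time_ms, recorded, command) plus a JSON
    metadata sidecar ``<path>.meta.json``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ms", "recorded", "command"])
        for t, r, c in zip(sweep.time, sweep.recorded, sweep.command):
            w.writerow([repr(float(t)), repr(float(r)), repr(float(c))])
    meta = {"mode": sweep.mode, "units_recorded":
            "mV" if sweep.mode == "current" else "pA",
            "units_command": "pA" if sweep.mode == "current" else "mV"}
    meta.update(_meta_to_attrs(sweep.meta))
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_sweep_csv(path) -> Sweep:
    """Read a single-sweep CSV; accepts volt/amp units declared in the
    sidecar and converts to mV/pA with a provenance note."""
    sidecar = str(path) + ".meta.json"
    meta = {}
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)
    try:
        data = np.genfromtxt(path, delimiter=",", names=True)
    except (OSError, ValueError) as exc:
        raise SweepIOError(f"unreadable CSV {path}: {exc}") from exc
    for col in ("time_ms", "recorded", "command"):
        if col not in (data.dtype.names or ()):
            raise SweepIOError(f"CSV {path}: missing column {col!r}")
    if np.isnan(data["recorded"]).any() or np.isnan(data["time_ms"]).any():
        raise SweepIOError(f"CSV {path}: truncated or non-numeric rows")
    rec = np.asarray(data["recorded"], float)
    cmd = np.asarray(data["command"], float)
    mode = meta.get("mode", "current")
    conv = []
    units_rec = meta.get("units_recorded",
                         "mV" if mode == "current" else "pA")
    if units_rec in ("V", "volts"):
        rec = rec * 1e3
        conv.append("recorded V->mV")
    elif units_rec in ("A", "amps"):
        rec = rec * 1e12
        conv.append("recorded A->pA")
    units_cmd = meta.get("units_command",
                         "pA" if mode == "current" else "mV")
    if units_cmd in ("A", "amps"):
        cmd = cmd * 1e12
        conv.append("command A->pA")
    elif units_cmd in ("V", "volts"):
        cmd = cmd * 1e3
        conv.append("command V->mV")
    out_meta = {k: v for k, v in meta.items()
                if k not in ("mode", "units_recorded", "units_command")}
    if conv:
        out_meta["unit_conversions"] = ";".join(conv)
    return Sweep(time=np.asarray(data["time_ms"], float), recorded=rec,
                 command=cmd, mode=mode, meta=out_meta)
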