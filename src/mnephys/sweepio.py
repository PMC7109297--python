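"""Sweep file formats.

Canonical dialect: self-describing delimited text with a commented header
(diffable, exact to ~1e-12 relative).  Optional dialect: HDF5 container for
bulk cohorts (bit-exact samples).  Both carry the same header fields and
are validated on read with distinct, named errors.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np

from .sweep import Sweep, SweepMeta

__all__ = ["write_sweep", "read_sweep", "SweepFormatError",
           "SweepVersionError", "SweepLengthError", "SweepUnitError",
           "SweepMetadataError", "FORMAT_VERSION"]

FORMAT_VERSION = 1
_FLOAT_FMT = "%.12g"

_UNITS = {"voltage_clamp": ("mV", "pA"), "current_clamp": ("pA", "mV")}


class SweepFormatError(ValueError):
    """Base class for sweep-file validation failures."""


class SweepVersionError(SweepFormatError):
    """Unrecognised format version."""


class SweepLengthError(SweepFormatError):
    """Declared sample count does not match rows present."""


class SweepUnitError(SweepFormatError):
    """Units inconsistent with the declared clamp mode."""


class SweepMetadataError(SweepFormatError):
    """Required header field missing or malformed."""


_HEADER_FIELDS = ("cell_id", "group", "age", "region", "protocol_id", "seed")


def _check_meta(meta: SweepMeta) -> None:
    for f in _HEADER_FIELDS:
        v = getattr(meta, f, None)
        if v is None or v == "":
            raise SweepMetadataError(f"metadata field {f!r} is missing")


def write_sweep(sweep: Sweep, destination: str | os.PathLike,
                dialect: str = "text") -> Path:
    """Write a sweep to disk; deterministic bytes for identical input.

    ``dialect`` is "text" (canonical) or "hdf5".
    """
    _check_meta(sweep.meta)
    dest = Path(destination)
    if dialect == "text":
        _write_text(sweep, dest)
    elif dialect == "hdf5":
        _write_hdf5(sweep, dest)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return dest


def _write_text(sweep: Sweep, dest: Path) -> None:
    cu, ru = _UNITS[sweep.mode]
    m = sweep.meta
    buf = io.StringIO()
    buf.write(f"# mnephys-sweep v{FORMAT_VERSION}\n")
    buf.write(f"# cell_id: {m.cell_id}\n")
    buf.write(f"# group: {m.group}\n")
    buf.write(f"# age: {m.age}\n")
    buf.write(f"# region: {m.region}\n")
    buf.write(f"# protocol_id: {m.protocol_id}\n")
    buf.write(f"# mode: {sweep.mode}\n")
    buf.write(f"# dt_ms: {sweep.dt!r}\n")
    buf.write(f"# command_units: {cu}\n")
    buf.write(f"# response_units: {ru}\n")
    buf.write(f"# seed: {m.seed}\n")
    buf.write(f"# n_samples: {sweep.n_samples}\n")
    buf.write("index\tcommand\tresponse\n")
    table = np.column_stack([np.arange(sweep.n_samples), sweep.command,
                             sweep.response])
    np.savetxt(buf, table, fmt=("%d", _FLOAT_FMT, _FLOAT_FMT),
               delimiter="\t")
    dest.write_text(buf.getvalue())


def _write_hdf5(sweep: Sweep, dest: Path) -> None:
    import h5py

    cu, ru = _UNITS[sweep.mode]
    m = sweep.meta
    with h5py.File(dest, "w", track_order=False) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["mode"] = sweep.mode
        f.attrs["dt_ms"] = sweep.dt
        f.attrs["command_units"] = cu
        f.attrs["response_units"] = ru
        f.attrs["n_samples"] = sweep.n_samples
        for field in _HEADER_FIELDS:
            f.attrs[field] = getattr(m, field)
        f.create_dataset("command", data=sweep.command, track_times=False)
        f.create_dataset("response", data=sweep.response, track_times=False)


def read_sweep(source: str | os.PathLike) -> Sweep:
    """Read and validate a sweep file in either dialect."""
    path = Path(source)
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return _read_hdf5(path)
    return _read_text(path)


def _parse_header(lines: list[str]) -> dict[str, str]:
    hdr: dict[str, str] = {}
    for ln in lines:
        body = ln[1:].strip()
        if ":" in body:
            k, v = body.split(":", 1)
            hdr[k.strip()] = v.strip()
    return hdr


def _validate(mode: str, cu: str, ru: str, declared_n: int, n: int,
              version: str) -> None:
    if version != f"v{FORMAT_VERSION}":
        raise SweepVersionError(f"unrecognised format version {version!r}")
    if mode not in _UNITS:
        raise SweepMetadataError(f"unknown mode {mode!r}")
    if (cu, ru) != _UNITS[mode]:
        raise SweepUnitError(
            f"units ({cu}, {ru}) inconsistent with mode {mode!r}; "
            f"expected {_UNITS[mode]}")
    if declared_n != n:
        raise SweepLengthError(
            f"declared {declared_n} samples but found {n}")


def _read_text(path: Path) -> Sweep:
    header_lines: list[str] = []
    data_rows: list[tuple[float, float]] = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# mnephys-sweep"):
            raise SweepFormatError(f"{path}: not an mnephys sweep file")
        version = first.split()[-1]
        for ln in fh:
            if ln.startswith("#"):
                header_lines.append(ln)
            elif ln.strip() and not ln.startswith("index"):
                parts = ln.split()
                if len(parts) != 3:
                    raise SweepFormatError(f"malformed sample row: {ln!r}")
                data_rows.append((float(parts[1]), float(parts[2])))
    hdr = _parse_header(header_lines)
    for f in _HEADER_FIELDS + ("mode", "dt_ms", "command_units",
                               "response_units", "n_samples"):
        if f not in hdr:
            raise SweepMetadataError(f"header field {f!r} is missing")
    mode = hdr["mode"]
    _validate(mode, hdr["command_units"], hdr["response_units"],
              int(hdr["n_samples"]), len(data_rows), version)
    cmd = np.array([r[0] for r in data_rows])
    resp = np.array([r[1] for r in data_rows])
    meta = SweepMeta(cell_id=hdr["cell_id"], group=hdr["group"],
                     age=hdr["age"], region=hdr["region"],
                     protocol_id=hdr["protocol_id"], seed=int(hdr["seed"]))
    return Sweep(dt=float(hdr["dt_ms"]), mode=mode, command=cmd,
                 response=resp, meta=meta)


def _read_hdf5(path: Path) -> Sweep:
    import h5py

    with h5py.File(path, "r") as f:
        version = f"v{f.attrs.get('format_version', '?')}"
        mode = str(f.attrs.get("mode", ""))
        cu = str(f.attrs.get("command_units", ""))
        ru = str(f.attrs.get("response_units", ""))
        declared = int(f.attrs.get("n_samples", -1))
        cmd = f["command"][()]
        resp = f["response"][()]
        missing = [k for k in _HEADER_FIELDS if k not in f.attrs]
        if missing:
            raise SweepMetadataError(f"header fields {missing} missing")
        _validate(mode, cu, ru, declared, len(cmd), version)
        if len(cmd) != len(resp):
            raise SweepLengthError("command/response length mismatch")
        meta = SweepMeta(
            cell_id=str(f.attrs["cell_id"]), group=str(f.attrs["group"]),
            age=str(f.attrs["age"]), region=str(f.attrs["region"]),
            protocol_id=str(f.attrs["protocol_id"]),
            seed=int(f.attrs["seed"]))
        return Sweep(dt=float(f.attrs["dt_ms"]), mode=mode, command=cmd,
                     response=resp, meta=meta)
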