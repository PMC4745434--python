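"""Minimal C3D motion-capture codec (POINT data only).

Implements the subset of the C3D standard (https://www.c3d.org) that gait
marker trajectories need: Intel (PC) processor type, floating-point 3D point
storage, the POINT parameter group (USED, FRAMES, RATE, SCALE, DATA_START,
LABELS, UNITS) and per-sample residuals, where a negative residual marks an
invalid (gap) sample.  Analog channels, multi-byte events and integer point
storage are out of scope; files using them are rejected with a clear error.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = ["C3DFormatError", "C3DData", "read_c3d_file", "write_c3d_file"]

_BLOCK = 512
_INTEL = 84


class C3DFormatError(ValueError):
    """Malformed or unsupported C3D content, locating the offending section."""


@dataclass
class C3DData:
    labels: list[str]
    points: np.ndarray      # (T, n, 3) in file units
    residuals: np.ndarray   # (T, n) float, negative = invalid
    rate: float
    units: str


def _read_params(buf: bytes, start: int) -> dict[str, dict[str, object]]:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    if len(buf) < start + 4:
        raise C3DFormatError(f"truncated parameter header at byte {start}")
    proc = buf[start + 3]
    if proc != _INTEL:
        raise C3DFormatError(
            f"unsupported processor type {proc} at byte {start + 3} (only Intel/84)")
    groups_by_id: dict[int, str] = {}
    params: dict[int, list[tuple[str, object]]] = {}
    pos = start + 4
    while pos < len(buf) - 1:
        nchar = struct.unpack_from("b", buf, pos)[0]
        if nchar == 0:
            break
        gid = struct.unpack_from("b", buf, pos + 1)[0]
        if gid == 0:
            break
        name = buf[pos + 2: pos + 2 + abs(nchar)].decode("ascii", "replace").strip()
        p = pos + 2 + abs(nchar)
        offset = struct.unpack_from("<h", buf, p)[0]
        body = p + 2
        if gid < 0:  # group definition
            groups_by_id.setdefault(-gid, name)
        else:        # parameter record
            try:
                value = _read_param_value(buf, body)
            except struct.error as exc:
                raise C3DFormatError(
                    f"truncated parameter {name!r} at byte {body}") from exc
            params.setdefault(gid, []).append((name, value))
        if offset == 0:
            break
        pos = p + offset
    out: dict[str, dict[str, object]] = {}
    for gid, items in params.items():
        gname = groups_by_id.get(gid, f"GROUP{gid}")
        out.setdefault(gname, {}).update(items)
    return out


def _read_param_value(buf: bytes, pos: int) -> object:
    dtype = struct.unpack_from("b", buf, pos)[0]
    ndims = struct.unpack_from("B", buf, pos + 1)[0]
    dims = [struct.unpack_from("B", buf, pos + 2 + i)[0] for i in range(ndims)]
    data_pos = pos + 2 + ndims
    count = int(np.prod(dims)) if dims else 1
    if dtype == -1:  # characters
        raw = buf[data_pos: data_pos + count]
        if ndims >= 2:
            width = dims[0]
            n = count // width
            return [raw[i * width:(i + 1) * width].decode("ascii", "replace").strip()
                    for i in range(n)]
        return raw.decode("ascii", "replace").strip()
    if dtype == 1:
        arr = np.frombuffer(buf, np.int8, count, data_pos)
    elif dtype == 2:
        arr = np.frombuffer(buf, "<i2", count, data_pos)
    elif dtype == 4:
        arr = np.frombuffer(buf, "<f4", count, data_pos)
    else:
        raise C3DFormatError(f"unknown parameter data type {dtype} at byte {pos}")
    return arr.reshape(dims[::-1]) if dims else arr[0]


def read_c3d_file(path) -> C3DData:
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < _BLOCK:
        raise C3DFormatError(f"file shorter than one 512-byte block ({len(buf)} bytes)")
    param_block, magic = buf[0], buf[1]
    if magic != 0x50:
        raise C3DFormatError(f"byte 1 is {magic:#x}, expected 0x50 (not a C3D file)")
    n_points, = struct.unpack_from("<H", buf, 2)
    first_frame, = struct.unpack_from("<H", buf, 6)
    last_frame, = struct.unpack_from("<H", buf, 8)
    scale, = struct.unpack_from("<f", buf, 12)
    data_block, = struct.unpack_from("<H", buf, 16)
    rate, = struct.unpack_from("<f", buf, 20)

    params = _read_params(buf, (param_block - 1) * _BLOCK)
    point = params.get("POINT", {})
    n_used = int(point.get("USED", n_points))
    if n_used <= 0:
        raise C3DFormatError("POINT:USED is 0 — file contains no markers")
    scale = float(point.get("SCALE", scale))
    if scale >= 0:
        raise C3DFormatError(
            "integer point storage (POINT:SCALE >= 0) is not supported")
    rate = float(point.get("RATE", rate))
    data_block = int(point.get("DATA_START", data_block))
    n_frames = int(point.get("FRAMES", last_frame - first_frame + 1))
    labels = point.get("LABELS") or [f"M{i + 1}" for i in range(n_used)]
    labels = list(labels)[:n_used]
    while len(labels) < n_used:
        labels.append(f"M{len(labels) + 1}")
    units = point.get("UNITS", "mm") or "mm"

    off = (data_block - 1) * _BLOCK
    need = n_frames * n_used * 4 * 4
    if off < 0 or off + need > len(buf):
        raise C3DFormatError(
            f"3D data section truncated: need {need} bytes at offset {off}, "
            f"file has {len(buf)}")
    raw = np.frombuffer(buf, "<f4", n_frames * n_used * 4, off)
    raw = raw.reshape(n_frames, n_used, 4).astype(float)
    return C3DData(labels, raw[:, :, :3].copy(), raw[:, :, 3].copy(), rate,
                   str(units))


def _param_record(name: str, gid: int, dtype: int, dims: list[int],
                  payload: bytes) -> bytes:
    head = struct.pack("bb", len(name), gid) + name.encode("ascii")
    body = struct.pack("bB", dtype, len(dims)) + bytes(dims) + payload + b"\x00"
    offset = 2 + len(body)
    return head + struct.pack("<h", offset) + body


def _group_record(name: str, gid: int) -> bytes:
    head = struct.pack("bb", len(name), -gid) + name.encode("ascii")
    body = b"\x00"
    return head + struct.pack("<h", 2 + len(body)) + body


def write_c3d_file(path, labels: list[str], points: np.ndarray,
                   residuals: np.ndarray | None, rate: float,
                   units: str = "mm") -> None:
    """Write POINT trajectories as a float/Intel C3D file.

    ``points`` is (T, n, 3) in ``units``; ``residuals`` (T, n) with negative
    values marking invalid samples (None means all valid).
    """
    points = np.asarray(points, float)
    T, n, _ = points.shape
    if n != len(labels):
        raise ValueError("label count does not match point columns")
    if residuals is None:
        residuals = np.zeros((T, n))
    residuals = np.asarray(residuals, float)

    label_width = max(4, max(len(s) for s in labels))
    label_payload = b"".join(s.ljust(label_width).encode("ascii") for s in labels)
    unit_bytes = units.ljust(4).encode("ascii")

    recs = _group_record("POINT", 1)
    recs += _param_record("USED", 1, 2, [], struct.pack("<h", n))
    recs += _param_record("FRAMES", 1, 2, [], struct.pack("<h", min(T, 32767)))
    recs += _param_record("SCALE", 1, 4, [], struct.pack("<f", -1.0))
    recs += _param_record("RATE", 1, 4, [], struct.pack("<f", rate))
    recs += _param_record("UNITS", 1, -1, [len(unit_bytes)], unit_bytes)
    recs += _param_record("LABELS", 1, -1, [label_width, n], label_payload)

    ds_rec = _param_record("DATA_START", 1, 2, [], struct.pack("<h", 0))
    n_param_blocks = (4 + len(recs) + len(ds_rec) + 2 + _BLOCK - 1) // _BLOCK
    data_block = 2 + n_param_blocks
    recs += _param_record("DATA_START", 1, 2, [], struct.pack("<h", data_block))
    recs += b"\x00\x00"  # terminator record
    param = struct.pack("BBBB", 1, 0x50, n_param_blocks, _INTEL) + recs
    param = param.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    struct.pack_into("BB", header, 0, 2, 0x50)
    struct.pack_into("<H", header, 2, n)
    struct.pack_into("<H", header, 4, 0)            # analog/frame
    struct.pack_into("<H", header, 6, 1)            # first frame
    struct.pack_into("<H", header, 8, min(T, 65535))
    struct.pack_into("<H", header, 10, 10)          # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)        # scale (float storage)
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 0)           # analog samples per frame
    struct.pack_into("<f", header, 20, rate)

    data = np.empty((T, n, 4), "<f4")
    data[:, :, :3] = points
    data[:, :, 3] = residuals
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param)
        fh.write(data.tobytes())
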