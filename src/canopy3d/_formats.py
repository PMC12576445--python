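"""Minimal readers/writers for the point-cloud formats the pipeline speaks.

LAS support covers version 1.2, point record formats 0-3 (xyz + intensity,
optionally RGB), which is what orchard LiDAR/drone exports use. PLY support
covers ascii and binary_little_endian vertex elements with optional
intensity and red/green/blue properties. Both are deliberately small,
self-contained implementations.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_LAS_HEADER_SIZE = 227
_POINT_RECORD_LEN = {0: 20, 1: 28, 2: 26, 3: 34}


def read_las(path) -> dict:
    """Parse a LAS 1.x file into arrays: coords (m), intensity, rgb."""
    raw = Path(path).read_bytes()
    if raw[:4] != b"LASF":
        raise IOError(f"{path}: missing LASF signature (field: file signature)")
    if len(raw) < _LAS_HEADER_SIZE:
        raise IOError(f"{path}: truncated LAS header")
    offset_to_points = struct.unpack_from("<I", raw, 96)[0]
    fmt_id = raw[104]
    rec_len = struct.unpack_from("<H", raw, 105)[0]
    n_points = struct.unpack_from("<I", raw, 107)[0]
    if fmt_id not in _POINT_RECORD_LEN:
        raise IOError(f"{path}: unsupported point data format {fmt_id}")
    scales = struct.unpack_from("<3d", raw, 131)
    offsets = struct.unpack_from("<3d", raw, 155)

    body = raw[offset_to_points : offset_to_points + n_points * rec_len]
    if len(body) < n_points * rec_len:
        raise IOError(f"{path}: point data truncated (field: point records)")
    rec = np.frombuffer(body, dtype=np.uint8).reshape(n_points, rec_len)
    xyz_i = rec[:, :12].copy().view("<i4").reshape(n_points, 3)
    coords = xyz_i * np.asarray(scales) + np.asarray(offsets)
    intensity = rec[:, 12:14].copy().view("<u2").ravel().astype(np.float64)

    rgb = None
    if fmt_id in (2, 3):
        off = 20 if fmt_id == 2 else 28
        rgb16 = rec[:, off : off + 6].copy().view("<u2").reshape(n_points, 3)
        # LAS RGB is nominally 16-bit; 8-bit writers leave the high byte zero
        rgb = rgb16.astype(np.int64)
        if rgb.size and rgb.max() > 255:
            rgb = rgb // 256
    return {"coords": coords, "intensity": intensity, "rgb": rgb}


def write_las(path, coords: np.ndarray, intensity=None, rgb=None) -> None:
    """Write LAS 1.2; format 0 (intensity only) or 2 (with RGB)."""
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    n = coords.shape[0]
    fmt_id = 2 if rgb is not None else 0
    rec_len = _POINT_RECORD_LEN[fmt_id]

    lo = coords.min(axis=0) if n else np.zeros(3)
    hi = coords.max(axis=0) if n else np.zeros(3)
    scale = np.full(3, 1e-4)  # 0.1 mm quantisation
    offset = lo

    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    header[24] = 1  # version major
    header[25] = 2  # version minor
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)
    header[104] = fmt_id
    struct.pack_into("<H", header, 105, rec_len)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # points by return [0]
    struct.pack_into("<3d", header, 131, *scale)
    struct.pack_into("<3d", header, 155, *offset)
    struct.pack_into("<6d", header, 179, hi[0], lo[0], hi[1], lo[1], hi[2], lo[2])

    rec = np.zeros((n, rec_len), dtype=np.uint8)
    xyz_i = np.round((coords - offset) / scale).astype("<i4")
    rec[:, :12] = xyz_i.view(np.uint8).reshape(n, 12)
    if intensity is not None:
        inten = np.asarray(intensity, dtype=np.float64).ravel()
        scale16 = inten * 65535 if inten.size and inten.max() <= 1.0 else inten
        rec[:, 12:14] = (
            np.clip(scale16, 0, 65535).astype("<u2").view(np.uint8).reshape(n, 2)
        )
    if rgb is not None:
        rgb16 = (np.asarray(rgb, dtype=np.int64).reshape(-1, 3) * 256).astype("<u2")
        rec[:, 20:26] = rgb16.view(np.uint8).reshape(n, 6)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------- PLY

def write_ply(path, coords: np.ndarray, intensity=None, rgb=None) -> None:
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    n = coords.shape[0]
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {n}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if intensity is not None:
        lines.append("property double intensity")
    if rgb is not None:
        lines += [
            "property uchar red",
            "property uchar green",
            "property uchar blue",
        ]
    lines += ["end_header"]
    inten = None if intensity is None else np.asarray(intensity, dtype=np.float64).ravel()
    colours = None if rgb is None else np.asarray(rgb, dtype=np.int64).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for i in range(n):
            vals = [f"{v:.10g}" for v in coords[i]]
            if inten is not None:
                vals.append(f"{inten[i]:.10g}")
            if colours is not None:
                vals += [str(int(v)) for v in colours[i]]
            fh.write(" ".join(vals) + "\n")


def read_ply(path) -> dict:
    with open(path, "rb") as fh:
        data = fh.read()
    try:
        header_end = data.index(b"end_header")
    except ValueError:
        raise IOError(f"{path}: no end_header (field: PLY header)")
    header = data[:header_end].decode("ascii", errors="replace").splitlines()
    body = data[header_end:]
    body = body[body.index(b"\n") + 1 :]

    if not header or header[0].strip() != "ply":
        raise IOError(f"{path}: missing 'ply' magic (field: PLY header)")
    fmt = "ascii"
    n_vertex = 0
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header[1:]:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            props.append((tok[1], tok[2]))

    _np_type = {
        "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
        "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
        "short": "<i2", "ushort": "<u2", "int": "<i4", "uint": "<u4",
        "int32": "<i4", "uint32": "<u4",
    }
    names = [p[1] for p in props]
    if fmt == "ascii":
        text = body.decode("ascii")
        arr = np.loadtxt(text.splitlines()[:n_vertex], ndmin=2) if n_vertex else np.zeros((0, len(props)))
        table = {name: arr[:, j] for j, (_, name) in enumerate(props)}
    elif fmt == "binary_little_endian":
        dt = np.dtype([(name, _np_type[t]) for t, name in props])
        rec = np.frombuffer(body, dtype=dt, count=n_vertex)
        table = {name: rec[name].astype(np.float64) for name in names}
    else:
        raise IOError(f"{path}: unsupported PLY format {fmt}")

    for ax in "xyz":
        if ax not in table:
            raise IOError(f"{path}: missing vertex property '{ax}'")
    coords = np.column_stack([table["x"], table["y"], table["z"]])
    intensity = table.get("intensity")
    rgb = None
    if all(c in table for c in ("red", "green", "blue")):
        rgb = np.column_stack(
            [table["red"], table["green"], table["blue"]]
        ).astype(np.int64)
    return {"coords": coords, "intensity": intensity, "rgb": rgb}


# ---------------------------------------------------------------- CSV

def read_csv_cloud(path) -> dict:
    """CSV columns: x,y,z[,intensity][,r,g,b]; header optional."""
    import pandas as pd

    try:
        df = pd.read_csv(path)
        # headerless numeric files: first row parsed as header -> re-read
        if any(_is_number(c) for c in df.columns):
            df = pd.read_csv(path, header=None)
            df.columns = ["x", "y", "z", "intensity", "r", "g", "b"][: df.shape[1]]
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"{path}: unreadable CSV ({exc})") from exc
    cols = {c.lower().strip(): c for c in df.columns}
    for ax in "xyz":
        if ax not in cols:
            raise IOError(f"{path}: missing column '{ax}'")
    coords = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=np.float64)
    intensity = None
    for key in ("intensity", "i"):
        if key in cols:
            intensity = df[cols[key]].to_numpy(dtype=np.float64)
            break
    rgb = None
    for keys in (("r", "g", "b"), ("red", "green", "blue")):
        if all(k in cols for k in keys):
            rgb = df[[cols[k] for k in keys]].to_numpy(dtype=np.int64)
            break
    return {"coords": coords, "intensity": intensity, "rgb": rgb}


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False
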