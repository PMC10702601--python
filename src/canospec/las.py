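"""Minimal LAS 1.2-1.4 point-cloud reader/writer.

Supports point record formats 0-3 and 6-8, with or without RGB, plus the
"Extra Bytes" VLR (LASF_Spec record id 4) used to persist the fused NIR
value, the pseudo-label and the tree id directly in the point records, so
the seven-attribute fused cloud travels as a single artifact.

Writing emits LAS 1.2, point format 2 (RGB) or 0, with a fixed coordinate
scale of 0.001 m; class ids are stored in the standard classification byte.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from .errors import FormatError
from .types import PointCloud

_SCALE = 0.001
HEADER_SIZE_12 = 227
HEADER_SIZE_14 = 375

# base point-record dtypes per format id
_BASE_FIELDS_LEGACY = [
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
    ("flags", "u1"), ("classification", "u1"), ("scan_angle", "i1"),
    ("user_data", "u1"), ("point_source", "<u2"),
]
_BASE_FIELDS_14 = [
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
    ("returns", "u1"), ("flags", "u1"), ("classification", "u1"),
    ("user_data", "u1"), ("scan_angle", "<i2"), ("point_source", "<u2"),
    ("gps_time", "<f8"),
]
_RGB = [("red", "<u2"), ("green", "<u2"), ("blue", "<u2")]


def _point_dtype(fmt: int) -> np.dtype:
    if fmt == 0:
        f = list(_BASE_FIELDS_LEGACY)
    elif fmt == 1:
        f = _BASE_FIELDS_LEGACY + [("gps_time", "<f8")]
    elif fmt == 2:
        f = _BASE_FIELDS_LEGACY + _RGB
    elif fmt == 3:
        f = _BASE_FIELDS_LEGACY + [("gps_time", "<f8")] + _RGB
    elif fmt == 6:
        f = list(_BASE_FIELDS_14)
    elif fmt == 7:
        f = _BASE_FIELDS_14 + _RGB
    elif fmt == 8:
        f = _BASE_FIELDS_14 + _RGB + [("nir_band", "<u2")]
    else:
        raise FormatError(f"unsupported LAS point format {fmt}")
    return np.dtype(f)


# extra-bytes data_type code -> numpy dtype
_EB_TYPES = {1: "u1", 2: "i1", 3: "<u2", 4: "<i2", 5: "<u4",
             6: "<i4", 7: "<u8", 8: "<i8", 9: "<f4", 10: "<f8"}
_EB_CODES = {np.dtype(v).str.lstrip("<"): k for k, v in _EB_TYPES.items()}


def _pack_eb_descriptor(name: str, dtype_code: int) -> bytes:
    rec = struct.pack("<HBB", 0, dtype_code, 0)
    rec += name.encode("ascii").ljust(32, b"\0")
    rec += b"\0" * 4          # unused
    rec += b"\0" * (24 * 5)   # no_data, min, max, scale, offset (unused)
    rec += b"\0" * 32         # description
    assert len(rec) == 192
    return rec


def _parse_eb_payload(payload: bytes) -> list:
    dims = []
    for off in range(0, len(payload) - len(payload) % 192, 192):
        rec = payload[off:off + 192]
        dtype_code = rec[2]
        name = rec[4:36].split(b"\0", 1)[0].decode("ascii", "replace")
        if dtype_code not in _EB_TYPES:
            raise FormatError(f"unsupported extra-bytes data type {dtype_code}")
        dims.append((name, _EB_TYPES[dtype_code]))
    return dims


def write_las(cloud: PointCloud, path) -> None:
    """Write ``cloud`` as LAS 1.2 (format 2 with RGB, else format 0).

    XYZ are quantized at 0.001 m; nir, label and tree_id (when present) are
    appended as extra-bytes dimensions named "nir", "label", "tree_id".
    """
    n = len(cloud)
    if n == 0:
        raise FormatError("refusing to write an empty point cloud")
    fmt = 2 if cloud.has_rgb else 0
    base_dtype = _point_dtype(fmt)

    extra = []
    if cloud.nir is not None:
        extra.append(("nir", "<f8", 10, cloud.nir))
    if cloud.nir_true is not None:
        extra.append(("nir_true", "<f8", 10, cloud.nir_true))
    if cloud.label is not None:
        extra.append(("label", "u1", 1, cloud.label))
    if cloud.tree_id is not None:
        extra.append(("tree_id", "<u4", 5, cloud.tree_id))

    dtype = np.dtype(base_dtype.descr + [(nm, dt) for nm, dt, _, _ in extra])
    rec = np.zeros(n, dtype=dtype)
    offset = (cloud.x.min(), cloud.y.min(), cloud.z.min())
    rec["X"] = np.round((cloud.x - offset[0]) / _SCALE).astype(np.int64)
    rec["Y"] = np.round((cloud.y - offset[1]) / _SCALE).astype(np.int64)
    rec["Z"] = np.round((cloud.z - offset[2]) / _SCALE).astype(np.int64)
    rec["flags"] = 0x09  # single return: return number 1 of 1
    if cloud.class_id is not None:
        rec["classification"] = cloud.class_id.astype(np.uint8)
    if fmt == 2:
        rec["red"] = np.clip(cloud.r, 0, 65535).astype(np.uint16)
        rec["green"] = np.clip(cloud.g, 0, 65535).astype(np.uint16)
        rec["blue"] = np.clip(cloud.b, 0, 65535).astype(np.uint16)
    for nm, _, _, vals in extra:
        rec[nm] = vals

    vlrs = b""
    n_vlrs = 0
    if extra:
        payload = b"".join(_pack_eb_descriptor(nm, code) for nm, _, code, _ in extra)
        vlr_header = struct.pack("<H16sHH32s", 0, b"LASF_Spec", 4, len(payload), b"extra bytes")
        vlrs = vlr_header + payload
        n_vlrs = 1

    offset_to_points = HEADER_SIZE_12 + len(vlrs)
    header = bytearray(HEADER_SIZE_12)
    header[0:4] = b"LASF"
    header[24] = 1
    header[25] = 2
    header[26:26 + 8] = b"canospec"
    header[58:58 + 8] = b"canospec"
    struct.pack_into("<HH", header, 90, 1, 2000)  # file day/year (nominal)
    struct.pack_into("<H", header, 94, HEADER_SIZE_12)
    struct.pack_into("<I", header, 96, offset_to_points)
    struct.pack_into("<I", header, 100, n_vlrs)
    header[104] = fmt
    struct.pack_into("<H", header, 105, dtype.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<5I", header, 111, n, 0, 0, 0, 0)
    struct.pack_into("<3d", header, 131, _SCALE, _SCALE, _SCALE)
    struct.pack_into("<3d", header, 155, *offset)
    struct.pack_into(
        "<6d", header, 179,
        cloud.x.max(), cloud.x.min(), cloud.y.max(),
        cloud.y.min(), cloud.z.max(), cloud.z.min(),
    )

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(vlrs)
        fh.write(rec.tobytes())


def read_las(path) -> PointCloud:
    """Read a LAS 1.2-1.4 file (point formats 0-3, 6-8).

    Coordinates are descaled to meters. RGB is attached when the format
    carries it; extra-bytes dimensions named "nir", "label" and "tree_id"
    are mapped onto the corresponding cloud attributes, and a nonzero
    classification byte onto ``class_id``.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such LAS file: {path}")
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < HEADER_SIZE_12 or data[0:4] != b"LASF":
        raise FormatError(f"not a LAS file: {path}")
    major, minor = data[24], data[25]
    if (major, minor) < (1, 1) or (major, minor) > (1, 4):
        raise FormatError(f"unsupported LAS version {major}.{minor}")
    header_size, = struct.unpack_from("<H", data, 94)
    offset_to_points, = struct.unpack_from("<I", data, 96)
    n_vlrs, = struct.unpack_from("<I", data, 100)
    fmt = data[104] & 0x3F
    rec_len, = struct.unpack_from("<H", data, 105)
    n_legacy, = struct.unpack_from("<I", data, 107)
    scales = struct.unpack_from("<3d", data, 131)
    offsets = struct.unpack_from("<3d", data, 155)
    n_points = n_legacy
    if minor == 4:
        n64, = struct.unpack_from("<Q", data, 247)
        if n64:
            n_points = n64

    base_dtype = _point_dtype(fmt)  # raises on unsupported formats

    extra_dims = []
    pos = header_size
    for _ in range(n_vlrs):
        _, user_id, record_id, rec_len_after, _ = struct.unpack_from("<H16sHH32s", data, pos)
        pos += 54
        payload = data[pos:pos + rec_len_after]
        pos += rec_len_after
        if user_id.rstrip(b"\0") == b"LASF_Spec" and record_id == 4:
            extra_dims = _parse_eb_payload(payload)

    n_extra_bytes = rec_len - base_dtype.itemsize
    if n_extra_bytes < 0:
        raise FormatError(f"point record length {rec_len} below format {fmt} minimum")
    declared = sum(np.dtype(dt).itemsize for _, dt in extra_dims)
    fields = list(base_dtype.descr) + [(nm, dt) for nm, dt in extra_dims]
    if declared < n_extra_bytes:  # undocumented trailing bytes
        fields.append(("_pad", f"V{n_extra_bytes - declared}"))
    dtype = np.dtype(fields)
    if dtype.itemsize != rec_len:
        raise FormatError("extra-bytes descriptors disagree with record length")

    rec = np.frombuffer(data, dtype=dtype, count=n_points, offset=offset_to_points)

    kw = {
        "x": rec["X"] * scales[0] + offsets[0],
        "y": rec["Y"] * scales[1] + offsets[1],
        "z": rec["Z"] * scales[2] + offsets[2],
    }
    if "red" in rec.dtype.names:
        kw["r"] = rec["red"].astype(np.float64)
        kw["g"] = rec["green"].astype(np.float64)
        kw["b"] = rec["blue"].astype(np.float64)
    cls = rec["classification"].astype(np.int64)
    if fmt < 6:
        cls = cls & 0x1F
    if np.any(cls):
        kw["class_id"] = cls
    names = {nm for nm, _ in extra_dims}
    if "nir" in names:
        kw["nir"] = rec["nir"].astype(np.float64)
    if "nir_true" in names:
        kw["nir_true"] = rec["nir_true"].astype(np.float64)
    if "label" in names:
        kw["label"] = rec["label"].astype(np.int64)
    if "tree_id" in names:
        kw["tree_id"] = rec["tree_id"].astype(np.int64)
    return PointCloud(**kw)
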