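"""ROI file I/O and result tables.

Reads polygon ROIs from ImageJ/Fiji ``.roi`` binary files (read-only) and
from a portable polygon-JSON dialect (read/write), and writes entropy
results as CSV or JSON.

The polygon-JSON dialect is a single object::

    {"name": "lesion", "vertices": [[x1, y1], [x2, y2], ...]}

with vertices in continuous pixel coordinates, round-tripped at full float
precision.
"""

from __future__ import annotations

import csv
import io
import json
import struct
from pathlib import Path
from typing import Iterable, List, Sequence, Union

from .core import EntropyResult, RelativeEntropyResult
from .errors import InvalidPolygonError, RoiFormatError, UnsupportedRoiTypeError
from .imaging import PolygonROI

__all__ = [
    "read_imagej_roi",
    "read_roi_file",
    "read_polygon_json",
    "write_polygon_json",
    "load_roi",
    "write_results",
]

_HEADER_SIZE = 64
_MAGIC = b"Iout"

# ROI type byte at offset 6 of the header.
_ROI_TYPE_NAMES = {
    0: "polygon",
    1: "rect",
    2: "oval",
    3: "line",
    4: "freeline",
    5: "polyline",
    6: "noRoi",
    7: "freehand",
    8: "traced",
    9: "angle",
    10: "point",
}
_POLYGON_TYPES = (0, 7)  # polygon, freehand-as-polygon

_OPT_SUBPIXEL = 128  # options bit: float coordinate block present


def read_imagej_roi(data: bytes) -> PolygonROI:
    """Decode an ImageJ ``.roi`` byte stream into a PolygonROI.

    Layout (big-endian): 64-byte header starting with the magic ``Iout``;
    the ROI type byte at offset 6; bounding box shorts (top, left, bottom,
    right) at 8..15; the vertex count at 16; the options bitfield at 50; the
    header2 offset at 60. Vertex data follows the header as ``n`` shorts of
    x offsets then ``n`` shorts of y offsets relative to (left, top). When
    the sub-pixel option bit is set (and the version supports it), ``2n``
    big-endian floats of absolute x then y coordinates follow and take
    precedence. The ROI name, when present, is UTF-16BE text located via
    header2.

    Only polygon and freehand types are accepted; other types raise
    :class:`UnsupportedRoiTypeError` naming the type found.
    """
    if len(data) < _HEADER_SIZE or data[:4] != _MAGIC:
        raise RoiFormatError(
            "not an ImageJ .roi file (missing 'Iout' magic or truncated header)"
        )
    version = struct.unpack(">h", data[4:6])[0]
    roi_type = data[6]
    if roi_type not in _POLYGON_TYPES:
        type_name = _ROI_TYPE_NAMES.get(roi_type, f"unknown({roi_type})")
        raise UnsupportedRoiTypeError(
            f"unsupported ROI type {type_name!r}; only polygon and freehand "
            "selections are supported"
        )
    top, left, _bottom, _right = struct.unpack(">4h", data[8:16])
    n = struct.unpack(">H", data[16:18])[0]
    if n < 3:
        raise InvalidPolygonError(f".roi file encodes only {n} vertices")
    options = struct.unpack(">H", data[50:52])[0]
    subpixel = bool(options & _OPT_SUBPIXEL) and version >= 222

    need = _HEADER_SIZE + 4 * n + (8 * n if subpixel else 0)
    if len(data) < need:
        raise RoiFormatError(
            f"truncated .roi file: need {need} bytes for {n} vertices, have {len(data)}"
        )

    off = _HEADER_SIZE
    if subpixel:
        off += 4 * n  # skip the integer block
        xf = struct.unpack(f">{n}f", data[off : off + 4 * n])
        yf = struct.unpack(f">{n}f", data[off + 4 * n : off + 8 * n])
        vertices = tuple(zip(xf, yf))
    else:
        xi = struct.unpack(f">{n}h", data[off : off + 2 * n])
        yi = struct.unpack(f">{n}h", data[off + 2 * n : off + 4 * n])
        vertices = tuple((left + x, top + y) for x, y in zip(xi, yi))

    name = _read_name(data)
    return PolygonROI(vertices=vertices, name=name)


def _read_name(data: bytes) -> str:
    hdr2 = struct.unpack(">i", data[60:64])[0]
    if hdr2 <= 0 or hdr2 + 24 > len(data):
        return ""
    name_off = struct.unpack(">i", data[hdr2 + 16 : hdr2 + 20])[0]
    name_len = struct.unpack(">i", data[hdr2 + 20 : hdr2 + 24])[0]
    if name_off <= 0 or name_len <= 0 or name_off + 2 * name_len > len(data):
        return ""
    raw = data[name_off : name_off + 2 * name_len]
    try:
        return raw.decode("utf-16-be")
    except UnicodeDecodeError:
        return ""


def read_roi_file(path: Union[str, Path]) -> PolygonROI:
    """Read an ImageJ ``.roi`` file from disk."""
    roi = read_imagej_roi(Path(path).read_bytes())
    if not roi.name:
        roi = PolygonROI(roi.vertices, name=Path(path).stem)
    return roi


def read_polygon_json(text: str) -> PolygonROI:
    """Parse the polygon-JSON dialect into a PolygonROI."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise InvalidPolygonError(f"polygon JSON does not parse: {exc}") from exc
    if not isinstance(obj, dict) or "vertices" not in obj:
        raise InvalidPolygonError("polygon JSON must be an object with a 'vertices' field")
    raw = obj["vertices"]
    if not isinstance(raw, list):
        raise InvalidPolygonError("'vertices' must be a list of [x, y] pairs")
    vertices = []
    for item in raw:
        if (
            not isinstance(item, (list, tuple))
            or len(item) != 2
            or not all(isinstance(c, (int, float)) and not isinstance(c, bool) for c in item)
        ):
            raise InvalidPolygonError(f"vertex {item!r} is not a numeric [x, y] pair")
        vertices.append((float(item[0]), float(item[1])))
    return PolygonROI(tuple(vertices), name=str(obj.get("name", "")))


def write_polygon_json(roi: PolygonROI) -> str:
    """Serialize a PolygonROI to the polygon-JSON dialect (lossless)."""
    return json.dumps(
        {"name": roi.name, "vertices": [[x, y] for x, y in roi.vertices]}
    )


def load_roi(path: Union[str, Path]) -> PolygonROI:
    """Load an ROI from disk, dispatching on extension (.roi binary, else JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".roi":
        return read_roi_file(path)
    roi = read_polygon_json(path.read_text())
    if not roi.name:
        roi = PolygonROI(roi.vertices, name=path.stem)
    return roi


_CSV_COLUMNS = ["label", "roi_pixels", "h_bits", "delta_h_bits"]


def write_results(
    records: Sequence[Union[EntropyResult, RelativeEntropyResult]],
    fmt: str = "csv",
) -> str:
    """Render results as a table mirroring the lesion/control report layout.

    CSV columns are label, roi_pixels, h_bits, delta_h_bits (one ROI per
    row); the dH cell is filled on lesion rows by matching each
    RelativeEntropyResult's lesion label, and left empty for control rows.
    H and dH display with 2 decimals in CSV; JSON keeps full precision plus
    the processing provenance (grayscale method, bin count).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    entropies: List[EntropyResult] = [r for r in records if isinstance(r, EntropyResult)]
    deltas: List[RelativeEntropyResult] = [
        r for r in records if isinstance(r, RelativeEntropyResult)
    ]
    if len(entropies) + len(deltas) != len(records):
        raise TypeError("records must be EntropyResult or RelativeEntropyResult")

    if fmt == "json":
        out = []
        for r in records:
            d = r.to_dict()
            d["record_type"] = (
                "roi_entropy" if isinstance(r, EntropyResult) else "relative_entropy"
            )
            out.append(d)
        return json.dumps(out, indent=2)

    if fmt != "csv":
        raise ValueError(f"unknown output format {fmt!r}; choose 'csv' or 'json'")

    delta_by_lesion = {}
    for d in deltas:
        delta_by_lesion[d.lesion_label] = d
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_CSV_COLUMNS)
    for r in entropies:
        d = delta_by_lesion.pop(r.label, None)
        writer.writerow(
            [
                r.label,
                r.roi_pixels,
                f"{r.h_bits:.2f}",
                f"{d.delta_h_bits:+.2f}" if d is not None else "",
            ]
        )
    # dH rows whose lesion has no entropy row of its own still appear
    for d in delta_by_lesion.values():
        writer.writerow([d.lesion_label, "", "", f"{d.delta_h_bits:+.2f}"])
    return buf.getvalue()
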