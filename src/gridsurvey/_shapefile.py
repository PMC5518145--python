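"""Tiny ESRI shapefile (polygon) writer/reader — just enough for PSU output.

Writes the .shp/.shx/.dbf triple for polygon features with numeric and text
attributes.  Only what the PSU layer needs is implemented: one outer ring
per part, no M/Z values, Latin-1 field names <= 10 characters.  The reader
exists to round-trip our own output in tests.
"""

from __future__ import annotations

import struct
from pathlib import Path

__all__ = ["write_polygon_shapefile", "read_polygon_shapefile"]

_SHP_POLYGON = 5


def _rings_bbox(rings):
    xs = [x for ring in rings for x, _ in ring]
    ys = [y for ring in rings for _, y in ring]
    return min(xs), min(ys), max(xs), max(ys)


def _polygon_record(rings) -> bytes:
    """Encode one polygon shape record content (type 5)."""
    xmin, ymin, xmax, ymax = _rings_bbox(rings)
    num_points = sum(len(r) for r in rings)
    buf = struct.pack("<i4d", _SHP_POLYGON, xmin, ymin, xmax, ymax)
    buf += struct.pack("<2i", len(rings), num_points)
    offset = 0
    for ring in rings:
        buf += struct.pack("<i", offset)
        offset += len(ring)
    for ring in rings:
        for x, y in ring:
            buf += struct.pack("<2d", x, y)
    return buf


def write_polygon_shapefile(path, geometries, fields, records) -> None:
    """Write polygons + attribute table.

    geometries: list of ring lists; each ring a list of (x, y), closed,
    outer rings in clockwise order per the shapefile convention.
    fields: list of (name, kind, width, decimals) with kind in {"N", "C"}.
    records: list of per-feature value tuples aligned with ``fields``.
    """
    path = Path(path)
    shp_records = []
    bboxes = []
    for rings in geometries:
        shp_records.append(_polygon_record(rings))
        bboxes.append(_rings_bbox(rings))
    xmin = min(b[0] for b in bboxes)
    ymin = min(b[1] for b in bboxes)
    xmax = max(b[2] for b in bboxes)
    ymax = max(b[3] for b in bboxes)

    def header(file_length_words: int) -> bytes:
        head = struct.pack(">i5ii", 9994, 0, 0, 0, 0, 0, file_length_words)
        head += struct.pack("<2i", 1000, _SHP_POLYGON)
        head += struct.pack("<8d", xmin, ymin, xmax, ymax, 0, 0, 0, 0)
        return head

    shp_body = b""
    shx_body = b""
    offset_words = 50  # header is 100 bytes = 50 words
    for i, content in enumerate(shp_records, start=1):
        length_words = len(content) // 2
        shp_body += struct.pack(">2i", i, length_words) + content
        shx_body += struct.pack(">2i", offset_words, length_words)
        offset_words += 4 + length_words

    with open(path.with_suffix(".shp"), "wb") as fh:
        fh.write(header(50 + len(shp_body) // 2))
        fh.write(shp_body)
    with open(path.with_suffix(".shx"), "wb") as fh:
        fh.write(header(50 + len(shx_body) // 2))
        fh.write(shx_body)
    _write_dbf(path.with_suffix(".dbf"), fields, records)


def _write_dbf(path, fields, records) -> None:
    record_len = 1 + sum(w for _, _, w, _ in fields)
    header_len = 32 + 32 * len(fields) + 1
    head = struct.pack(
        "<B3BIHH20x", 0x03, 26, 1, 1, len(records), header_len, record_len
    )
    descriptors = b""
    for name, kind, width, decimals in fields:
        if len(name) > 10:
            raise ValueError(f"dbf field name too long: {name}")
        descriptors += struct.pack(
            "<11sc4xBB14x", name.encode("ascii"), kind.encode("ascii"), width, decimals
        )
    body = b""
    for rec in records:
        body += b" "
        for (name, kind, width, decimals), value in zip(fields, rec):
            if kind == "N":
                if decimals:
                    text = f"{float(value):.{decimals}f}"
                else:
                    text = str(int(value))
                body += text.rjust(width).encode("ascii")[:width]
            else:
                body += str(value).ljust(width).encode("latin-1")[:width]
    with open(path, "wb") as fh:
        fh.write(head + descriptors + b"\x0d" + body + b"\x1a")


def read_polygon_shapefile(path):
    """Read back (geometries, fields, records) written by this module."""
    path = Path(path)
    geometries = []
    with open(path.with_suffix(".shp"), "rb") as fh:
        data = fh.read()
    pos = 100
    while pos < len(data):
        (_, length_words) = struct.unpack(">2i", data[pos : pos + 8])
        content = data[pos + 8 : pos + 8 + length_words * 2]
        pos += 8 + length_words * 2
        shape_type = struct.unpack("<i", content[:4])[0]
        if shape_type != _SHP_POLYGON:
            raise ValueError(f"unsupported shape type {shape_type}")
        num_parts, num_points = struct.unpack("<2i", content[36:44])
        part_idx = list(struct.unpack(f"<{num_parts}i", content[44 : 44 + 4 * num_parts]))
        pts_raw = content[44 + 4 * num_parts :]
        pts = [
            struct.unpack("<2d", pts_raw[i * 16 : i * 16 + 16]) for i in range(num_points)
        ]
        part_idx.append(num_points)
        geometries.append(
            [pts[part_idx[i] : part_idx[i + 1]] for i in range(num_parts)]
        )

    with open(path.with_suffix(".dbf"), "rb") as fh:
        dbf = fh.read()
    n_records, header_len, record_len = struct.unpack("<IHH", dbf[4:12])
    fields = []
    pos = 32
    while dbf[pos] != 0x0D:
        name = dbf[pos : pos + 11].split(b"\x00")[0].decode("ascii")
        kind = chr(dbf[pos + 11])
        width, decimals = dbf[pos + 16], dbf[pos + 17]
        fields.append((name, kind, width, decimals))
        pos += 32
    records = []
    pos = header_len
    for _ in range(n_records):
        rec = []
        cursor = pos + 1
        for name, kind, width, decimals in fields:
            raw = dbf[cursor : cursor + width].decode("latin-1").strip()
            cursor += width
            if kind == "N":
                rec.append(float(raw) if decimals else int(raw))
            else:
                rec.append(raw)
        records.append(tuple(rec))
        pos += record_len
    return geometries, fields, records
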