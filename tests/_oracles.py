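"""Independent reference implementations used only as test oracles.

These are deliberately written from first principles (scalar loops, direct
formulas) and share no code with the package, so agreement is evidence and
not tautology.
"""

import math
import struct


def point_in_polygon(x, y, vertices):
    """Classic pnpoly even-odd ray cast for a single point."""
    inside = False
    j = len(vertices) - 1
    for i in range(len(vertices)):
        xi, yi = vertices[i]
        xj, yj = vertices[j]
        if (yi > y) != (yj > y):
            x_cross = xi + (y - yi) * (xj - xi) / (yj - yi)
            if x < x_cross:
                inside = not inside
        j = i
    return inside


def rasterize_oracle(vertices, width, height):
    """Boolean mask from per-pixel-center ray casting."""
    return [
        [point_in_polygon(c + 0.5, r + 0.5, vertices) for c in range(width)]
        for r in range(height)
    ]


def pixel_entropy_oracle(values):
    """Entropy in bits from a flat iterable of pixel values, tallied directly."""
    freq = {}
    n = 0
    for v in values:
        freq[v] = freq.get(v, 0) + 1
        n += 1
    h = 0.0
    for count in freq.values():
        f = count / n
        h -= f * math.log2(f)
    return h


def encode_imagej_roi(vertices, roi_type=0, name="", subpixel=False, version=228):
    """Independent ImageJ .roi encoder, written directly from the published
    byte layout (big-endian 64-byte header, 'Iout' magic, type byte at 6,
    bounding box at 8, n at 16, options at 50, header2 offset at 60;
    integer x-then-y offsets after the header; absolute float coordinates
    after those when the sub-pixel option bit 128 is set; name as UTF-16BE
    located through header2 offsets 16/20)."""
    n = len(vertices)
    xs = [v[0] for v in vertices]
    ys = [v[1] for v in vertices]
    left = int(math.floor(min(xs)))
    top = int(math.floor(min(ys)))
    right = int(math.ceil(max(xs)))
    bottom = int(math.ceil(max(ys)))

    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, version)
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    struct.pack_into(">H", header, 50, 128 if subpixel else 0)

    body = bytearray()
    for x in xs:
        body += struct.pack(">h", int(round(x)) - left)
    for y in ys:
        body += struct.pack(">h", int(round(y)) - top)
    if subpixel:
        for x in xs:
            body += struct.pack(">f", x)
        for y in ys:
            body += struct.pack(">f", y)

    tail = b""
    if name:
        hdr2_off = 64 + len(body)
        struct.pack_into(">i", header, 60, hdr2_off)
        hdr2 = bytearray(64)
        struct.pack_into(">i", hdr2, 16, hdr2_off + 64)  # name offset
        struct.pack_into(">i", hdr2, 20, len(name))      # name length in chars
        tail = bytes(hdr2) + name.encode("utf-16-be")

    return bytes(header) + bytes(body) + tail
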