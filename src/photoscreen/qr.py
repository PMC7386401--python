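"""Minimal QR symbology for the scale fiducial (ISO/IEC 18004 subset).

The screening protocol uses a QR code of known physical edge length, shown on
a phone at the examinee's forehead, as the frontal-plane scale reference.
This module provides just enough of the symbology for that role:

* **encode**: byte mode, versions 1-5, error-correction level L, mask
  pattern 0 — produces a standard module matrix any QR reader can decode;
* **decode**: a frontal, upright-symbol reader (run-length finder-pattern
  location, grid sampling, Reed-Solomon verification with single-error
  correction) that also reports the symbol's corner points in pixels, which
  is what the scale calibration actually needs.

Perspective distortion and rotated symbols are out of scope: the capture
protocol holds the fiducial in the frontal plane, facing the camera.
"""

from __future__ import annotations

import numpy as np

from .errors import ScaleDecodeError, ValidationError

# ----------------------------------------------------------------------------
# GF(256) arithmetic (polynomial 0x11d), Reed-Solomon over codewords
# ----------------------------------------------------------------------------

_EXP = np.zeros(512, dtype=np.int64)
_LOG = np.zeros(256, dtype=np.int64)
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
_EXP[255:510] = _EXP[:255]


def _gmul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_EXP[_LOG[a] + _LOG[b]])


def _poly_eval(poly, x: int) -> int:
    # poly[0] is the highest-degree coefficient
    y = 0
    for c in poly:
        y = _gmul(y, x) ^ c
    return y


def rs_encode(data: list[int], n_ec: int) -> list[int]:
    """Return ``n_ec`` Reed-Solomon parity codewords for ``data``."""
    gen = [1]
    for i in range(n_ec):
        # multiply gen by (x - alpha^i)
        nxt = [0] * (len(gen) + 1)
        for j, g in enumerate(gen):
            nxt[j] ^= _gmul(g, 1)
            nxt[j + 1] ^= _gmul(g, int(_EXP[i]))
        gen = nxt
    rem = list(data) + [0] * n_ec
    for i in range(len(data)):
        coef = rem[i]
        if coef != 0:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gmul(gen[j], coef)
    return rem[len(data):]


def rs_check_and_correct(codewords: list[int], n_ec: int) -> list[int]:
    """Verify a codeword block; correct at most one symbol error.

    Returns the (possibly corrected) block.  Raises ScaleDecodeError if the
    syndromes indicate more corruption than a single-symbol error.
    """
    synd = [_poly_eval(codewords, int(_EXP[i])) for i in range(n_ec)]
    if not any(synd):
        return codewords
    if synd[0] == 0:
        raise ScaleDecodeError("QR payload fails Reed-Solomon check")
    # single error at coefficient position j with magnitude e:
    # s_i = e * (alpha^j)^i  =>  j = log(s1) - log(s0), e = s0
    e = synd[0]
    if synd[1] == 0:
        raise ScaleDecodeError("QR payload fails Reed-Solomon check")
    j = (int(_LOG[synd[1]]) - int(_LOG[synd[0]])) % 255
    if j >= len(codewords):
        raise ScaleDecodeError("QR payload fails Reed-Solomon check")
    for i, s in enumerate(synd):
        if s != _gmul(e, int(_EXP[(i * j) % 255])):
            raise ScaleDecodeError(
                "QR payload fails Reed-Solomon check (multi-symbol error)"
            )
    out = list(codewords)
    out[len(codewords) - 1 - j] ^= e
    return out


# ----------------------------------------------------------------------------
# Symbol structure tables (versions 1-5, EC level L: one block each)
# ----------------------------------------------------------------------------

_DATA_CODEWORDS = {1: 19, 2: 34, 3: 55, 4: 80, 5: 108}
_EC_CODEWORDS = {1: 7, 2: 10, 3: 15, 4: 20, 5: 26}
_ALIGN_CENTERS = {1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30]}

_MASKS = {
    0: lambda r, c: (r + c) % 2 == 0,
    1: lambda r, c: r % 2 == 0,
    2: lambda r, c: c % 3 == 0,
    3: lambda r, c: (r + c) % 3 == 0,
    4: lambda r, c: (r // 2 + c // 3) % 2 == 0,
    5: lambda r, c: (r * c) % 2 + (r * c) % 3 == 0,
    6: lambda r, c: ((r * c) % 2 + (r * c) % 3) % 2 == 0,
    7: lambda r, c: ((r + c) % 2 + (r * c) % 3) % 2 == 0,
}

_EC_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}


def _format_value(ec: str, mask: int) -> int:
    val = (_EC_BITS[ec] << 3) | mask
    # BCH(15,5), generator x^10+x^8+x^5+x^4+x^2+x+1 (0x537), XOR mask 0x5412
    rem = val << 10
    for i in range(14, 9, -1):
        if rem & (1 << i):
            rem ^= 0x537 << (i - 10)
    return ((val << 10) | rem) ^ 0x5412


_ALL_FORMATS = {
    _format_value(ec, m): (ec, m) for ec in _EC_BITS for m in range(8)
}


def _format_positions(size: int):
    """Module positions of the 15 format bits (LSB first), both copies."""
    copy1 = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
             (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]
    copy2 = [(size - 1, 8), (size - 2, 8), (size - 3, 8), (size - 4, 8),
             (size - 5, 8), (size - 6, 8), (size - 7, 8),
             (8, size - 8), (8, size - 7), (8, size - 6), (8, size - 5),
             (8, size - 4), (8, size - 3), (8, size - 2), (8, size - 1)]
    return copy1, copy2


def _function_mask(version: int) -> np.ndarray:
    """Boolean map of function modules (finders, timing, alignment, format)."""
    size = 17 + 4 * version
    func = np.zeros((size, size), dtype=bool)
    for r0, c0 in [(0, 0), (0, size - 8), (size - 8, 0)]:
        func[r0:r0 + 8, c0:c0 + 8] = True  # finder + separator
    func[6, :] = True
    func[:, 6] = True
    for cy in _ALIGN_CENTERS[version]:
        for cx in _ALIGN_CENTERS[version]:
            if func[cy, cx]:
                continue  # overlaps a finder
            func[cy - 2:cy + 3, cx - 2:cx + 3] = True
    for pos in _format_positions(size)[0] + _format_positions(size)[1]:
        func[pos] = True
    func[size - 8, 8] = True  # dark module
    return func


def _data_positions(version: int) -> list[tuple[int, int]]:
    """Module coordinates in codeword placement order (zigzag, col pairs)."""
    size = 17 + 4 * version
    func = _function_mask(version)
    positions = []
    col = size - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(size - 1, -1, -1) if upward else range(size)
        for row in rows:
            for c in (col, col - 1):
                if not func[row, c]:
                    positions.append((row, c))
        upward = not upward
        col -= 2
    return positions


def _draw_function_patterns(mat: np.ndarray, version: int) -> None:
    size = mat.shape[0]
    finder = np.array([
        [1, 1, 1, 1, 1, 1, 1],
        [1, 0, 0, 0, 0, 0, 1],
        [1, 0, 1, 1, 1, 0, 1],
        [1, 0, 1, 1, 1, 0, 1],
        [1, 0, 1, 1, 1, 0, 1],
        [1, 0, 0, 0, 0, 0, 1],
        [1, 1, 1, 1, 1, 1, 1],
    ], dtype=bool)
    for r0, c0 in [(0, 0), (0, size - 7), (size - 7, 0)]:
        mat[r0:r0 + 7, c0:c0 + 7] = finder
    for i in range(8, size - 8):
        mat[6, i] = i % 2 == 0
        mat[i, 6] = i % 2 == 0
    align = np.array([
        [1, 1, 1, 1, 1],
        [1, 0, 0, 0, 1],
        [1, 0, 1, 0, 1],
        [1, 0, 0, 0, 1],
        [1, 1, 1, 1, 1],
    ], dtype=bool)
    fm = np.zeros((size, size), dtype=bool)
    for r0, c0 in [(0, 0), (0, size - 8), (size - 8, 0)]:
        fm[r0:r0 + 8, c0:c0 + 8] = True
    for cy in _ALIGN_CENTERS[version]:
        for cx in _ALIGN_CENTERS[version]:
            if fm[cy, cx]:
                continue
            mat[cy - 2:cy + 3, cx - 2:cx + 3] = align
    mat[size - 8, 8] = True  # dark module


def encode(payload: str | bytes, version: int | None = None,
           mask: int = 0) -> np.ndarray:
    """Encode ``payload`` (byte mode, EC level L) into a module matrix.

    Returns a (size, size) boolean array, True = dark module.  ``version``
    is chosen automatically (smallest of 1-5 that fits) when None.
    """
    data = payload.encode("utf-8") if isinstance(payload, str) else bytes(payload)
    if version is None:
        for v in sorted(_DATA_CODEWORDS):
            if 4 + 8 + 8 * len(data) <= 8 * _DATA_CODEWORDS[v]:
                version = v
                break
        else:
            raise ValidationError(
                f"payload of {len(data)} bytes exceeds the supported "
                f"symbol capacity ({_DATA_CODEWORDS[max(_DATA_CODEWORDS)] - 2} bytes)"
            )
    if version not in _DATA_CODEWORDS:
        raise ValidationError(f"version must be in 1..5, got {version}")
    n_data = _DATA_CODEWORDS[version]
    if 4 + 8 + 8 * len(data) > 8 * n_data:
        raise ValidationError(
            f"payload of {len(data)} bytes does not fit in version {version}"
        )

    bits: list[int] = []

    def put(value: int, n: int):
        bits.extend((value >> (n - 1 - i)) & 1 for i in range(n))

    put(0b0100, 4)            # byte mode
    put(len(data), 8)         # character count (versions 1-9)
    for b in data:
        put(b, 8)
    put(0, min(4, 8 * n_data - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    pad = (0xEC, 0x11)
    while len(codewords) < n_data:
        codewords.append(pad[(len(codewords) - len(bits) // 8) % 2])
    codewords += rs_encode(codewords, _EC_CODEWORDS[version])

    size = 17 + 4 * version
    mat = np.zeros((size, size), dtype=bool)
    _draw_function_patterns(mat, version)

    stream = []
    for cw in codewords:
        stream.extend((cw >> (7 - i)) & 1 for i in range(8))
    mask_fn = _MASKS[mask]
    for (r, c), bit in zip(_data_positions(version), stream):
        mat[r, c] = bool(bit) ^ mask_fn(r, c)

    fmt = _format_value("L", mask)
    c1, c2 = _format_positions(size)
    for i in range(15):
        bit = bool((fmt >> i) & 1)
        mat[c1[i]] = bit
        mat[c2[i]] = bit
    return mat


# ----------------------------------------------------------------------------
# Decoding
# ----------------------------------------------------------------------------

def decode_matrix(mat: np.ndarray) -> str:
    """Decode a sampled module matrix (True = dark) back to its payload."""
    size = mat.shape[0]
    version = (size - 17) // 4
    if size != 17 + 4 * version or version not in _DATA_CODEWORDS:
        raise ScaleDecodeError(f"invalid symbol size {size}")
    c1, c2 = _format_positions(size)
    ec = mask = None
    for copy in (c1, c2):
        fmt = sum(int(bool(mat[copy[i]])) << i for i in range(15))
        best = min(_ALL_FORMATS, key=lambda v: bin(v ^ fmt).count("1"))
        if bin(best ^ fmt).count("1") <= 3:
            ec, mask = _ALL_FORMATS[best]
            break
    if mask is None:
        raise ScaleDecodeError("QR format information unreadable")
    if ec != "L":
        raise ScaleDecodeError(f"unsupported error-correction level {ec}")

    mask_fn = _MASKS[mask]
    n_total = _DATA_CODEWORDS[version] + _EC_CODEWORDS[version]
    bits = [
        int(bool(mat[r, c]) ^ mask_fn(r, c))
        for r, c in _data_positions(version)[: 8 * n_total]
    ]
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    codewords = rs_check_and_correct(codewords, _EC_CODEWORDS[version])
    data_cw = codewords[: _DATA_CODEWORDS[version]]

    stream = []
    for cw in data_cw:
        stream.extend((cw >> (7 - i)) & 1 for i in range(8))

    def take(n):
        nonlocal pos
        v = int("".join(map(str, stream[pos:pos + n])), 2)
        pos += n
        return v

    pos = 0
    mode = take(4)
    if mode != 0b0100:
        raise ScaleDecodeError(f"unsupported QR mode {mode:04b}")
    count = take(8)
    out = bytes(take(8) for _ in range(count))
    return out.decode("utf-8")


def _scan_runs(line: np.ndarray):
    """Run-length encode a boolean line: list of (value, start, length)."""
    changes = np.flatnonzero(np.diff(line.astype(np.int8)))
    starts = np.concatenate([[0], changes + 1])
    ends = np.concatenate([changes + 1, [len(line)]])
    return [(bool(line[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def _finder_candidates_1d(line: np.ndarray):
    """Centers of 1:1:3:1:1 dark/light/dark/light/dark patterns along a line."""
    runs = _scan_runs(line)
    out = []
    for i in range(len(runs) - 4):
        window = runs[i:i + 5]
        if not (window[0][0] and not window[1][0] and window[2][0]
                and not window[3][0] and window[4][0]):
            continue
        lens = [w[2] for w in window]
        m = sum(lens) / 7.0
        if m < 1.5:
            continue
        tol = max(1.5, 0.6 * m)
        if all(abs(lens[k] - m) <= tol for k in (0, 1, 3, 4)) and \
                abs(lens[2] - 3 * m) <= 2 * tol:
            center = window[0][1] + sum(lens) / 2.0
            out.append((center, m))
    return out


def _verify_finder(dark: np.ndarray, x: float, y: float, m: float) -> bool:
    """Check the 2-D ring structure of a finder pattern at (x, y).

    In Chebyshev distance (modules) from the center: <=1 dark core,
    =2 light ring, =3 dark ring.
    """
    h, w = dark.shape

    def probe(dx, dy, want):
        px = int(round(x + dx * m))
        py = int(round(y + dy * m))
        if not (0 <= px < w and 0 <= py < h):
            return False
        return bool(dark[py, px]) == want

    ring2 = [(2, 0), (-2, 0), (0, 2), (0, -2),
             (2, 2), (2, -2), (-2, 2), (-2, -2)]
    ring3 = [(3, 0), (-3, 0), (0, 3), (0, -3),
             (3, 3), (3, -3), (-3, 3), (-3, -3)]
    return (probe(0, 0, True)
            and all(probe(dx, dy, False) for dx, dy in ring2)
            and all(probe(dx, dy, True) for dx, dy in ring3))


def _locate_finders(dark: np.ndarray):
    """Find the three finder-pattern centers of one upright symbol."""
    h, w = dark.shape
    raw = []  # (x, y, module)
    for y in range(h):
        for cx, m in _finder_candidates_1d(dark[y]):
            col = dark[:, int(round(cx))] if 0 <= round(cx) < w else None
            if col is None:
                continue
            for cy, mv in _finder_candidates_1d(col):
                if abs(cy - y) <= 3.5 * m and abs(mv - m) <= 0.6 * m:
                    raw.append((cx, cy, (m + mv) / 2.0))
                    break
    if not raw:
        raise ScaleDecodeError("no QR finder patterns found")
    clusters: list[list] = []
    for x, y, m in raw:
        for cl in clusters:
            cm = cl[2] / cl[3]
            if abs(cl[0] / cl[3] - x) < 3 * m and abs(cl[1] / cl[3] - y) < 3 * m \
                    and abs(m - cm) <= 0.25 * cm:
                cl[0] += x
                cl[1] += y
                cl[2] += m
                cl[3] += 1
                break
        else:
            clusters.append([x, y, m, 1])
    # genuine finders gather support from every scan row crossing their
    # core and exhibit the full 2-D ring structure; chance alignments in
    # the data region fail one or the other
    support = max(c[3] for c in clusters)
    clusters = [c for c in clusters if c[3] >= max(3, 0.5 * support)]
    clusters = [
        c for c in clusters
        if _verify_finder(dark, c[0] / c[3], c[1] / c[3], c[2] / c[3])
    ]
    centers = [(c[0] / c[3], c[1] / c[3], c[2] / c[3]) for c in clusters]
    if len(centers) < 3:
        raise ScaleDecodeError(
            f"expected 3 QR finder patterns, found {len(centers)}"
        )
    if len(centers) > 3:
        raise ScaleDecodeError(
            f"found {len(centers)} finder patterns; expected exactly one symbol"
        )
    return centers


def decode_image(rgb_or_gray: np.ndarray):
    """Locate and decode one upright frontal QR symbol in an image.

    Returns ``(payload_text, corners)`` with ``corners`` the (4, 2) outer
    corner points of the symbol in pixel (x, y) coordinates, ordered
    top-left, top-right, bottom-right, bottom-left.
    """
    img = np.asarray(rgb_or_gray, dtype=float)
    gray = img.mean(axis=2) if img.ndim == 3 else img
    lo, hi = gray.min(), gray.max()
    if hi - lo < 10:
        raise ScaleDecodeError("image has no contrast; no QR symbol found")
    from skimage.filters import threshold_otsu

    dark = gray < threshold_otsu(gray)
    centers = _locate_finders(dark)

    # identify corners: the two most distant centers are TR and BL
    pts = np.array([(c[0], c[1]) for c in centers])
    d01 = np.linalg.norm(pts[0] - pts[1])
    d02 = np.linalg.norm(pts[0] - pts[2])
    d12 = np.linalg.norm(pts[1] - pts[2])
    tl_idx = [2, 1, 0][int(np.argmax([d01, d02, d12]))]
    others = [i for i in range(3) if i != tl_idx]
    tl = pts[tl_idx]
    # upright symbol: the horizontal partner is TR
    if abs(pts[others[0]][1] - tl[1]) < abs(pts[others[0]][0] - tl[0]):
        tr, bl = pts[others[0]], pts[others[1]]
    else:
        tr, bl = pts[others[1]], pts[others[0]]
    if tr[0] < tl[0] or bl[1] < tl[1]:
        raise ScaleDecodeError("QR symbol is not upright; unsupported orientation")

    module = np.mean([c[2] for c in centers])
    span = (np.linalg.norm(tr - tl) + np.linalg.norm(bl - tl)) / 2.0
    n_span = int(round(span / module))  # modules between finder centers
    size = n_span + 7
    version = (size - 17) / 4
    if version != int(version) or not 1 <= version <= 5:
        # snap to the nearest valid size
        size = int(np.clip(round((size - 17) / 4), 1, 5)) * 4 + 17
    version = (size - 17) // 4

    mx = (tr[0] - tl[0]) / (size - 7)
    my = (bl[1] - tl[1]) / (size - 7)
    cols = tl[0] + (np.arange(size) - 3) * mx
    rows = tl[1] + (np.arange(size) - 3) * my
    # sample a 3x3 neighborhood mean at each module center
    offs = np.array([-0.25, 0.0, 0.25])
    acc = np.zeros((size, size))
    h, w = gray.shape
    for oy in offs:
        for ox in offs:
            yy = np.clip(np.round(rows + oy * my).astype(int), 0, h - 1)
            xx = np.clip(np.round(cols + ox * mx).astype(int), 0, w - 1)
            acc += gray[np.ix_(yy, xx)]
    acc /= len(offs) ** 2
    mat = acc < (acc.min() + acc.max()) / 2.0

    text = decode_matrix(mat)
    corners = np.array([
        [tl[0] - 3.5 * mx, tl[1] - 3.5 * my],
        [tr[0] + 3.5 * mx, tr[1] - 3.5 * my],
        [tr[0] + 3.5 * mx, bl[1] + 3.5 * my],
        [tl[0] - 3.5 * mx, bl[1] + 3.5 * my],
    ])
    return text, corners
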