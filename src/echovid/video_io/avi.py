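"""Self-contained reader/writer for uncompressed (BI_RGB 'DIB ') AVI files.

Only raw 24-bit BGR and 8-bit grayscale payloads are handled; that is the
subset this package ever writes, and it keeps clip round-trips free of any
external codec dependency. Frames are exchanged as uint8 arrays of shape
(T, H, W, 3) or (T, H, W).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from ..errors import DecodeError, EmptyVideoError

__all__ = ["write_avi", "read_avi"]

_AVIF_HASINDEX = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    data = struct.pack("<4sI", fourcc, len(payload)) + payload
    if len(payload) % 2:
        data += b"\x00"
    return data


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def write_avi(path, frames: np.ndarray, fps: int = 25) -> None:
    """Write uint8 frames (T,H,W,3) RGB or (T,H,W) grayscale as raw AVI."""
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        raise ValueError("frames must be uint8")
    if frames.ndim == 3:
        gray = True
    elif frames.ndim == 4 and frames.shape[-1] == 3:
        gray = False
    else:
        raise ValueError(f"unsupported frame shape {frames.shape}")
    n, height, width = frames.shape[:3]
    if n == 0:
        raise ValueError("cannot write an empty video")

    if gray:
        bitcount = 8
        row = width
    else:
        bitcount = 24
        row = width * 3
    stride = (row + 3) & ~3
    frame_bytes = stride * height

    movi_payload = bytearray(b"movi")
    index_entries = []
    for f in frames:
        if gray:
            raw = f[::-1, :]  # bottom-up rows
            buf = np.zeros((height, stride), dtype=np.uint8)
            buf[:, :width] = raw
        else:
            raw = f[::-1, :, ::-1]  # bottom-up rows, RGB -> BGR
            buf = np.zeros((height, stride), dtype=np.uint8)
            buf[:, :row] = raw.reshape(height, row)
        offset = len(movi_payload)
        movi_payload += _chunk(b"00db", buf.tobytes())
        index_entries.append((offset, frame_bytes))

    avih = struct.pack(
        "<IIIIIIIIIIIIII",
        int(1e6 / fps), frame_bytes * fps, 0, _AVIF_HASINDEX, n, 0, 1,
        frame_bytes, width, height, 0, 0, 0, 0)
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0, 1, fps, 0, n, frame_bytes,
        0xFFFFFFFF & -1, 0, 0, 0, width, height)
    palette = b""
    if gray:
        palette = b"".join(struct.pack("<BBBB", i, i, i, 0) for i in range(256))
    strf = struct.pack(
        "<IiiHHIIiiII", 40, width, height, 1, bitcount, 0, frame_bytes,
        0, 0, 256 if gray else 0, 0) + palette

    hdrl = _list(b"hdrl", _chunk(b"avih", avih) +
                 _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)))
    movi = _chunk(b"LIST", bytes(movi_payload))
    idx1 = _chunk(b"idx1", b"".join(
        struct.pack("<4sIII", b"00db", 0x10, off + 4, size)
        for off, size in index_entries))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(struct.pack("<4sI", b"RIFF", len(body)) + body)


def _iter_chunks(data: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc, size = struct.unpack_from("<4sI", data, pos)
        payload_start = pos + 8
        yield fourcc, payload_start, size
        pos = payload_start + size + (size % 2)


def read_avi(path) -> np.ndarray:
    """Read a raw DIB AVI into uint8 (T, H, W, 3) RGB (grayscale replicated)."""
    path = Path(path)
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise DecodeError(f"cannot read {path}: {exc}") from exc
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise DecodeError(f"{path} is not an AVI (RIFF) file")

    width = height = bitcount = None
    frames: list[np.ndarray] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, bitcount
        for fourcc, pstart, size in _iter_chunks(data, start, end):
            pend = pstart + size
            if fourcc == b"LIST":
                walk(pstart + 4, pend)
            elif fourcc == b"strf" and width is None:
                if size < 40:
                    raise DecodeError("truncated BITMAPINFOHEADER")
                _, w, h, _, bc = struct.unpack_from("<IiiHH", data, pstart)
                width, height, bitcount = w, abs(h), bc
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames.append(np.frombuffer(data, dtype=np.uint8, count=size, offset=pstart))

    walk(12, len(data))

    if width is None or bitcount is None:
        raise DecodeError(f"{path}: no video stream format found")
    if bitcount not in (8, 24):
        raise DecodeError(f"{path}: unsupported bit depth {bitcount}")
    if not frames:
        raise EmptyVideoError(f"{path}: video has zero frames")

    row = width * (bitcount // 8)
    stride = (row + 3) & ~3
    out = np.empty((len(frames), height, width, 3), dtype=np.uint8)
    for i, raw in enumerate(frames):
        if raw.size < stride * height:
            raise DecodeError(f"{path}: frame {i} payload too small")
        rows = raw[: stride * height].reshape(height, stride)[:, :row]
        if bitcount == 8:
            img = rows[::-1, :]
            out[i] = img[..., None]
        else:
            img = rows.reshape(height, width, 3)[::-1, :, ::-1]
            out[i] = img
    return out
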