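"""Minimal bit-exact grayscale PNG codec and the PNG-Rate entropy proxy.

By the source coding theorem, a lossless compressor cannot shrink a signal
below its entropy times its length, so the on-disk size of a losslessly
compressed file tracks the entropy of its content.  The "PNG Rate" is the
size in bytes of a PNG file divided by its pixel count: a cheap, linear
proxy for the entropy rate of the pixel stream.

The writer here emits only the critical chunks (signature, IHDR, one IDAT,
IEND), grayscale color type 0 at bit depth 1 or 8, scanline filter fixed to
type 0 (None) and a single zlib/DEFLATE stream.  No ancillary chunks means
the overhead floor — the size of an all-zero image — is a small deterministic
constant (90 bytes for 100 x 100), so rate differences reflect content, not
metadata.

Mutual information via compression: write the trials-x-time matrix as one
image (compression runs along time -> signal entropy proxy), rotate it 90
degrees and write it again (compression runs across trials -> noise entropy
proxy); the difference of the two PNG Rates tracks the information
transferred from stimulus to response.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass

import numpy as np

from .shannon_direct import TrialMatrix

__all__ = [
    "GrayImage",
    "PngRateResult",
    "MiPngResult",
    "PngFormatError",
    "normalize_to_8bit",
    "encode_png",
    "decode_png",
    "png_rate",
    "png_overhead",
    "rotate90",
    "matrix_to_image",
    "mi_png_rate",
    "DEFAULT_ZLIB_LEVEL",
]

PNG_SIGNATURE = b"\x89PNG\r\n\x1a\n"

#: zlib container level used for every published rate unless overridden.
DEFAULT_ZLIB_LEVEL = 6


class PngFormatError(ValueError):
    """Raised on malformed or unsupported PNG input."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of gray values at bit depth 1 or 8."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must form a non-empty 2-D grid")
        if self.bit_depth not in (1, 8):
            raise ValueError("bit_depth must be 1 or 8")
        px = px.astype(np.uint8)
        if px.max(initial=0) > (1 << self.bit_depth) - 1:
            raise ValueError("pixel values exceed bit depth range")
        object.__setattr__(self, "pixels", px)

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def n_pixels(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class PngRateResult:
    """On-disk size per pixel; optionally scaled to bytes per second."""

    file_bytes: int
    n_pixels: int
    rate_bytes_per_pixel: float
    rate_bytes_per_s: float | None = None


@dataclass(frozen=True)
class MiPngResult:
    """Signal and noise PNG Rates and their difference (the MI proxy)."""

    signal_rate: float
    noise_rate: float
    difference: float
    units: str = "bytes/pixel"


def normalize_to_8bit(samples) -> np.ndarray:
    """Map a real signal onto gray values 0..255.

    Subtract the minimum, divide by the range, multiply by 255 and round
    half-up.  A constant signal maps to all zeros.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.uint8)
    return np.floor((x - lo) / (hi - lo) * 255.0 + 0.5).astype(np.uint8)


def _chunk(tag: bytes, payload: bytes) -> bytes:
    crc = zlib.crc32(tag + payload) & 0xFFFFFFFF
    return struct.pack(">I", len(payload)) + tag + payload + struct.pack(">I", crc)


def _pack_scanlines(image: GrayImage) -> bytes:
    """Filter-type-0 scanlines; 1-bit rows packed MSB-first, byte-padded."""
    if image.bit_depth == 8:
        rows = image.pixels
    else:
        rows = np.packbits(image.pixels, axis=1)  # MSB first, zero padded
    filt = np.zeros((rows.shape[0], 1), dtype=np.uint8)
    return np.concatenate([filt, rows], axis=1).tobytes()


def encode_png(image: GrayImage, zlib_level: int = DEFAULT_ZLIB_LEVEL) -> bytes:
    """Serialize a grayscale image as a minimal standard-conformant PNG.

    Critical chunks only, one IDAT, no interlace, scanline filter None.
    Any standard reader decodes the stream back to identical pixels.
    """
    if not 0 <= zlib_level <= 9:
        raise ValueError("zlib_level must be in 0..9")
    ihdr = struct.pack(">IIBBBBB", image.width, image.height,
                       image.bit_depth, 0, 0, 0, 0)
    idat = zlib.compress(_pack_scanlines(image), zlib_level)
    return (PNG_SIGNATURE
            + _chunk(b"IHDR", ihdr)
            + _chunk(b"IDAT", idat)
            + _chunk(b"IEND", b""))


def _unfilter(raw: np.ndarray, width_bytes: int) -> np.ndarray:
    """Undo per-scanline filters 0-4 (bytewise, bpp = 1 byte)."""
    stride = width_bytes + 1
    n_rows = raw.size // stride
    rows = raw.reshape(n_rows, stride)
    out = np.zeros((n_rows, width_bytes), dtype=np.uint8)
    prev = np.zeros(width_bytes, dtype=np.uint16)
    for i in range(n_rows):
        ftype = int(rows[i, 0])
        line = rows[i, 1:].astype(np.uint16)
        if ftype == 0:
            cur = line
        elif ftype == 1:  # Sub
            cur = line.copy()
            for j in range(1, width_bytes):
                cur[j] = (cur[j] + cur[j - 1]) & 0xFF
        elif ftype == 2:  # Up
            cur = (line + prev) & 0xFF
        elif ftype == 3:  # Average
            cur = line.copy()
            for j in range(width_bytes):
                left = cur[j - 1] if j else 0
                cur[j] = (cur[j] + ((left + prev[j]) >> 1)) & 0xFF
        elif ftype == 4:  # Paeth
            cur = line.copy()
            for j in range(width_bytes):
                a = int(cur[j - 1]) if j else 0
                b = int(prev[j])
                c = int(prev[j - 1]) if j else 0
                p = a + b - c
                pa, pb, pc = abs(p - a), abs(p - b), abs(p - c)
                pred = a if (pa <= pb and pa <= pc) else (b if pb <= pc else c)
                cur[j] = (cur[j] + pred) & 0xFF
        else:
            raise PngFormatError(f"unknown filter type {ftype}")
        out[i] = cur.astype(np.uint8)
        prev = cur
    return out


def decode_png(data: bytes) -> GrayImage:
    """Parse a grayscale (color type 0) PNG back to pixels.

    Verifies the signature and every chunk CRC; rejects non-grayscale color
    types, unsupported bit depths, interlacing and truncated streams.
    """
    if not data.startswith(PNG_SIGNATURE):
        raise PngFormatError("not a PNG stream (bad signature)")
    pos = len(PNG_SIGNATURE)
    ihdr = None
    idat = b""
    while pos < len(data):
        if pos + 8 > len(data):
            raise PngFormatError("truncated chunk header")
        length, tag = struct.unpack(">I4s", data[pos:pos + 8])
        end = pos + 8 + length + 4
        if end > len(data):
            raise PngFormatError("truncated chunk payload")
        payload = data[pos + 8:pos + 8 + length]
        (crc,) = struct.unpack(">I", data[pos + 8 + length:end])
        if zlib.crc32(tag + payload) & 0xFFFFFFFF != crc:
            raise PngFormatError(f"CRC mismatch in {tag!r} chunk")
        if tag == b"IHDR":
            ihdr = struct.unpack(">IIBBBBB", payload)
        elif tag == b"IDAT":
            idat += payload
        elif tag == b"IEND":
            break
        pos = end
    if ihdr is None:
        raise PngFormatError("missing IHDR chunk")
    width, height, depth, color, comp, filt, interlace = ihdr
    if color != 0:
        raise PngFormatError(f"unsupported color type {color}; grayscale only")
    if depth not in (1, 8):
        raise PngFormatError(f"unsupported bit depth {depth}")
    if interlace != 0:
        raise PngFormatError("interlaced PNGs are not supported")
    if comp != 0 or filt != 0:
        raise PngFormatError("non-standard compression/filter method")
    try:
        raw = np.frombuffer(zlib.decompress(idat), dtype=np.uint8)
    except zlib.error as exc:
        raise PngFormatError(f"corrupt IDAT stream: {exc}") from None
    width_bytes = width if depth == 8 else (width + 7) // 8
    if raw.size != height * (width_bytes + 1):
        raise PngFormatError("scanline data has wrong length")
    rows = _unfilter(raw, width_bytes)
    if depth == 1:
        rows = np.unpackbits(rows, axis=1)[:, :width]
    return GrayImage(rows, bit_depth=depth)


def png_rate(image: GrayImage, zlib_level: int = DEFAULT_ZLIB_LEVEL,
             sampling_rate: float | None = None) -> PngRateResult:
    """PNG Rate: total on-disk bytes (header included) per pixel.

    With a sampling rate the result is also expressed in bytes per second
    (rate/pixel times samples/second).
    """
    size = len(encode_png(image, zlib_level))
    rate = size / image.n_pixels
    per_s = rate * sampling_rate if sampling_rate is not None else None
    return PngRateResult(size, image.n_pixels, rate, per_s)


def png_overhead(width: int, height: int, bit_depth: int = 8,
                 zlib_level: int = DEFAULT_ZLIB_LEVEL) -> int:
    """Size of the all-zero image: the additive floor of the PNG-Rate proxy."""
    img = GrayImage(np.zeros((height, width), dtype=np.uint8), bit_depth)
    return len(encode_png(img, zlib_level))


def rotate90(image: GrayImage) -> GrayImage:
    """Clockwise quarter-turn; four applications are the identity."""
    return GrayImage(np.rot90(image.pixels, k=-1), image.bit_depth)


def matrix_to_image(trials: TrialMatrix, bit_depth: int = 8) -> GrayImage:
    """Render a trial matrix as an image: rows = trials, columns = time.

    At depth 8 the whole matrix is normalized jointly so every trial shares
    one gray scale; at depth 1 the matrix must already be binary.
    """
    if bit_depth == 8:
        return GrayImage(normalize_to_8bit(trials.trials), 8)
    values = np.unique(trials.trials)
    if not np.all(np.isin(values, (0, 1))):
        raise ValueError("1-bit images require a binary (0/1) trial matrix")
    return GrayImage(trials.trials.astype(np.uint8), 1)


def mi_png_rate(trials: TrialMatrix, bit_depth: int = 8,
                zlib_level: int = DEFAULT_ZLIB_LEVEL) -> MiPngResult:
    """Rotate-and-recompress mutual-information proxy.

    signal = PNG Rate of the trials-x-time image, noise = PNG Rate of its
    90-degree rotation, both scaled by the sampling rate to bytes/s; the
    difference tracks the stimulus-response information transfer rate.
    """
    if trials.n_trials < 2:
        raise ValueError("mutual information requires at least 2 trials")
    img = matrix_to_image(trials, bit_depth)
    fs = trials.sampling_rate
    signal = png_rate(img, zlib_level, fs).rate_bytes_per_s
    noise = png_rate(rotate90(img), zlib_level, fs).rate_bytes_per_s
    return MiPngResult(signal, noise, signal - noise, units="bytes/s")
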