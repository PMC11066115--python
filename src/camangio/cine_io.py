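"""Reading and writing cine loops, images, masks and point annotations.

Conventions used throughout the package:

* Coordinates are 0-based ``(row, col)`` with row 0 at the top; continuous
  coordinates place pixel centers at integer positions.
* All processing happens in floating point on the intensity range [0, 1];
  integer files are converted on read by dividing by the dtype maximum
  (255 or 65535), never by a per-file min/max.
* Multi-frame TIFF is the lossless reference interchange format for cine
  loops.  A single uncompressed 8-bit grayscale AVI flavor (RIFF/DIB) is
  supported for interoperability; it is equally lossless.
* No frame registration is applied on read: the downstream differencing
  model assumes co-registered frames with a static background.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import imageio.v2 as iio
import numpy as np
import tifffile

from .exceptions import CineIOError, ValidationError

__all__ = [
    "CineLoop",
    "RoiMask",
    "PointAnnotation",
    "read_cine",
    "write_cine",
    "read_image",
    "write_image",
    "read_annotations",
    "write_annotations",
    "mask_to_rle",
    "rle_to_mask",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CineLoop:
    """An ordered stack of T co-registered grayscale frames.

    Parameters
    ----------
    frames
        Array of shape ``(T, M, N)``; frame order is acquisition order
        (temporal differencing is order-sensitive).
    pixel_size_mm
        Optional isotropic pixel size in millimetres.
    frame_rate_hz
        Optional acquisition frame rate.
    """

    frames: np.ndarray
    pixel_size_mm: Optional[float] = None
    frame_rate_hz: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"cine frames must be a (T, M, N) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValidationError("differencing requires T >= 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("cine intensities must be finite")
        if np.any(self.frames < 0):
            raise ValidationError("cine intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class RoiMask:
    """A rough binary annotation mask seeding segmentation."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {self.mask.shape}")
        if not self.mask.any():
            raise ValidationError("mask must contain at least one true pixel")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape


@dataclass
class PointAnnotation:
    """Ordered user-clicked points: a closed boundary or an open curve."""

    points: np.ndarray
    closed: bool
    label: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("points must be an ordered list of (row, col) pairs")
        n_min = 3 if self.closed else 2
        if self.points.shape[0] < n_min:
            kind = "closed boundaries" if self.closed else "open curves"
            raise ValidationError(f"{kind} need at least {n_min} points")
        if np.any(self.points < 0):
            raise ValidationError(
                f"annotation points must be non-negative, got {self.points.min()}"
            )

    def validate_extent(self, shape: Tuple[int, int]) -> None:
        """Check all points lie within a frame of the given (M, N) shape."""
        m, n = shape
        if np.any(self.points[:, 0] > m - 1) or np.any(self.points[:, 1] > n - 1):
            raise ValidationError(
                f"annotation points exceed the frame extent {shape}"
            )


# ---------------------------------------------------------------------------
# Raw uncompressed 8-bit grayscale AVI (RIFF/DIB)
# ---------------------------------------------------------------------------
# Minimal RIFF-AVI container with BI_RGB 8-bit frames and a grayscale
# palette: lossless and codec-free.  Only this flavor is supported.

def _avi_write(path: Path, frames: np.ndarray, fps: float) -> None:
    t, m, n = frames.shape
    pad = (-n) % 4  # DIB rows padded to 4-byte multiples
    row_bytes = n + pad
    frame_bytes = row_bytes * m

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        data = struct.pack("<4sI", fourcc, len(payload)) + payload
        if len(payload) % 2:
            data += b"\x00"
        return data

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    rate = max(1, int(round(fps)))
    avih = struct.pack(
        "<14I",
        int(1e6 / rate), frame_bytes * rate, 0, 0x10,  # AVIF_HASINDEX
        t, 0, 1, frame_bytes, n, m, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIiI4h",
        b"vids", b"DIB ", 0, 0, 0, 0, 1, rate, 0, t,
        frame_bytes, -1, 0, 0, 0, int(n), int(m),
    )
    palette = b"".join(struct.pack("<4B", i, i, i, 0) for i in range(256))
    strf = struct.pack("<IiiHHIIiiII", 40, n, m, 1, 8, 0, frame_bytes, 0, 0, 256, 0) + palette
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)))

    movi_payload = b"movi"
    idx = b""
    offset = 4  # relative to start of 'movi' fourcc
    for i in range(t):
        rows = frames[i][::-1]  # DIB stores rows bottom-up
        if pad:
            rows = np.pad(rows, ((0, 0), (0, pad)))
        payload = rows.astype(np.uint8).tobytes()
        movi_payload += chunk(b"00db", payload)
        idx += struct.pack("<4sIII", b"00db", 0x10, offset, len(payload))
        offset += 8 + len(payload) + (len(payload) % 2)
    movi = chunk(b"LIST", movi_payload)

    body = b"AVI " + hdrl + movi + chunk(b"idx1", idx)
    with open(path, "wb") as fh:
        fh.write(struct.pack("<4sI", b"RIFF", len(body)) + body)


def _avi_read(path: Path) -> Tuple[np.ndarray, Optional[float]]:
    data = path.read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise CineIOError(f"not a RIFF AVI file: {path}")

    width = height = bitcount = compression = None
    rate = scale = None
    frames: List[bytes] = []

    def walk(buf: bytes, pos: int, end: int) -> None:
        nonlocal width, height, bitcount, compression, rate, scale
        while pos + 8 <= end:
            fourcc, size = struct.unpack_from("<4sI", buf, pos)
            body_start = pos + 8
            if fourcc == b"LIST":
                walk(buf, body_start + 4, body_start + size)
            elif fourcc == b"strh":
                fcc_type, _, _, _, _, _, scl, rt = struct.unpack_from("<4s4sIHHIII", buf, body_start)
                if fcc_type == b"vids":
                    scale, rate = scl, rt
            elif fourcc == b"strf" and width is None:
                _, width, height, _, bitcount, compression = struct.unpack_from(
                    "<IiiHHI", buf, body_start
                )
            elif fourcc in (b"00db", b"00dc"):
                frames.append(buf[body_start:body_start + size])
            pos = body_start + size + (size % 2)

    walk(data, 12, len(data))
    if width is None or not frames:
        raise CineIOError(f"no decodable video stream in {path}")
    if bitcount != 8 or compression != 0:
        raise CineIOError(
            f"unsupported AVI flavor in {path}: only uncompressed 8-bit "
            f"grayscale (BI_RGB, 8 bpp) is readable"
        )
    m, n = abs(height), width
    row_bytes = n + ((-n) % 4)
    out = np.empty((len(frames), m, n), dtype=np.uint8)
    for i, payload in enumerate(frames):
        arr = np.frombuffer(payload[: row_bytes * m], dtype=np.uint8).reshape(m, row_bytes)
        rows = arr[:, :n]
        out[i] = rows[::-1] if height > 0 else rows  # bottom-up unless height < 0
    fps = (rate / scale) if rate and scale else None
    return out, fps


# ---------------------------------------------------------------------------
# Cine I/O
# ---------------------------------------------------------------------------

def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Collapse a trailing channel axis by averaging (color -> grayscale)."""
    if frames.ndim == 4:
        frames = frames.astype(np.float64).mean(axis=-1)
    return frames


def _dtype_max(dtype: np.dtype) -> Optional[float]:
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    return None


def read_cine(path: Union[str, Path], normalize: bool = True) -> CineLoop:
    """Read a multi-frame TIFF or uncompressed grayscale AVI as a cine loop.

    Color frames are converted to grayscale by channel averaging.  With
    ``normalize`` integer intensities are divided by the dtype maximum
    (255 or 65535); floating-point files are taken as already scaled.
    """
    path = Path(path)
    if not path.exists():
        raise CineIOError(f"cine file not found: {path}")
    suffix = path.suffix.lower()
    frame_rate = None
    try:
        if suffix in (".tif", ".tiff"):
            frames = tifffile.imread(path)
        elif suffix == ".avi":
            frames, frame_rate = _avi_read(path)
        else:
            frames = np.asarray(iio.mimread(path, memtest=False))
    except CineIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - decode errors become I/O errors
        raise CineIOError(f"could not read cine file {path}: {exc}") from exc

    frames = np.asarray(frames)
    if frames.ndim == 2 or (frames.ndim == 3 and frames.shape[-1] in (3, 4) and frames.shape[0] > 4):
        # A single grayscale frame, or a single color frame.
        raise ValidationError(f"differencing requires T >= 2 frames, got 1 in {path}")
    maxval = _dtype_max(frames.dtype)  # before grayscale conversion casts to float
    frames = _to_grayscale(frames)
    if frames.ndim != 3:
        raise ValidationError(f"cannot interpret {path} as a (T, M, N) cine stack")
    if normalize:
        frames = frames.astype(np.float64)
        if maxval is not None:
            frames = frames / maxval
    return CineLoop(frames=frames.astype(np.float64), frame_rate_hz=frame_rate)


def write_cine(
    loop: CineLoop,
    path: Union[str, Path],
    bit_depth: int = 8,
    fps: float = 10.0,
) -> None:
    """Write a [0, 1] cine loop as multi-frame TIFF or raw grayscale AVI.

    Intensities are quantized to ``bit_depth`` bits with round-half-away-
    from-zero; values of the form k / (2^bit_depth - 1) round-trip exactly.
    AVI supports 8-bit only.
    """
    path = Path(path)
    if bit_depth not in (8, 16):
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    frames = loop.frames
    if frames.min() < 0 or frames.max() > 1:
        raise ValidationError("cine intensities must be in [0, 1]; normalize first")
    maxval = 2 ** bit_depth - 1
    quantized = np.floor(frames * maxval + 0.5).astype(np.uint8 if bit_depth == 8 else np.uint16)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, quantized, photometric="minisblack")
    elif suffix == ".avi":
        if bit_depth != 8:
            raise ValidationError("AVI output supports 8-bit only")
        _avi_write(path, quantized, fps=loop.frame_rate_hz or fps)
    else:
        raise ValidationError(f"unsupported cine format: {path.suffix}")


# ---------------------------------------------------------------------------
# Still images
# ---------------------------------------------------------------------------

def write_image(image: np.ndarray, path: Union[str, Path], bit_depth: int = 8) -> None:
    """Write a [0, 1] image as 8- or 16-bit PNG/TIFF.

    Real values map linearly to the integer range with round-half-away-
    from-zero (0.5 at 8 bit becomes 128).
    """
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim not in (2, 3):
        raise ValidationError(f"image must be 2-D (or RGB), got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image values must be finite")
    if image.min() < 0 or image.max() > 1:
        raise ValidationError(
            "image values must lie in [0, 1]; normalize before writing"
        )
    if bit_depth not in (8, 16):
        raise ValidationError(f"bit_depth must be 8 or 16, got {bit_depth}")
    maxval = 2 ** bit_depth - 1
    out = np.floor(image * maxval + 0.5).astype(np.uint8 if bit_depth == 8 else np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a still image to float64 in [0, 1] (grayscale by averaging)."""
    path = Path(path)
    if not path.exists():
        raise CineIOError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise CineIOError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr.astype(np.float64).mean(axis=-1)
    maxval = _dtype_max(arr.dtype)
    arr = arr.astype(np.float64)
    if maxval is not None:
        arr = arr / maxval
    return arr


# ---------------------------------------------------------------------------
# Annotation JSON (points + run-length-encoded masks)
# ---------------------------------------------------------------------------

def mask_to_rle(mask: np.ndarray) -> List[int]:
    """Run-length encode a boolean mask (row-major, first run counts False)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:  # runs must start with the False count
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_to_mask(rle: Sequence[int], shape: Tuple[int, int]) -> np.ndarray:
    total = int(np.prod(shape))
    if sum(rle) != total:
        raise ValidationError(
            f"items[].rle: run lengths sum to {sum(rle)}, expected {total}"
        )
    flat = np.zeros(total, dtype=bool)
    pos, value = 0, False
    for run in rle:
        if run < 0:
            raise ValidationError("items[].rle: negative run length")
        if value:
            flat[pos:pos + run] = True
        pos += run
        value = not value
    return flat.reshape(shape)


AnnotationItem = Union[RoiMask, PointAnnotation]


def write_annotations(items: Iterable[AnnotationItem], path: Union[str, Path]) -> None:
    """Persist masks and point annotations losslessly as JSON."""
    payload = []
    for item in items:
        if isinstance(item, RoiMask):
            payload.append({
                "type": "mask",
                "shape": list(item.mask.shape),
                "rle": mask_to_rle(item.mask),
                "label": item.label,
            })
        elif isinstance(item, PointAnnotation):
            payload.append({
                "type": "points",
                "closed": bool(item.closed),
                "points": [[float(r), float(c)] for r, c in item.points],
                "label": item.label,
            })
        else:
            raise ValidationError(f"unsupported annotation item: {type(item).__name__}")
    Path(path).write_text(json.dumps({"items": payload}, indent=1))


def read_annotations(path: Union[str, Path]) -> List[AnnotationItem]:
    """Read the annotation JSON written by :func:`write_annotations`."""
    path = Path(path)
    if not path.exists():
        raise CineIOError(f"annotation file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed annotation JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("items"), list):
        raise ValidationError('annotation JSON must be {"items": [...]}')
    out: List[AnnotationItem] = []
    for i, item in enumerate(doc["items"]):
        where = f"items[{i}]"
        if not isinstance(item, dict) or "type" not in item:
            raise ValidationError(f"{where}: missing 'type'")
        try:
            if item["type"] == "mask":
                mask = rle_to_mask(item["rle"], tuple(item["shape"]))
                out.append(RoiMask(mask=mask, label=item.get("label", "")))
            elif item["type"] == "points":
                out.append(PointAnnotation(
                    points=np.asarray(item["points"], dtype=np.float64),
                    closed=bool(item["closed"]),
                    label=item.get("label", ""),
                ))
            else:
                raise ValidationError(f"{where}.type: unknown type {item['type']!r}")
        except KeyError as exc:
            raise ValidationError(f"{where}: missing field {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
    return out
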