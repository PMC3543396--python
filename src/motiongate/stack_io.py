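"""Image-stack container, TIFF/PNG I/O, channel splitting and metadata parsing.

The universal in-memory object is :class:`FrameStack`: an ordered run of
``T`` frames of ``H x W`` pixels with ``C`` 8-bit channels (``C`` is 1 for a
single fluorescence channel or 3 for the RGB-packed export produced by
two-photon acquisition software).  Each frame carries its *origin index* —
its position in the original acquisition — which survives every filtering
stage so that timestamps stay accurate after frames are removed.

Acquisition metadata (frame interval, pixel size, channel naming) comes from
a minimal plain-text ``key = value`` sidecar emulating the TXT exports of
commercial microscope software.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ConfigurationError, MetadataError, StackFormatError

logger = logging.getLogger(__name__)

#: Acquisition frame-interval range (seconds) typical of resonant/galvo
#: two-photon imaging at 2.5-15 frames per second; values outside it are
#: accepted with a warning.
FRAME_INTERVAL_RANGE_S = (1.0 / 15.0, 1.0 / 2.5)

RGB_CHANNEL_NAMES = ("red", "green", "blue")


@dataclass(frozen=True)
class FrameStack:
    """An ordered time-lapse stack of 8-bit frames.

    Parameters
    ----------
    frames:
        ``(T, H, W, C)`` uint8 array, ``C in {1, 3}``.
    channel_names:
        One label per channel (e.g. ``("red", "green", "blue")``).
    origin_indices:
        Strictly increasing original acquisition index of each frame
        (0-based).  Defaults to ``0..T-1``.
    """

    frames: np.ndarray
    channel_names: tuple[str, ...] = ()
    origin_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim == 3:  # (T, H, W) shorthand for single channel
            frames = frames[..., np.newaxis]
        if frames.ndim != 4:
            raise StackFormatError(
                f"frames must be (T, H, W, C); got shape {frames.shape}"
            )
        if frames.dtype != np.uint8:
            raise StackFormatError(
                f"frames must be 8-bit (uint8); got dtype {frames.dtype}"
            )
        T, H, W, C = frames.shape
        if T < 1:
            raise StackFormatError("stack must hold at least one frame")
        if C not in (1, 3):
            raise StackFormatError(f"channel count must be 1 or 3; got {C}")
        names = tuple(self.channel_names)
        if not names:
            names = RGB_CHANNEL_NAMES if C == 3 else ("gray",)
        if len(names) != C:
            raise StackFormatError(
                f"{len(names)} channel names for {C} channels"
            )
        origin = self.origin_indices
        if origin is None:
            origin = np.arange(T)
        origin = np.asarray(origin, dtype=np.int64)
        if origin.shape != (T,):
            raise StackFormatError("origin_indices length must equal T")
        if T > 1 and not np.all(np.diff(origin) > 0):
            raise StackFormatError("origin_indices must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "origin_indices", origin)

    # -- shape accessors -------------------------------------------------
    @property
    def T(self) -> int:
        return self.frames.shape[0]

    @property
    def H(self) -> int:
        return self.frames.shape[1]

    @property
    def W(self) -> int:
        return self.frames.shape[2]

    @property
    def C(self) -> int:
        return self.frames.shape[3]

    def __len__(self) -> int:
        return self.T

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(T, H, W)`` uint8 view of one named channel."""
        try:
            c = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"unknown channel {name!r}; stack has {self.channel_names}"
            ) from None
        return self.frames[..., c]

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """New stack with replaced pixel data, same bookkeeping."""
        return replace(self, frames=frames)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition settings needed by timestamping and scale bars.

    ``frame_interval`` is in seconds per frame, ``pixel_size`` in
    micrometres per pixel (``None`` when the sidecar omits it, in which
    case scale-bar overlays refuse to run).
    """

    frame_interval: float
    pixel_size: float | None = None
    channel_names: tuple[str, ...] = RGB_CHANNEL_NAMES
    reference_channel: str = "red"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise MetadataError("frame_interval must be > 0 seconds")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise MetadataError("pixel_size must be > 0 micrometres")
        if self.reference_channel not in self.channel_names:
            raise MetadataError(
                f"reference_channel {self.reference_channel!r} not among "
                f"channel_names {self.channel_names}"
            )
        lo, hi = FRAME_INTERVAL_RANGE_S
        if not (lo <= self.frame_interval <= hi):
            logger.warning(
                "frame_interval %.4f s lies outside the typical acquisition "
                "range [%.4f, %.4f] s", self.frame_interval, lo, hi,
            )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def _check_depth(arr: np.ndarray, source: str) -> np.ndarray:
    if arr.dtype != np.uint8:
        raise StackFormatError(
            f"{source}: only 8-bit-per-channel images are supported; "
            f"found {arr.dtype.itemsize * 8}-bit samples ({arr.dtype})"
        )
    return arr


def _pages_from_dir(path: Path) -> list[np.ndarray]:
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise StackFormatError(f"no TIFF/PNG frames found in directory {path}")
    return [_check_depth(np.asarray(iio.imread(p)), str(p)) for p in files]


def read_stack(path: str | Path, layout: str = "rgb") -> FrameStack:
    """Read a multipage TIFF (or a directory of numbered TIFF/PNG frames).

    ``layout="rgb"`` expects 3 samples per pixel and yields ``C=3`` with
    channel order red, green, blue; ``layout="gray"`` yields ``C=1``.
    Origin indices are restored from a ``<stem>.frames.json`` sidecar when
    present, else set to ``0..T-1``.
    """
    if layout not in ("rgb", "gray"):
        raise ConfigurationError(f"layout must be 'rgb' or 'gray'; got {layout!r}")
    path = Path(path)
    if path.is_dir():
        pages = _pages_from_dir(path)
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise StackFormatError(f"mixed frame dimensions in {path}: {shapes}")
        frames = np.stack(pages)
    else:
        try:
            frames = np.asarray(tifffile.imread(path))
        except (OSError, ValueError) as exc:
            raise StackFormatError(f"cannot read image stack {path}: {exc}") from exc
        _check_depth(frames, str(path))
        if frames.ndim == 2:  # single gray page
            frames = frames[np.newaxis]
        elif frames.ndim == 3 and layout == "rgb" and frames.shape[-1] == 3:
            frames = frames[np.newaxis]  # single RGB page

    if layout == "rgb":
        if frames.ndim != 4 or frames.shape[-1] != 3:
            raise StackFormatError(
                f"layout 'rgb' expects (T, H, W, 3) pages; got {frames.shape}"
            )
        names: tuple[str, ...] = RGB_CHANNEL_NAMES
    else:
        if frames.ndim == 4 and frames.shape[-1] == 1:
            frames = frames[..., 0]
        if frames.ndim != 3:
            raise StackFormatError(
                f"layout 'gray' expects (T, H, W) pages; got {frames.shape}"
            )
        frames = frames[..., np.newaxis]
        names = ("gray",)

    origin = None
    sidecar = _sidecar_path(path)
    if sidecar.is_file():
        payload = json.loads(sidecar.read_text())
        origin = np.asarray(payload["origin_indices"], dtype=np.int64)
        if "channel_names" in payload:
            names = tuple(payload["channel_names"])
    return FrameStack(frames=frames, channel_names=names, origin_indices=origin)


def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "frames.json"
    return path.with_suffix("").with_suffix(".frames.json") if path.suffix else path.with_name(path.name + ".frames.json")


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a multipage TIFF (one page per frame) plus a JSON sidecar
    ``<stem>.frames.json`` holding origin indices and channel names."""
    path = Path(path)
    if not path.parent.is_dir():
        raise StackFormatError(f"parent directory does not exist: {path.parent}")
    data = stack.frames if stack.C == 3 else stack.frames[..., 0]
    photometric = "rgb" if stack.C == 3 else "minisblack"
    try:
        tifffile.imwrite(path, data, photometric=photometric)
    except OSError as exc:
        raise StackFormatError(f"cannot write {path}: {exc}") from exc
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "origin_indices": stack.origin_indices.tolist(),
        "channel_names": list(stack.channel_names),
    }))
    return path


# ---------------------------------------------------------------------------
# channel packing
# ---------------------------------------------------------------------------

def split_channels(stack: FrameStack) -> tuple[FrameStack, FrameStack, FrameStack]:
    """Split an RGB-packed stack into three single-channel stacks
    (red, green, blue order), carrying each channel's name over."""
    if stack.C != 3:
        raise ConfigurationError(f"split_channels requires C=3; got C={stack.C}")
    out = []
    for c in range(3):
        out.append(FrameStack(
            frames=stack.frames[..., c : c + 1].copy(),
            channel_names=(stack.channel_names[c],),
            origin_indices=stack.origin_indices,
        ))
    return out[0], out[1], out[2]


def merge_channels(r: FrameStack, g: FrameStack, b: FrameStack) -> FrameStack:
    """Pack three single-channel stacks back into one C=3 stack (r, g, b)."""
    parts = (r, g, b)
    shapes = {(s.T, s.H, s.W, s.C) for s in parts}
    if len(shapes) != 1 or parts[0].C != 1:
        raise ConfigurationError(
            f"merge_channels requires three identically shaped single-channel "
            f"stacks; got shapes {[(s.T, s.H, s.W, s.C) for s in parts]}"
        )
    frames = np.concatenate([s.frames for s in parts], axis=-1)
    return FrameStack(
        frames=frames,
        channel_names=tuple(s.channel_names[0] for s in parts),
        origin_indices=r.origin_indices,
    )


# ---------------------------------------------------------------------------
# metadata sidecar
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"frame_interval_s", "pixel_size_um", "channels", "reference_channel"}


def parse_metadata(path: str | Path) -> AcquisitionMeta:
    """Parse a plain-text ``key = value`` acquisition-metadata sidecar.

    Recognized keys: ``frame_interval_s`` (required), ``pixel_size_um``,
    ``channels`` (comma-separated labels), ``reference_channel``.
    Unknown keys are ignored with a logged warning.
    """
    path = Path(path)
    values: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise MetadataError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in _KNOWN_KEYS:
            logger.warning("%s:%d: ignoring unknown metadata key %r", path, lineno, key)
            continue
        values[key] = val

    if "frame_interval_s" not in values:
        raise MetadataError(f"{path}: required key 'frame_interval_s' is missing")

    def _positive_float(key: str) -> float:
        try:
            x = float(values[key])
        except ValueError as exc:
            raise MetadataError(f"{path}: {key} is not a number: {values[key]!r}") from exc
        if x <= 0:
            raise MetadataError(f"{path}: {key} must be > 0; got {x}")
        return x

    interval = _positive_float("frame_interval_s")
    pixel_size = _positive_float("pixel_size_um") if "pixel_size_um" in values else None
    if "channels" in values:
        names = tuple(c.strip() for c in values["channels"].split(",") if c.strip())
        if not 1 <= len(names) <= 3:
            raise MetadataError(f"{path}: 'channels' must list 1-3 labels; got {names}")
    else:
        names = RGB_CHANNEL_NAMES
    reference = values.get("reference_channel", names[0])
    return AcquisitionMeta(
        frame_interval=interval,
        pixel_size=pixel_size,
        channel_names=names,
        reference_channel=reference,
    )
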