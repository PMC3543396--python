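"""Removal-aware timestamps and physical scale bars.

A frame's timestamp is a pure function of its *origin index* and the
acquisition frame interval — never of its position after filtering — so
videos stay truthfully timed no matter how many frames were removed.
Overlays can be burned into the pixels (white text / bar with a black
outline, rendered from a built-in bitmap font) or emitted as a sidecar
table only, leaving pixel data bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._font import render_text
from .errors import ConfigurationError, MetadataError
from .stack_io import AcquisitionMeta, FrameStack

CORNERS = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class TimestampSpec:
    """Timestamp overlay settings; format is fixed as MM:SS.mmm."""

    position: str = "top_left"
    scale: int = 1
    apply: str = "burn_in"  # or "sidecar_only"
    margin: int = 2

    def __post_init__(self) -> None:
        if self.position not in CORNERS:
            raise ConfigurationError(f"position must be one of {CORNERS}")
        if self.apply not in ("burn_in", "sidecar_only"):
            raise ConfigurationError("apply must be 'burn_in' or 'sidecar_only'")
        if self.scale < 1:
            raise ConfigurationError("scale must be >= 1")


def format_timestamp(seconds: float) -> str:
    """MM:SS.mmm with millisecond rounding (minutes may exceed two digits
    in very long recordings)."""
    if seconds < 0:
        raise ConfigurationError("timestamp seconds must be >= 0")
    total_ms = int(round(seconds * 1000.0))
    minutes, rem = divmod(total_ms, 60_000)
    sec, ms = divmod(rem, 1000)
    return f"{minutes:02d}:{sec:02d}.{ms:03d}"


def _corner_origin(position: str, H: int, W: int, h: int, w: int, margin: int):
    row = margin if position.startswith("top") else H - h - margin
    col = margin if position.endswith("left") else W - w - margin
    return max(0, row), max(0, col)


def _burn_mask(frame: np.ndarray, mask: np.ndarray, row: int, col: int) -> None:
    """White ink with a 1-px black outline, drawn in place on all channels."""
    h, w = mask.shape
    outline = ndimage.binary_dilation(mask, iterations=1) & ~mask
    region = frame[row : row + h, col : col + w]
    region[mask[: region.shape[0], : region.shape[1]]] = 255
    region[outline[: region.shape[0], : region.shape[1]]] = 0


def timestamp_overlay(
    stack: FrameStack,
    meta: AcquisitionMeta,
    spec: TimestampSpec | None = None,
) -> tuple[FrameStack, pd.DataFrame]:
    """Annotate each retained frame with its ORIGINAL acquisition time
    (origin index x frame interval).  Returns the (possibly) annotated
    stack and a sidecar table (always produced)."""
    spec = spec or TimestampSpec()
    if meta.frame_interval is None or meta.frame_interval <= 0:
        raise MetadataError("timestamping requires a positive frame_interval")
    times = stack.origin_indices * meta.frame_interval
    labels = [format_timestamp(t) for t in times]
    sidecar = pd.DataFrame({
        "origin_index": stack.origin_indices,
        "position_index": np.arange(stack.T),
        "time_s": times,
        "label": labels,
    })
    if spec.apply == "sidecar_only":
        return stack, sidecar
    frames = stack.frames.copy()
    for t, label in enumerate(labels):
        mask = render_text(label, scale=spec.scale)
        row, col = _corner_origin(
            spec.position, stack.H, stack.W, *mask.shape, spec.margin
        )
        _burn_mask(frames[t], mask, row, col)
    return stack.with_frames(frames), sidecar


def scale_bar_overlay(
    stack: FrameStack,
    meta: AcquisitionMeta,
    length_um: float,
    *,
    position: str = "bottom_right",
    apply: str = "burn_in",
    margin: int = 4,
) -> FrameStack:
    """Burn a horizontal bar of ``round(length_um / pixel_size)`` pixels
    with a micrometre label into every frame."""
    if meta.pixel_size is None:
        raise MetadataError("scale bar requires pixel_size in the metadata")
    if length_um <= 0:
        raise ConfigurationError("scale-bar length must be > 0 um")
    if position not in CORNERS:
        raise ConfigurationError(f"position must be one of {CORNERS}")
    bar_px = int(round(length_um / meta.pixel_size))
    if bar_px > stack.W - 2 * margin:
        raise ConfigurationError(
            f"scale bar of {bar_px} px does not fit a {stack.W}-px-wide frame"
        )
    if apply == "sidecar_only":
        return stack
    label = f"{length_um:g} um"
    text = render_text(label)
    bar_h = 3
    block_h = bar_h + 2 + text.shape[0]
    block_w = max(bar_px, text.shape[1])
    block = np.zeros((block_h, block_w), dtype=bool)
    block[0:bar_h, 0:bar_px] = True
    block[bar_h + 2 :, 0 : text.shape[1]] = text
    frames = stack.frames.copy()
    row, col = _corner_origin(position, stack.H, stack.W, block_h, block_w, margin)
    for t in range(stack.T):
        _burn_mask(frames[t], block, row, col)
    return stack.with_frames(frames)
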