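"""Minimal built-in 5x7 bitmap font for burn-in overlays.

Only the glyphs needed by timestamps ("MM:SS.mmm") and scale-bar labels
("<length> um") are provided.  Using a fixed bitmap keeps burned-in text
pixel-deterministic across platforms (no font libraries involved).
"""

from __future__ import annotations

import numpy as np

_GLYPHS: dict[str, tuple[str, ...]] = {
    "0": ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),
    "1": ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    "2": ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    "3": ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    "4": ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    "5": ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    "6": ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    "7": ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    "8": ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    "9": ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
    ":": ("00000", "00100", "00100", "00000", "00100", "00100", "00000"),
    ".": ("00000", "00000", "00000", "00000", "00000", "01100", "01100"),
    " ": ("00000", "00000", "00000", "00000", "00000", "00000", "00000"),
    "u": ("00000", "00000", "10001", "10001", "10001", "10011", "01101"),
    "m": ("00000", "00000", "11010", "10101", "10101", "10101", "10101"),
}

GLYPH_H, GLYPH_W = 7, 5


def render_text(text: str, scale: int = 1) -> np.ndarray:
    """Render ``text`` to a boolean mask (True = ink); 1-px letter spacing,
    integer ``scale`` magnification."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    cols = []
    for ch in text:
        glyph = _GLYPHS.get(ch, _GLYPHS[" "])
        block = np.array([[c == "1" for c in row] for row in glyph], dtype=bool)
        cols.append(block)
        cols.append(np.zeros((GLYPH_H, 1), dtype=bool))
    mask = np.hstack(cols[:-1]) if cols else np.zeros((GLYPH_H, 0), bool)
    if scale > 1:
        mask = np.kron(mask, np.ones((scale, scale), dtype=bool))
    return mask
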