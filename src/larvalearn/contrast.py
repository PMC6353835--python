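"""Visual-contrast arithmetic for conditioned patterns.

The conditioned pattern's grayscale value is the rounded mean of its RGB
channels; its visual contrast is the grayscale difference to the
pure-gray (grayscale-128) background shown on the other arena half.
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["BACKGROUND_GRAYSCALE", "pattern_grayscale", "visual_contrast"]

BACKGROUND_GRAYSCALE = 128


def pattern_grayscale(mean_rgb: Sequence[int]) -> int:
    """Grayscale value of a pattern: the rounded mean of its RGB channels."""
    rgb = tuple(mean_rgb)
    if len(rgb) != 3:
        raise ValueError(f"expected 3 RGB channels, got {len(rgb)}")
    for c in rgb:
        if not (0 <= c <= 255):
            raise ValueError(f"RGB channel {c} outside [0, 255]")
    return round(sum(rgb) / 3.0)


def visual_contrast(grayscale: int, background_grayscale: int = BACKGROUND_GRAYSCALE) -> int:
    """Grayscale difference between a conditioned pattern and the background."""
    for g in (grayscale, background_grayscale):
        if not (0 <= g <= 255):
            raise ValueError(f"grayscale {g} outside [0, 255]")
    return int(grayscale) - int(background_grayscale)
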