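"""Visual-contrast arithmetic of the standard conditioned patterns.

Each pattern's grayscale value is the rounded mean of its RGB channels;
its visual contrast is that grayscale minus the pure-gray (128)
background shown on the other arena half.  Negative contrast = darker
than the background; zero contrast (white-black checkerboard) means the
pattern differs from the background only in spatial structure.
"""

from larvalearn import TABLE_PATTERNS

print(f"{'pattern':28s} {'mean RGB':>15s} {'grayscale':>9s} {'contrast':>8s}")
for name, pat in TABLE_PATTERNS.items():
    print(f"{name:28s} {str(pat.mean_rgb):>15s} {pat.grayscale:9d} {pat.contrast:8d}")
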