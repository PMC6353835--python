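"""Single-fish dark-field tracking on grayscale frames.

A minimal re-implementation of the online image-processing stage: detect
the one bright fish-shaped blob in a dark-field frame and estimate head,
center and tail positions plus the heading angle.  Validated in closed
loop against :func:`render_fish`, which draws a synthetic larva with a
known ground-truth pose.

Image convention: row 0 is the top of the frame; arena coordinates have
y increasing upward, so ``row = (H - 1) - y / scale`` and
``col = x / scale`` with ``scale`` in cm per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .session import TrackPoint, ValidationError, wrap_angle_deg

__all__ = [
    "FrameImage",
    "DetectionError",
    "render_fish",
    "track_frame",
    "detect_turn_frames",
    "TURN_THRESHOLD_DEG",
]

TURN_THRESHOLD_DEG = 15.0


class DetectionError(RuntimeError):
    """No (or more than one) plausible fish blob was found in a frame."""


@dataclass
class FrameImage:
    """A grayscale frame plus the geometry linking pixels to arena cm."""

    pixels: np.ndarray  # 2-D float array, higher = brighter
    scale: float  # cm per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("FrameImage.pixels must be 2-D")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0 cm/px")

    def to_cm(self, row: float, col: float) -> tuple[float, float]:
        h = self.pixels.shape[0]
        return col * self.scale, ((h - 1) - row) * self.scale

    def to_px(self, x: float, y: float) -> tuple[float, float]:
        h = self.pixels.shape[0]
        return (h - 1) - y / self.scale, x / self.scale


def _elliptical_blob(rows: np.ndarray, cols: np.ndarray, r0: float, c0: float,
                     heading_deg: float, amp: float, sigma_par: float,
                     sigma_perp: float) -> np.ndarray:
    # axis direction in image coordinates (row decreases with +y)
    theta = np.radians(heading_deg)
    ur, uc = -np.sin(theta), np.cos(theta)
    dr, dc = rows - r0, cols - c0
    par = dr * ur + dc * uc
    perp = -dr * uc + dc * ur
    return amp * np.exp(-0.5 * ((par / sigma_par) ** 2 + (perp / sigma_perp) ** 2))


def render_fish(point: TrackPoint, image_shape: tuple[int, int] = (120, 120),
                scale: float = 0.025, rng: np.random.Generator | None = None,
                noise_sd: float = 0.01, background: float = 0.06) -> FrameImage:
    """Draw a synthetic larva at a known pose on a noisy dark background.

    The body is a pair of identical anisotropic Gaussian blobs placed
    symmetrically about the fish center along the heading, so the
    intensity-weighted centroid sits exactly on the center regardless of
    the threshold; a small, low-mass bright dot on the head side makes
    the head the brighter end without displacing the centroid
    appreciably (< 0.15 px).
    """
    h, w = image_shape
    img = np.full((h, w), background)
    frame = FrameImage(pixels=img, scale=scale)

    for label_, (x, y) in (("head", point.head), ("center", point.center),
                           ("tail", point.tail)):
        r, c = frame.to_px(x, y)
        if not (0 <= r < h and 0 <= c < w):
            raise ValidationError(f"fish {label_} at ({x}, {y}) cm falls outside the frame")

    theta = np.radians(point.heading)
    ux, uy = np.cos(theta), np.sin(theta)
    off = 0.05  # cm from center to each body-blob center
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    for s in (+1.0, -1.0):
        r0, c0 = frame.to_px(point.center[0] + s * off * ux,
                             point.center[1] + s * off * uy)
        img += _elliptical_blob(rows, cols, r0, c0, point.heading,
                                amp=1.0, sigma_par=2.6, sigma_perp=1.6)
    rh, ch = frame.to_px(point.center[0] + 1.5 * off * ux,
                         point.center[1] + 1.5 * off * uy)
    img += _elliptical_blob(rows, cols, rh, ch, point.heading,
                            amp=0.5, sigma_par=0.8, sigma_perp=0.8)
    if rng is not None and noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    frame.pixels = np.clip(img, 0.0, None)
    return frame


def track_frame(img: FrameImage, threshold: float | str = "auto",
                min_area_px: int = 12,
                prev_heading: float | None = None,
                asymmetry_floor: float = 1.05,
                t: float = 0.0) -> TrackPoint:
    """Estimate the fish pose from a single dark-field frame.

    The frame is thresholded (Otsu by default); exactly one connected
    component of plausible area must remain, else a
    :class:`DetectionError` is raised (the frame is flagged, never
    fabricated).  The center is the intensity-weighted centroid, the body
    axis the principal axis of the second central moments, head and tail
    the extremal points along the axis, with the head on the side of the
    brighter intensity peak.  When the peak asymmetry is below
    ``asymmetry_floor`` the head choice falls back to ``prev_heading``.
    """
    pixels = img.pixels
    thr = threshold_otsu(pixels) if threshold == "auto" else float(threshold)
    mask = pixels > thr
    labels = label(mask)
    regions = [r for r in regionprops(labels) if r.area >= min_area_px]
    if len(regions) != 1:
        raise DetectionError(
            f"expected exactly one fish blob, found {len(regions)} "
            f"(threshold {thr:.3f})"
        )
    region = regions[0]
    component = labels == region.label
    weights = np.where(component, pixels, 0.0)
    total = weights.sum()

    rows, cols = np.mgrid[0:pixels.shape[0], 0:pixels.shape[1]].astype(float)
    rbar = (weights * rows).sum() / total
    cbar = (weights * cols).sum() / total

    dr = rows - rbar
    dc = cols - cbar
    mrr = (weights * dr * dr).sum() / total
    mcc = (weights * dc * dc).sum() / total
    mrc = (weights * dr * dc).sum() / total
    cov = np.array([[mrr, mrc], [mrc, mcc]])
    eigvals, eigvecs = np.linalg.eigh(cov)
    vr, vc = eigvecs[:, np.argmax(eigvals)]  # major axis, (row, col) components

    proj = dr * vr + dc * vc
    pos = component & (proj > 0)
    neg = component & (proj < 0)
    if not pos.any() or not neg.any():
        raise DetectionError("degenerate blob: no extent along the principal axis")
    # compare brightness away from the axis midpoint, where the two body
    # lobes overlap and the peak side is decided by pixel-grid accident
    pos_far = component & (proj > 2.0)
    neg_far = component & (proj < -2.0)
    peak_pos = pixels[pos_far].max() if pos_far.any() else pixels[pos].max()
    peak_neg = pixels[neg_far].max() if neg_far.any() else pixels[neg].max()

    ratio = max(peak_pos, peak_neg) / max(min(peak_pos, peak_neg), 1e-12)
    head_sign = 1.0 if peak_pos >= peak_neg else -1.0
    heading = float(wrap_angle_deg(np.degrees(np.arctan2(-vr * head_sign, vc * head_sign))))
    if ratio < asymmetry_floor and prev_heading is not None:
        # ambiguous head/tail: keep the orientation closer to the last frame
        alt = float(wrap_angle_deg(heading + 180.0))
        d0 = abs(float(wrap_angle_deg(heading - prev_heading)))
        d1 = abs(float(wrap_angle_deg(alt - prev_heading)))
        if d1 < d0:
            heading = alt
            head_sign = -head_sign

    projs = proj[component] * head_sign
    rows_c = rows[component]
    cols_c = cols[component]
    i_head = int(np.argmax(projs))
    i_tail = int(np.argmin(projs))
    head = img.to_cm(rows_c[i_head], cols_c[i_head])
    tail = img.to_cm(rows_c[i_tail], cols_c[i_tail])
    center = img.to_cm(rbar, cbar)
    return TrackPoint(t=t, head=head, center=center, tail=tail, heading=heading)


def detect_turn_frames(headings: np.ndarray,
                       threshold_deg: float = TURN_THRESHOLD_DEG) -> np.ndarray:
    """Boolean mask marking frames whose wrapped heading change from the
    previous frame strictly exceeds the threshold.

    The change is computed on the circle, so 179 deg -> -179 deg is a
    2 deg change, not 358 deg.  The first frame is never a turn.
    """
    headings = np.asarray(headings, dtype=float)
    if headings.size < 2:
        raise ValidationError("detect_turn_frames needs at least 2 frames")
    dh = np.abs((np.diff(headings) + 180.0) % 360.0 - 180.0)
    mask = np.zeros(headings.size, dtype=bool)
    mask[1:] = dh > threshold_deg
    return mask
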