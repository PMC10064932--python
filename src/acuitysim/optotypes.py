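"""Programmatic Sloan optotype bank.

Renders the 10 Sloan letters (C D H K N O R S V Z) as grayscale rasters on a
fixed frame (default 255 x 255 px at 92 dpi viewed from 2 m), for every size
from -0.5 to +1.3 logMAR in 0.1 steps.  Letters are drawn from geometric
primitives on the canonical Sloan 5 x 5 grid (letter width = letter height,
stroke width = height / 5) rather than from a system font, so two builds with
the same configuration are bit-identical on any platform.

A letter of size L logMAR subtends 5 * 10**L arcmin; the arcmin-per-pixel
scale follows from the dot pitch (25.4 mm / dpi) and the viewing distance.
Sub-pixel sizes at the small end of the range are rendered anti-aliased
(4 x 4 supersampling of the analytic letter region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "SLOAN_LETTERS",
    "DEFAULT_LOGMAR_LEVELS",
    "RenderConfig",
    "OptotypeBank",
    "angular_scale",
    "render_optotype",
    "build_bank",
]

SLOAN_LETTERS = ("C", "D", "H", "K", "N", "O", "R", "S", "V", "Z")

#: -0.5 ... +1.3 logMAR in 0.1 steps (19 levels), rounded to one decimal.
DEFAULT_LOGMAR_LEVELS = tuple(round(-0.5 + 0.1 * i, 1) for i in range(19))


class RenderError(ValueError):
    """Raised when a letter cannot be drawn inside the image frame."""


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and intensity conventions of the optotype raster."""

    image_size_px: int = 255
    resolution_dpi: float = 92.0
    viewing_distance_m: float = 2.0
    letters: tuple[str, ...] = SLOAN_LETTERS
    logmar_levels: tuple[float, ...] = DEFAULT_LOGMAR_LEVELS
    foreground: float = 0.0  # dark letter ...
    background: float = 1.0  # ... on a white field (chart convention)
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.resolution_dpi <= 0 or self.viewing_distance_m <= 0:
            raise ValueError("dpi and viewing distance must be positive")
        if self.image_size_px <= 0:
            raise ValueError("image size must be positive")


def angular_scale(cfg: RenderConfig) -> float:
    """Angular pixel pitch in arcmin per pixel.

    arctan(pixel pitch / viewing distance), with pixel pitch 25.4 mm / dpi.
    """
    pitch_mm = 25.4 / cfg.resolution_dpi
    return math.degrees(math.atan2(pitch_mm, cfg.viewing_distance_m * 1000.0)) * 60.0


def letter_height_px(level: float, cfg: RenderConfig) -> float:
    """Letter height in pixels for a logMAR size (5 * 10**L arcmin tall)."""
    return 5.0 * 10.0 ** level / angular_scale(cfg)


# ---------------------------------------------------------------------------
# Letter geometry on the 5 x 5 Sloan grid.
#
# Each region function takes unit coordinates u (rightward, 0..5) and
# v (upward, 0..5) and returns a boolean ink mask.  Strokes are 1 unit wide.
# ---------------------------------------------------------------------------


def _rect(u, v, u0, u1, v0, v1):
    return (u >= u0) & (u <= u1) & (v >= v0) & (v <= v1)


def _disk(u, v, cu, cv, r):
    return (u - cu) ** 2 + (v - cv) ** 2 <= r * r


def _ring(u, v, cu, cv, ro, ri):
    d2 = (u - cu) ** 2 + (v - cv) ** 2
    return (d2 <= ro * ro) & (d2 >= ri * ri)


def _ellipse(u, v, cu, cv, a, b):
    return ((u - cu) / a) ** 2 + ((v - cv) / b) ** 2 <= 1.0


def _capsule(u, v, p0, p1, r):
    # distance from (u, v) to the segment p0-p1 <= r
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    L2 = dx * dx + dy * dy
    t = np.clip(((u - p0[0]) * dx + (v - p0[1]) * dy) / L2, 0.0, 1.0)
    qx = p0[0] + t * dx
    qy = p0[1] + t * dy
    return (u - qx) ** 2 + (v - qy) ** 2 <= r * r


def _slab(u, v, top_u, bot_u, v0, v1):
    """Unit-wide diagonal band: at height v the band spans [uL, uL + 1] with
    uL interpolating linearly from ``bot_u`` at v0 to ``top_u`` at v1."""
    frac = (v - v0) / (v1 - v0)
    uL = bot_u + (top_u - bot_u) * frac
    return (v >= v0) & (v <= v1) & (u >= uL) & (u <= uL + 1.0)


def _letter_C(u, v):
    return _ring(u, v, 2.5, 2.5, 2.5, 1.5) & ~_rect(u, v, 2.5, 5.0, 2.0, 3.0)


def _letter_D(u, v):
    outer = _rect(u, v, 0.0, 2.5, 0.0, 5.0) | _disk(u, v, 2.5, 2.5, 2.5)
    hole = _rect(u, v, 1.0, 2.5, 1.0, 4.0) | _disk(u, v, 2.5, 2.5, 1.5)
    return outer & ~hole


def _letter_H(u, v):
    return (
        _rect(u, v, 0.0, 1.0, 0.0, 5.0)
        | _rect(u, v, 4.0, 5.0, 0.0, 5.0)
        | _rect(u, v, 1.0, 4.0, 2.0, 3.0)
    )


def _letter_K(u, v):
    ink = (
        _rect(u, v, 0.0, 1.0, 0.0, 5.0)
        | _capsule(u, v, (0.8, 2.5), (4.6, 4.9), 0.5)
        | _capsule(u, v, (0.8, 2.5), (4.6, 0.1), 0.5)
    )
    return ink & _rect(u, v, 0.0, 5.0, 0.0, 5.0)


def _letter_N(u, v):
    return (
        _rect(u, v, 0.0, 1.0, 0.0, 5.0)
        | _rect(u, v, 4.0, 5.0, 0.0, 5.0)
        | _slab(u, v, 1.0, 3.0, 0.0, 5.0)
    )


def _letter_O(u, v):
    return _ring(u, v, 2.5, 2.5, 2.5, 1.5)


def _letter_R(u, v):
    bowl = (_rect(u, v, 0.0, 2.5, 2.0, 5.0) | _disk(u, v, 2.5, 3.5, 1.5)) & ~(
        _rect(u, v, 1.0, 2.5, 3.0, 4.0) | _disk(u, v, 2.5, 3.5, 0.5)
    )
    leg = _capsule(u, v, (2.2, 2.4), (4.5, 0.35), 0.5)
    return (bowl | leg) & _rect(u, v, 0.0, 5.0, 0.0, 5.0)


def _letter_S(u, v):
    top = (
        _ellipse(u, v, 2.5, 3.75, 2.5, 1.25)
        & ~_ellipse(u, v, 2.5, 3.75, 1.5, 0.25)
        & ~((u > 2.5) & (v < 3.75))
    )
    bottom = (
        _ellipse(u, v, 2.5, 1.25, 2.5, 1.25)
        & ~_ellipse(u, v, 2.5, 1.25, 1.5, 0.25)
        & ~((u < 2.5) & (v > 1.25))
    )
    # explicit middle stroke so the two hooks join with full stroke width
    mid = _rect(u, v, 1.5, 3.5, 2.0, 3.0)
    return top | bottom | mid


def _letter_V(u, v):
    left = _slab(u, v, 0.0, 2.0, 0.0, 5.0)
    right = _slab(u, v, 4.0, 2.0, 0.0, 5.0)
    return left | right


def _letter_Z(u, v):
    return (
        _rect(u, v, 0.0, 5.0, 4.0, 5.0)
        | _rect(u, v, 0.0, 5.0, 0.0, 1.0)
        | _slab(u, v, 4.0, 0.0, 1.0, 4.0)
    )


_LETTER_REGIONS = {
    "C": _letter_C,
    "D": _letter_D,
    "H": _letter_H,
    "K": _letter_K,
    "N": _letter_N,
    "O": _letter_O,
    "R": _letter_R,
    "S": _letter_S,
    "V": _letter_V,
    "Z": _letter_Z,
}


def render_optotype(letter: str, level: float, cfg: RenderConfig | None = None) -> np.ndarray:
    """Render one Sloan letter at a logMAR size, centered in the frame.

    Returns a float64 array of shape (image_size_px, image_size_px) with the
    configured background intensity and the letter drawn in the foreground
    intensity, anti-aliased by supersampled coverage.
    """
    cfg = cfg or RenderConfig()
    if letter not in _LETTER_REGIONS:
        raise ValueError(f"unknown Sloan letter {letter!r}")
    n = cfg.image_size_px
    h = letter_height_px(level, cfg)
    if h > n:
        raise RenderError(
            f"letter height {h:.1f}px exceeds the {n}px frame at {level} logMAR"
        )

    s = cfg.supersample
    # subpixel sample centers in pixel coordinates, restricted to the letter's
    # bounding box (plus one pixel of guard) for speed
    c = (n - 1) / 2.0
    half = h / 2.0
    lo = max(0, int(math.floor(c - half)) - 1)
    hi = min(n, int(math.ceil(c + half)) + 2)
    m = hi - lo
    offs = (np.arange(s) + 0.5) / s - 0.5
    px = np.arange(lo, hi, dtype=np.float64)
    xx = (px[:, None] + offs[None, :]).ravel()  # m*s subpixel coords
    # unit coordinates: u rightward, v upward; letter spans [0, 5] over h px.
    # Image rows run top to bottom, so v decreases with the pixel coordinate.
    uu = (xx - (c - half)) * (5.0 / h)
    vv = ((c + half) - xx) * (5.0 / h)
    U = np.broadcast_to(uu[None, :], (m * s, m * s))
    V = np.broadcast_to(vv[:, None], (m * s, m * s))
    mask = _LETTER_REGIONS[letter](U, V)
    coverage = mask.reshape(m, s, m, s).mean(axis=(1, 3))

    img = np.full((n, n), cfg.background, dtype=np.float64)
    img[lo:hi, lo:hi] += (cfg.foreground - cfg.background) * coverage
    return img


@dataclass(frozen=True)
class OptotypeBank:
    """All (letter, logMAR) rasters for one render configuration."""

    render_config: RenderConfig
    images: dict[tuple[str, float], np.ndarray] = field(repr=False, default_factory=dict)

    def __getitem__(self, key: tuple[str, float]) -> np.ndarray:
        letter, level = key
        return self.images[(letter, round(level, 1))]

    def __len__(self) -> int:
        return len(self.images)

    @property
    def letters(self) -> tuple[str, ...]:
        return self.render_config.letters

    @property
    def levels(self) -> tuple[float, ...]:
        return self.render_config.logmar_levels


def build_bank(cfg: RenderConfig | None = None) -> OptotypeBank:
    """Render the full optotype database (10 letters x 19 sizes by default).

    Deterministic: identical configurations give bit-identical banks.
    """
    cfg = cfg or RenderConfig()
    return _build_bank_cached(cfg)


@lru_cache(maxsize=4)
def _build_bank_cached(cfg: RenderConfig) -> OptotypeBank:
    images = {
        (letter, round(level, 1)): render_optotype(letter, level, cfg)
        for letter in cfg.letters
        for level in cfg.logmar_levels
    }
    return OptotypeBank(render_config=cfg, images=images)
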