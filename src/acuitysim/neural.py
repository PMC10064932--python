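"""Neural transfer function and neural noise.

After optical filtering, both template and test images pass through a
radially symmetric low-pass neural transfer function (NTF) standing for
post-retinal contrast attenuation in a young adult (nominally 25 years old)
at a photopic retinal illuminance of 1100 trolands.  The gain is modelled as
a log-linear fall-off with spatial frequency,

    NTF(f) = exp(-f / f0),

the single scale constant ``f0`` (cycles/degree) being a documented constant
of the build (see docs/methods.md for how it was fixed).  Zero-mean white
Gaussian noise of variance 0.144 (normalized-intensity units squared) is
then added to the test image only; the stored template is treated as the
noiseless neural representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optotypes import RenderConfig, angular_scale

__all__ = ["NTFConfig", "NoiseConfig", "ntf_gain", "ntf_grid", "apply_ntf", "add_noise"]


@dataclass(frozen=True)
class NTFConfig:
    """Parameterization of the neural low-pass filter.

    ``age_years`` and ``retinal_illuminance_td`` document the observer the
    constant represents; ``scale_cpd`` is the e-folding frequency of the
    exponential gain.
    """

    age_years: float = 25.0
    retinal_illuminance_td: float = 1100.0
    scale_cpd: float = 12.0

    def __post_init__(self) -> None:
        if self.scale_cpd <= 0:
            raise ValueError("NTF scale must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive white Gaussian neural noise (variance in intensity^2)."""

    variance: float = 0.144

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be nonnegative")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def ntf_gain(freq_cpd: np.ndarray | float, cfg: NTFConfig | None = None) -> np.ndarray | float:
    """Neural gain in [0, 1]; unity at DC, non-increasing with frequency."""
    cfg = cfg or NTFConfig()
    out = np.exp(-np.abs(np.asarray(freq_cpd, dtype=float)) / cfg.scale_cpd)
    return out if out.ndim else float(out)


def ntf_grid(render_cfg: RenderConfig, cfg: NTFConfig | None = None) -> np.ndarray:
    """Radial NTF sampled on the image's 2-D DFT frequency grid."""
    pixel_deg = angular_scale(render_cfg) / 60.0
    f = np.fft.fftfreq(render_cfg.image_size_px, d=pixel_deg)
    radial = np.hypot(f[:, None], f[None, :])
    return np.asarray(ntf_gain(radial, cfg))


def apply_ntf(img: np.ndarray, render_cfg: RenderConfig, cfg: NTFConfig | None = None) -> np.ndarray:
    """Filter an image with the radial NTF (mean luminance preserved)."""
    gain = ntf_grid(render_cfg, cfg)
    return np.real(np.fft.ifft2(np.fft.fft2(img) * gain))


def add_noise(img: np.ndarray, cfg: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Add pixel-wise zero-mean Gaussian noise; no clipping (linear pipeline)."""
    if cfg.variance == 0:
        return img.copy()
    return img + rng.standard_normal(img.shape) * cfg.sd
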