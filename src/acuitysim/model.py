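"""End-to-end template-matching acuity engine.

Wires the pipeline together: rendered optotype -> optical filtering (OTF for
the population-average higher-order aberrations, plus induced defocus for
test images) -> neural transfer function -> additive neural noise (test image
only) -> normalized cross-correlation identification against the 10
same-size templates.

Temporal defocus is handled through the linearity of the filtering steps:
the average of N defocused images equals the single image filtered by the
average of the N OTFs, so a trial's effective stimulus is produced by one
inverse FFT of the test spectrum multiplied by a weighted-mean OTF.  OTFs
are cached on a defocus grid quantized to ``quant_step_d`` diopters (default
0.01 D, far below the eye's depth of focus), and the weighted mean is taken
over the quantized values present in the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import optics
from .matching import MatcherConfig, MatchResult, decide
from .neural import NoiseConfig, NTFConfig, ntf_grid
from .optics import OpticsConfig, ZernikeCoefficients, load_hoa_population
from .optotypes import OptotypeBank, RenderConfig, build_bank, letter_height_px
from .temporal import (
    DefocusSignal,
    EpochConfig,
    Strategy,
    defocus_series,
    strategy_sample_indices,
)

__all__ = ["AcuityEngine", "TrialOutcome"]


@dataclass(frozen=True)
class TrialOutcome:
    presented: str
    response: str
    correct: bool
    level: float
    t0_ms: float
    match: MatchResult


class AcuityEngine:
    """Shared, condition-independent state for acuity simulations."""

    def __init__(
        self,
        bank: OptotypeBank | None = None,
        hoa: ZernikeCoefficients | None = None,
        optics_cfg: OpticsConfig | None = None,
        ntf_cfg: NTFConfig | None = None,
        noise_cfg: NoiseConfig | None = None,
        matcher_cfg: MatcherConfig | None = None,
        epoch: EpochConfig | None = None,
        quant_step_d: float = 0.01,
    ) -> None:
        self.bank = bank or build_bank()
        self.render_cfg: RenderConfig = self.bank.render_config
        self.hoa = load_hoa_population() if hoa is None else hoa
        self.optics_cfg = optics_cfg or OpticsConfig()
        self.ntf_cfg = ntf_cfg or NTFConfig()
        self.noise_cfg = noise_cfg or NoiseConfig()
        self.matcher_cfg = matcher_cfg or MatcherConfig()
        self.epoch = epoch or EpochConfig()
        self.quant_step_d = float(quant_step_d)

        n = self.render_cfg.image_size_px
        self._n = n
        self._ntf = ntf_grid(self.render_cfg, self.ntf_cfg)[:, : n // 2 + 1]
        self._otf_cache: dict[int, np.ndarray] = {}
        self._test_spec: dict[tuple[str, float], np.ndarray] = {}
        self._templates: dict[float, dict[str, np.ndarray]] = {}
        self._rois: dict[float, tuple[slice, slice, int]] = {}
        self._match_tables: dict[float, tuple] = {}

    # -- optical transfer functions --------------------------------------

    def _otf_rfft(self, z: ZernikeCoefficients) -> np.ndarray:
        """OTF on the image grid, reduced to the rfft2 layout (complex64)."""
        full = optics.otf_image_grid(z, self.render_cfg, self.optics_cfg)
        return full[:, : self._n // 2 + 1].astype(np.complex64)

    def otf_for_defocus_index(self, qidx: int) -> np.ndarray:
        """Cached HOA + defocus OTF for a quantized defocus level."""
        got = self._otf_cache.get(qidx)
        if got is None:
            d = qidx * self.quant_step_d
            got = self._otf_rfft(self.hoa.with_defocus(d))
            self._otf_cache[qidx] = got
        return got

    def mean_otf(self, defocus_values_d: np.ndarray) -> np.ndarray:
        """Weighted mean OTF over the (quantized) defocus samples."""
        q = np.rint(np.asarray(defocus_values_d) / self.quant_step_d).astype(int)
        idx, counts = np.unique(q, return_counts=True)
        total = counts.sum()
        out = np.zeros_like(self.otf_for_defocus_index(int(idx[0])))
        for i, c in zip(idx, counts):
            out += self.otf_for_defocus_index(int(i)) * np.complex64(c / total)
        return out

    # -- stimulus/template construction ----------------------------------

    def _test_spectrum(self, letter: str, level: float) -> np.ndarray:
        key = (letter, round(level, 1))
        got = self._test_spec.get(key)
        if got is None:
            img = self.bank[key]
            got = (np.fft.rfft2(img) * self._ntf).astype(np.complex64)
            self._test_spec[key] = got
        return got

    def _roi(self, level: float) -> tuple[slice, slice, int]:
        """Template bounding box (centered) and the 10%-dilation margin."""
        level = round(level, 1)
        got = self._rois.get(level)
        if got is None:
            n = self._n
            h = letter_height_px(level, self.render_cfg)
            side = min(n, int(np.ceil(h)) + 2)
            c = (n - 1) / 2.0
            lo = max(0, int(round(c - side / 2.0)))
            hi = min(n, lo + side)
            margin = max(1, int(round(self.matcher_cfg.roi_dilation / 2.0 * side)))
            got = (slice(lo, hi), slice(lo, hi), margin)
            self._rois[level] = got
        return got

    def templates_for_level(self, level: float) -> dict[str, np.ndarray]:
        """HOA+NTF-filtered template crops for all 10 letters at one size."""
        level = round(level, 1)
        got = self._templates.get(level)
        if got is None:
            rs, cs, _ = self._roi(level)
            otf0 = self.otf_for_defocus_index(0)
            got = {}
            for letter in self.bank.letters:
                spec = self._test_spectrum(letter, level) * otf0
                img = np.fft.irfft2(spec, s=(self._n, self._n))
                got[letter] = np.ascontiguousarray(img[rs, cs], dtype=np.float64)
            self._templates[level] = got
        return got

    def effective_test_image(
        self, letter: str, level: float, defocus_values_d: np.ndarray
    ) -> np.ndarray:
        """Noise-free effective stimulus: the epoch-averaged defocused image,
        computed as the test spectrum filtered by the mean OTF."""
        spec = self._test_spectrum(letter, level) * self.mean_otf(defocus_values_d)
        return np.fft.irfft2(spec, s=(self._n, self._n))

    # -- decision ---------------------------------------------------------

    def _matcher_tables(self, level: float):
        """Precomputed zero-mean template spectra and norms for batched NCC.

        The sliding NCC numerator is a linear correlation of the search
        window with each zero-mean template.  With the FFT taken at the
        search-window size the circular wrap only contaminates positions
        outside the valid region (overlap-save), so no zero padding is
        needed.  Denominators use sliding window sums from integral images,
        shared across the 10 templates (identical window size).
        """
        level = round(level, 1)
        got = self._match_tables.get(level)
        if got is None:
            rs, cs, margin = self._roi(level)
            side = rs.stop - rs.start
            p = side + 2 * margin
            letters, specs, norms = [], [], []
            for letter, tpl in self.templates_for_level(level).items():
                z = tpl - tpl.mean()
                letters.append(letter)
                norms.append(float(np.sqrt((z * z).sum())))
                specs.append(np.fft.rfft2(z[::-1, ::-1], s=(p, p)))
            got = (tuple(letters), np.stack(specs), np.asarray(norms), side, p)
            self._match_tables[level] = got
        return got

    def identify_image(
        self, test: np.ndarray, level: float, rng: np.random.Generator
    ) -> MatchResult:
        """Match a full-frame test image against the 10 same-size templates.

        Equivalent to per-template ``matching.normalized_xcorr_peak`` over
        the dilated-bounding-box ROI (a tested equivalence), batched for
        speed.
        """
        rs, cs, margin = self._roi(level)
        n = self._n
        r0, r1 = max(0, rs.start - margin), min(n, rs.stop + margin)
        c0, c1 = max(0, cs.start - margin), min(n, cs.stop + margin)
        search = test[r0:r1, c0:c1]
        letters, specs, norms, side, p = self._matcher_tables(level)
        if search.shape != (p, p):  # ROI clipped at the frame edge: slow path
            from .matching import normalized_xcorr_peak

            templates = self.templates_for_level(level)
            scores = {
                letter: normalized_xcorr_peak(search, tpl, self.matcher_cfg)
                for letter, tpl in templates.items()
            }
            return decide(scores, self.matcher_cfg, rng)

        area = side * side
        wspec = np.fft.rfft2(search)
        corr = np.fft.irfft2(wspec[None, :, :] * specs, s=(p, p))
        valid = corr[:, side - 1 :, side - 1 :]  # linear corr at valid offsets

        # sliding sums over side x side windows from padded cumulative sums
        c1_ = np.zeros((p + 1, p + 1))
        c2_ = np.zeros((p + 1, p + 1))
        c1_[1:, 1:] = search.cumsum(0).cumsum(1)
        c2_[1:, 1:] = (search * search).cumsum(0).cumsum(1)

        def window_sums(c):
            return (
                c[side:, side:] - c[:-side, side:] - c[side:, :-side] + c[:-side, :-side]
            )

        wsum = window_sums(c1_)
        wss = window_sums(c2_)
        wvar = np.maximum(wss - wsum * wsum / area, 0.0)
        denom = np.sqrt(wvar)[None, :, :] * norms[:, None, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ncc = np.where(denom > 1e-12, valid / denom, 0.0)
        peaks = np.clip(np.nan_to_num(ncc), -1.0, 1.0).max(axis=(1, 2))
        scores = dict(zip(letters, (float(x) for x in peaks)))
        return decide(scores, self.matcher_cfg, rng)

    def effective_stimulus(
        self,
        series: np.ndarray,
        letter: str,
        level: float,
        strategy: Strategy | str,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Noise-free effective image a strategy extracts from a defocus
        series (average / least-bin / early / late / mixed)."""
        idx = strategy_sample_indices(series, strategy, self.epoch, rng)
        return self.effective_test_image(letter, level, series[idx])

    # -- one trial --------------------------------------------------------

    def run_trial(
        self,
        letter: str,
        level: float,
        signal: DefocusSignal,
        strategy: Strategy | str,
        rng: np.random.Generator,
    ) -> TrialOutcome:
        """Simulate one presentation: random epoch placement on the defocus
        cycle, strategy-weighted OTF averaging, NTF, noise, identification."""
        t0_ms = float(rng.uniform(0.0, signal.period_s * 1e3))
        series = defocus_series(signal, t0_ms, self.epoch)
        idx = strategy_sample_indices(series, strategy, self.epoch, rng)
        img = self.effective_test_image(letter, level, series[idx])
        if self.noise_cfg.variance > 0:
            img = img + rng.standard_normal(img.shape) * self.noise_cfg.sd
        match = self.identify_image(img, level, rng)
        return TrialOutcome(
            presented=letter,
            response=match.letter,
            correct=match.letter == letter,
            level=round(level, 1),
            t0_ms=t0_ms,
            match=match,
        )
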