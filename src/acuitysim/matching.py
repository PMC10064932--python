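"""Template identification by normalized cross-correlation.

The decision stage slides each same-size template over the test image and
takes the peak zero-mean normalized cross-correlation (NCC).  Templates whose
peak reaches the candidate threshold (default 0.95) form the candidate set;
the response is the candidate with the highest peak.  Peaks that are equal
when rounded to three decimals are resolved by a seeded random pick, and if
no template reaches threshold the observer still answers (forced choice) with
the global argmax.

Matching is restricted to the region containing the optotype: both the
template and the search area are cropped to the letter's bounding box dilated
by 10%, which keeps spurious peaks in blank field regions out of the
decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

__all__ = ["MatcherConfig", "MatchResult", "normalized_xcorr_peak", "identify"]


@dataclass(frozen=True)
class MatcherConfig:
    candidate_threshold: float = 0.95
    tie_decimals: int = 3
    roi_dilation: float = 0.10  # bounding-box dilation (fraction of its side)

    def __post_init__(self) -> None:
        if not (0.0 < self.candidate_threshold <= 1.0):
            raise ValueError("candidate threshold must be in (0, 1]")


@dataclass(frozen=True)
class MatchResult:
    letter: str
    scores: dict[str, float] = field(repr=False)
    tie_broken: bool = False
    candidates: tuple[str, ...] = ()


def normalized_xcorr_peak(
    test: np.ndarray, template: np.ndarray, cfg: MatcherConfig | None = None
) -> float:
    """Peak sliding NCC of ``template`` over ``test`` (template <= test).

    Zero-variance windows contribute a score of 0.
    """
    if template.shape[0] > test.shape[0] or template.shape[1] > test.shape[1]:
        raise ValueError("template must not exceed the test image")
    if float(template.std()) == 0.0:
        return 0.0
    scores = match_template(test, template, pad_input=False)
    scores = np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)
    return float(np.clip(scores, -1.0, 1.0).max())


def identify(
    test: np.ndarray,
    templates: dict[str, np.ndarray],
    cfg: MatcherConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MatchResult:
    """Forced-choice identification of the test image among 10 templates."""
    cfg = cfg or MatcherConfig()
    if len(templates) != 10:
        raise ValueError(f"expected 10 templates, got {len(templates)}")
    scores = {
        letter: normalized_xcorr_peak(test, tpl, cfg) for letter, tpl in templates.items()
    }
    return decide(scores, cfg, rng)


def decide(
    scores: dict[str, float],
    cfg: MatcherConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MatchResult:
    """Apply the candidate-threshold / argmax / tie-break decision rule."""
    cfg = cfg or MatcherConfig()
    candidates = tuple(l for l, s in scores.items() if s >= cfg.candidate_threshold)
    pool = candidates if candidates else tuple(scores)
    rounded = {l: round(scores[l], cfg.tie_decimals) for l in pool}
    top = max(rounded.values())
    tied = [l for l in pool if rounded[l] == top]
    if len(tied) > 1:
        if rng is None:
            rng = np.random.default_rng()
        choice = tied[int(rng.integers(len(tied)))]
        return MatchResult(choice, scores, tie_broken=True, candidates=candidates)
    return MatchResult(tied[0], scores, tie_broken=False, candidates=candidates)
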