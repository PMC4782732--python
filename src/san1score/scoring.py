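"""The sliding-window San1 similarity score and the global initial score.

For every valid window center the score multiplies three window-level
quantities: the fraction of residues with consensus disorder above
threshold, the fraction of residues inside qualifying ANCHOR-positive
stretches (15-40 residues by default), and the length of the longest
lysine-free run in the window divided by the window size. A protein is
summarized by the maximum product over all centers ("the San1
similarity score").

Window geometry
---------------
An even window of width ``w`` centered at 0-based index ``i`` spans
``[i - w/2, i + w/2)``; valid centers are ``i in [w/2, n - w/2)``, so
for the default ``w = 150`` the score is undefined at the first and
last 75 positions and a protein of length ``n`` has ``n - 150`` valid
centers. Proteins with no valid center (length <= window) are assigned
a score of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import longest_k_free_run, lysine_positions, stretch_coverage_mask
from .records import AnnotatedProtein, Run, ScoreParams

__all__ = [
    "WindowComponents",
    "San1Result",
    "InitialScore",
    "ScoreProfile",
    "valid_centers",
    "window_components",
    "score_profile",
    "san1_similarity",
    "initial_score",
]

_PRODUCT_TOL = 1e-12


@dataclass(frozen=True)
class WindowComponents:
    """The three window-level quantities and their product at one center."""

    center: int
    window: Run
    disorder_frac: float
    anchor_stretch_frac: float
    kfree_frac: float
    product: float

    def __post_init__(self) -> None:
        expected = self.disorder_frac * self.anchor_stretch_frac * self.kfree_frac
        if abs(self.product - expected) > _PRODUCT_TOL:
            raise ValueError("product inconsistent with its factors")


@dataclass(frozen=True)
class San1Result:
    """Per-protein similarity score with its best window.

    ``best`` is absent exactly when the protein has no valid window
    center (length <= window), in which case the score is zero and
    ``defined_range`` is empty.
    """

    protein_id: str
    score: float
    best: WindowComponents | None
    defined_range: Run

    def __post_init__(self) -> None:
        if self.best is None:
            if self.score != 0.0:
                raise ValueError("score must be 0 when no window is defined")
        elif self.score != self.best.product:
            raise ValueError("score must equal the best window's product")


@dataclass(frozen=True)
class InitialScore:
    """Whole-protein disorder fraction x ANCHOR stretch score (the
    pre-sliding-window ranking statistic)."""

    protein_id: str
    disorder_frac: float
    anchor_stretch: float
    product: float

    def __post_init__(self) -> None:
        if abs(self.product - self.disorder_frac * self.anchor_stretch) > _PRODUCT_TOL:
            raise ValueError("product inconsistent with its factors")


@dataclass(frozen=True)
class ScoreProfile:
    """Per-center component vectors for one protein (for profile plots)."""

    protein_id: str
    centers: np.ndarray
    disorder_frac: np.ndarray
    anchor_stretch_frac: np.ndarray
    kfree_frac: np.ndarray
    product: np.ndarray


def valid_centers(n: int, params: ScoreParams) -> Run:
    """The half-open range of valid window centers for a protein of length *n*.

    Empty (``start == end``) when ``n <= params.window``.
    """
    half = params.window // 2
    lo, hi = half, n - half
    if hi <= lo:
        return Run(0, 0)
    return Run(lo, hi)


def window_components(
    protein: AnnotatedProtein, params: ScoreParams, center: int
) -> WindowComponents:
    """Compute the three quantities over the window centered at *center*.

    This is the definitional, from-scratch computation; the sliding
    profile in :func:`score_profile` must agree with it exactly.
    """
    rng = valid_centers(len(protein), params)
    if not (rng.start <= center < rng.end):
        raise ValueError(
            f"{protein.id}: center {center} outside defined range "
            f"[{rng.start}, {rng.end})"
        )
    half = params.window // 2
    window = Run(center - half, center + half)
    w = params.window

    dvals = protein.disorder.values[window.start : window.end]
    disorder_frac = float(np.count_nonzero(dvals > params.disorder_threshold)) / w

    mask = stretch_coverage_mask(protein, params)
    anchor_frac = float(np.count_nonzero(mask[window.start : window.end])) / w

    kfree = longest_k_free_run(protein.record.sequence, window).length / w

    return WindowComponents(
        center=center,
        window=window,
        disorder_frac=disorder_frac,
        anchor_stretch_frac=anchor_frac,
        kfree_frac=kfree,
        product=disorder_frac * anchor_frac * kfree,
    )


def score_profile(protein: AnnotatedProtein, params: ScoreParams) -> ScoreProfile:
    """Component vectors at every valid center.

    Uses prefix sums for the two fraction terms; the lysine-free term is
    computed per center from the sorted lysine positions. Agreement with
    per-center :func:`window_components` is a tested invariant, not an
    assumption.
    """
    n = len(protein)
    rng = valid_centers(n, params)
    centers = np.arange(rng.start, rng.end)
    if centers.size == 0:
        empty = np.empty(0)
        return ScoreProfile(protein.id, centers, empty, empty, empty, empty)

    w = params.window
    half = w // 2
    starts = centers - half
    ends = centers + half

    disorder_pos = np.concatenate(
        ([0], np.cumsum(protein.disorder.values > params.disorder_threshold))
    )
    mask_cum = np.concatenate(
        ([0], np.cumsum(stretch_coverage_mask(protein, params)))
    )
    disorder_frac = (disorder_pos[ends] - disorder_pos[starts]) / w
    anchor_frac = (mask_cum[ends] - mask_cum[starts]) / w

    kpos = np.asarray(lysine_positions(protein.record.sequence), dtype=int)
    kfree_len = np.empty(centers.size, dtype=float)
    lo_idx = np.searchsorted(kpos, starts, side="left")
    hi_idx = np.searchsorted(kpos, ends, side="left")
    for j in range(centers.size):
        ks = kpos[lo_idx[j] : hi_idx[j]]
        if ks.size == 0:
            kfree_len[j] = w
        else:
            first = ks[0] - starts[j]
            last = ends[j] - ks[-1] - 1
            inner = int(np.max(np.diff(ks))) - 1 if ks.size > 1 else 0
            kfree_len[j] = max(first, last, inner)
    kfree_frac = kfree_len / w

    return ScoreProfile(
        protein_id=protein.id,
        centers=centers,
        disorder_frac=disorder_frac,
        anchor_stretch_frac=anchor_frac,
        kfree_frac=kfree_frac,
        product=disorder_frac * anchor_frac * kfree_frac,
    )


def san1_similarity(protein: AnnotatedProtein, params: ScoreParams) -> San1Result:
    """Maximum window product over all valid centers (leftmost on ties)."""
    profile = score_profile(protein, params)
    rng = valid_centers(len(protein), params)
    if profile.centers.size == 0:
        return San1Result(protein.id, 0.0, None, rng)
    j = int(np.argmax(profile.product))  # argmax returns the leftmost maximum
    center = int(profile.centers[j])
    half = params.window // 2
    best = WindowComponents(
        center=center,
        window=Run(center - half, center + half),
        disorder_frac=float(profile.disorder_frac[j]),
        anchor_stretch_frac=float(profile.anchor_stretch_frac[j]),
        kfree_frac=float(profile.kfree_frac[j]),
        product=float(profile.product[j]),
    )
    return San1Result(protein.id, best.product, best, rng)


def initial_score(protein: AnnotatedProtein, params: ScoreParams) -> InitialScore:
    """Whole-protein disorder fraction times whole-protein ANCHOR stretch score."""
    from .features import anchor_stretch_score, disorder_fraction

    d = disorder_fraction(protein.disorder, params.disorder_threshold)
    a = anchor_stretch_score(protein, params)
    return InitialScore(protein.id, d, a, d * a)
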