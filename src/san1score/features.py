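"""Per-protein track-derived features.

Disorder fractions, ANCHOR-positive runs and qualifying binding
stretches, stretch coverage masks, and lysine run analysis. All
thresholding is strict (value > threshold); a value exactly equal to
the threshold is negative.
"""

from __future__ import annotations

import numpy as np

from .records import AnnotatedProtein, ResidueTrack, Run, ScoreParams

__all__ = [
    "disorder_fraction",
    "positive_fraction",
    "find_positive_runs",
    "qualifying_stretches",
    "anchor_stretch_score",
    "stretch_coverage_mask",
    "lysine_positions",
    "longest_k_free_run",
]


def positive_fraction(track: ResidueTrack, threshold: float) -> float:
    """Fraction of residues with track value strictly above *threshold*."""
    return float(np.count_nonzero(track.values > threshold)) / len(track)


def disorder_fraction(track: ResidueTrack, threshold: float = 0.5) -> float:
    """Fraction of residues predicted disordered (consensus > *threshold*).

    Same formula as :func:`positive_fraction`, restricted to consensus
    disorder tracks.
    """
    if track.kind != "disorder_consensus":
        raise ValueError(f"expected a disorder_consensus track, got {track.kind}")
    return positive_fraction(track, threshold)


def find_positive_runs(track: ResidueTrack, threshold: float) -> list[Run]:
    """Maximal runs of consecutive residues with value > *threshold*.

    Returns runs in ascending start order; runs are disjoint and
    non-adjacent (each maximal by construction).
    """
    positive = track.values > threshold
    return _mask_runs(positive)


def _mask_runs(mask: np.ndarray) -> list[Run]:
    """Maximal True-runs of a boolean vector as half-open intervals."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [Run(int(s), int(e)) for s, e in zip(starts, ends)]


def qualifying_stretches(runs: list[Run], params: ScoreParams) -> list[Run]:
    """Subset of maximal runs whose length lies in [stretch_min, stretch_max].

    Qualification is a property of the maximal run: a run longer than
    ``stretch_max`` contributes nothing (no sub-window is counted).
    """
    return [r for r in runs if params.stretch_min <= r.length <= params.stretch_max]


def anchor_stretch_score(protein: AnnotatedProtein, params: ScoreParams) -> float:
    """Residues inside qualifying ANCHOR stretches, normalized by protein length."""
    runs = find_positive_runs(protein.anchor, params.anchor_threshold)
    kept = qualifying_stretches(runs, params)
    return float(sum(r.length for r in kept)) / len(protein)


def stretch_coverage_mask(protein: AnnotatedProtein, params: ScoreParams) -> np.ndarray:
    """Boolean per-residue mask of qualifying-stretch coverage.

    Qualification is decided once on the full protein; windowed scores
    later intersect this mask with the window, so a stretch straddling a
    window boundary contributes its in-window residues without its
    qualification status depending on window placement.
    """
    mask = np.zeros(len(protein), dtype=bool)
    runs = find_positive_runs(protein.anchor, params.anchor_threshold)
    for r in qualifying_stretches(runs, params):
        mask[r.start : r.end] = True
    return mask


def lysine_positions(sequence: str) -> list[int]:
    """Ascending 0-based indices of lysine (K) residues."""
    return [i for i, c in enumerate(sequence) if c == "K"]


def longest_k_free_run(sequence: str, interval: Run | None = None) -> Run:
    """Longest lysine-free run within *interval* (whole sequence if None).

    Ties are broken leftmost. Any non-K letter (including X) counts as
    lysine-free. If the interval consists entirely of lysines, a
    zero-length sentinel run at the interval start is returned.
    """
    if interval is None:
        start, end = 0, len(sequence)
    else:
        start = max(0, interval.start)
        end = min(len(sequence), interval.end)
        if start >= end:
            raise ValueError(f"interval [{interval.start}, {interval.end}) is empty")

    best_start, best_len = start, 0
    run_start = start
    for i in range(start, end):
        if sequence[i] == "K":
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = i + 1
    if end - run_start > best_len:
        best_start, best_len = run_start, end - run_start
    return Run(best_start, best_start + best_len)
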