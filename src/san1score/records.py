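"""Core data containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the
1-based inclusive convention of per-residue predictor files exists only
at the I/O boundary (see :mod:`san1score.io_tables`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids; X is additionally accepted in input
#: sequences and is treated as "not lysine" throughout.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = frozenset(AMINO_ACIDS + "X")

TRACK_KINDS = ("disorder_consensus", "anchor")


@dataclass(frozen=True)
class Run:
    """A half-open interval ``[start, end)`` of residue positions.

    Runs produced by run detection always have length >= 1; a
    zero-length ``Run`` is used only as the documented sentinel returned
    by :func:`san1score.features.longest_k_free_run` on an all-lysine
    interval.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid run [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScoreParams:
    """All thresholds and window sizes of the similarity score.

    Parameters
    ----------
    disorder_threshold, anchor_threshold
        Per-residue scores strictly above these count as positive.
    stretch_min, stretch_max
        Inclusive length bounds for a maximal ANCHOR-positive run to
        qualify as a binding stretch (default 15-40 residues).
    window
        Sliding-window width in residues (default 150); must be even so
        the window is centered symmetrically.
    """

    disorder_threshold: float = 0.5
    anchor_threshold: float = 0.5
    stretch_min: int = 15
    stretch_max: int = 40
    window: int = 150

    def __post_init__(self) -> None:
        for name in ("disorder_threshold", "anchor_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 1 <= self.stretch_min <= self.stretch_max:
            raise ValueError(
                f"need 1 <= stretch_min <= stretch_max, got "
                f"[{self.stretch_min}, {self.stretch_max}]"
            )
        if self.window < 2 or self.window % 2:
            raise ValueError(f"window must be an even integer >= 2, got {self.window}")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identity metadata."""

    id: str
    sequence: str
    name: str = ""
    organism: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must have length >= 1")
        bad = [
            (i, c) for i, c in enumerate(self.sequence) if c not in VALID_LETTERS
        ]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"{self.id}: invalid amino-acid character {c!r} at position {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueTrack:
    """A named per-residue score vector in [0, 1] aligned to a sequence."""

    protein_id: str
    kind: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}; expected {TRACK_KINDS}")
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValueError(f"{self.protein_id}/{self.kind}: track must be a non-empty vector")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{self.protein_id}/{self.kind}: non-finite track value")
        if values.min() < 0.0 or values.max() > 1.0:
            i = int(np.argmax((values < 0.0) | (values > 1.0)))
            raise ValueError(
                f"{self.protein_id}/{self.kind}: value {values[i]} at position "
                f"{i + 1} outside [0, 1]"
            )

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class AnnotatedProtein:
    """A protein together with its disorder and ANCHOR tracks."""

    record: ProteinRecord
    disorder: ResidueTrack
    anchor: ResidueTrack

    def __post_init__(self) -> None:
        n = len(self.record)
        for track, kind in ((self.disorder, "disorder_consensus"), (self.anchor, "anchor")):
            if track.kind != kind:
                raise ValueError(
                    f"{self.record.id}: expected a {kind} track, got {track.kind}"
                )
            if track.protein_id != self.record.id:
                raise ValueError(
                    f"track protein_id {track.protein_id!r} does not match "
                    f"record id {self.record.id!r}"
                )
            if len(track) != n:
                raise ValueError(
                    f"{self.record.id}: {kind} track length {len(track)} != "
                    f"sequence length {n}"
                )

    @property
    def id(self) -> str:
        return self.record.id

    def __len__(self) -> int:
        return len(self.record)
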