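"""Candidate ranking, top-N extraction, and the parameter-sensitivity scan."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .records import AnnotatedProtein, ScoreParams
from .scoring import InitialScore, San1Result, initial_score, san1_similarity

__all__ = [
    "RankEntry",
    "RankTable",
    "OverlapResult",
    "rank_proteins",
    "top_n",
    "sensitivity_scan",
]


@dataclass(frozen=True)
class RankEntry:
    protein_id: str
    score: float
    rank: int


@dataclass(frozen=True)
class RankTable:
    """Proteins ordered by descending score with competition ranks.

    Tied scores share the better rank and subsequent ranks are skipped
    (ranks 1, 2, 2, 4, ...); exact ties are ordered by protein id so the
    table is deterministic.
    """

    entries: tuple[RankEntry, ...]
    score_kind: str
    params: ScoreParams


def _score_of(result: San1Result | InitialScore) -> float:
    return result.score if isinstance(result, San1Result) else result.product


def rank_proteins(
    results: list[San1Result] | list[InitialScore],
    score_kind: str,
    params: ScoreParams | None = None,
) -> RankTable:
    """Build a competition-ranked table from scoring results.

    ``score_kind`` is ``"san1"`` for sliding-window results or
    ``"initial"`` for whole-protein product scores.
    """
    if score_kind not in ("san1", "initial"):
        raise ValueError(f"score_kind must be 'san1' or 'initial', got {score_kind!r}")
    if not results:
        raise ValueError("cannot rank an empty result list")
    ids = [r.protein_id for r in results]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))
        raise ValueError(f"duplicate protein id {dup!r} in results")

    ordered = sorted(results, key=lambda r: (-_score_of(r), r.protein_id))
    entries = []
    rank = 0
    prev_score: float | None = None
    for i, r in enumerate(ordered):
        s = _score_of(r)
        if prev_score is None or s != prev_score:
            rank = i + 1
            prev_score = s
        entries.append(RankEntry(r.protein_id, s, rank))
    return RankTable(tuple(entries), score_kind, params or ScoreParams())


def top_n(table: RankTable, n: int) -> set[str]:
    """Ids with rank <= n.

    Ties straddling the cutoff are included, so the returned set can be
    larger than *n*; if *n* exceeds the table size the whole table is
    returned with a warning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if n > len(table.entries):
        warnings.warn(
            f"top_n: n={n} exceeds table size {len(table.entries)}; "
            "returning the whole table",
            stacklevel=2,
        )
    return {e.protein_id for e in table.entries if e.rank <= n}


@dataclass(frozen=True)
class OverlapResult:
    """Top-N overlap between the base parameterization and one variant.

    ``preserved`` is ``|top_a & top_b|``. Because ties straddling the
    rank-N cutoff are included, the top sets (whose sizes are recorded)
    can exceed *n*, and so can ``preserved``; with distinct scores at
    the boundary, ``preserved <= n`` and an identical variant preserves
    exactly *n*.
    """

    params_a: ScoreParams
    params_b: ScoreParams
    n: int
    preserved: int
    top_a: frozenset[str]
    top_b: frozenset[str]


def _score_all(dataset: list[AnnotatedProtein], params: ScoreParams) -> RankTable:
    return rank_proteins(
        [san1_similarity(p, params) for p in dataset], "san1", params
    )


def sensitivity_scan(
    dataset: list[AnnotatedProtein],
    base: ScoreParams,
    variants: list[ScoreParams],
    n: int,
) -> list[OverlapResult]:
    """Top-N preservation when stretch bounds and/or window size change.

    Every variant triggers a full rescoring pass; only ``stretch_min``,
    ``stretch_max`` and ``window`` may differ from *base*.
    """
    for v in variants:
        if replace(
            v, stretch_min=base.stretch_min, stretch_max=base.stretch_max,
            window=base.window,
        ) != base:
            raise ValueError(
                "variants may differ from base only in stretch bounds and window"
            )
    base_top = top_n(_score_all(dataset, base), n)
    out = []
    for v in variants:
        v_top = top_n(_score_all(dataset, v), n)
        out.append(
            OverlapResult(
                params_a=base,
                params_b=v,
                n=n,
                preserved=len(base_top & v_top),
                top_a=frozenset(base_top),
                top_b=frozenset(v_top),
            )
        )
    return out


def initial_scores(
    dataset: list[AnnotatedProtein], params: ScoreParams
) -> list[InitialScore]:
    """Whole-protein product scores for every protein in the dataset."""
    return [initial_score(p, params) for p in dataset]
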