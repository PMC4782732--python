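"""Readers and writers for all external representations.

Formats: FASTA for sequences (via Biopython), tab-separated tables for
per-residue tracks, results, rank tables and labels, and XLSX/CSV for
annotated E3 tables in the long per-residue layout. File positions are
1-based inclusive (the convention of per-residue predictor outputs);
conversion to the package's 0-based half-open coordinates happens here
and nowhere else.

Floating-point values in result tables are serialized with 6
significant digits; round-tripping reproduces values to that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ranking import OverlapResult, RankTable
from .records import AnnotatedProtein, ProteinRecord, ResidueTrack
from .scoring import InitialScore, San1Result, ScoreProfile

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The header token before the first whitespace becomes the id (the
    remainder the display name); sequences are upper-cased and trailing
    ``*`` terminators stripped. Duplicate ids, invalid residue letters
    and empty files are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().rstrip("*")
        name = entry.description[len(entry.id):].strip()
        records.append(ProteinRecord(id=entry.id, sequence=seq, name=name))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, proteins: Iterable[ProteinRecord]) -> None:
    entries = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.name)
        for p in proteins
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Per-residue track tables

TRACK_COLUMNS = ("protein_id", "position", "disorder", "anchor")


def _assemble_annotated(
    frame: pd.DataFrame, proteins_by_id: dict[str, ProteinRecord], source: str
) -> list[AnnotatedProtein]:
    """Validate a long-format (protein_id, position, disorder, anchor)
    frame against known sequences and build AnnotatedProteins in the
    proteins' original order."""
    out: list[AnnotatedProtein] = []
    groups = {pid: g for pid, g in frame.groupby("protein_id", sort=False)}
    unknown = set(groups) - set(proteins_by_id)
    if unknown:
        raise ValueError(f"{source}: unknown protein_id {sorted(unknown)[0]!r}")
    for pid, record in proteins_by_id.items():
        g = groups.get(pid)
        if g is None:
            continue
        n = len(record)
        positions = g["position"].to_numpy(dtype=int)
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        expected = np.arange(1, n + 1)
        if positions.size != n or not np.array_equal(positions, expected):
            present = set(positions.tolist())
            missing = [p for p in range(1, n + 1) if p not in present]
            if missing:
                raise ValueError(
                    f"{source}: protein {pid!r} is missing position {missing[0]} "
                    f"(sequence length {n})"
                )
            raise ValueError(
                f"{source}: protein {pid!r} has positions outside 1..{n} "
                "or duplicates"
            )
        disorder = g["disorder"].to_numpy(dtype=float)[order]
        anchor = g["anchor"].to_numpy(dtype=float)[order]
        out.append(
            AnnotatedProtein(
                record=record,
                disorder=ResidueTrack(pid, "disorder_consensus", disorder),
                anchor=ResidueTrack(pid, "anchor", anchor),
            )
        )
    return out


def read_track_table(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[AnnotatedProtein]:
    """Read a TSV of per-residue disorder/ANCHOR scores.

    Columns: ``protein_id``, ``position`` (1-based), ``disorder``,
    ``anchor``; positions must be contiguous from 1 to the sequence
    length for every protein present. Proteins without any rows are
    omitted from the result.
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing_cols = [c for c in TRACK_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: missing column(s) {missing_cols}; found {list(frame.columns)}"
        )
    by_id = {p.id: p for p in proteins}
    return _assemble_annotated(frame, by_id, str(path))


def write_track_table(path: str | Path, annotated: Iterable[AnnotatedProtein]) -> None:
    """Write per-residue tracks as the TSV read by :func:`read_track_table`.

    Track values are written in full (repr) precision so the round trip
    is bitwise exact.
    """
    rows = []
    for ap in annotated:
        n = len(ap)
        rows.append(
            pd.DataFrame(
                {
                    "protein_id": np.repeat(ap.id, n),
                    "position": np.arange(1, n + 1),
                    "disorder": ap.disorder.values,
                    "anchor": ap.anchor.values,
                }
            )
        )
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=list(TRACK_COLUMNS))
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Annotated E3 tables (XLSX/CSV, configurable column mapping)

@dataclass(frozen=True)
class E3ColumnMap:
    """Column mapping for an annotated E3 table export.

    The table is expected in long per-residue layout: one row per
    (protein, position) with disorder and ANCHOR columns. The residue
    letter may come from a per-row column (``residue``) or, if that
    column is absent, from a companion FASTA supplied to
    :func:`read_e3_table`. Defaults follow this package's own exports.
    """

    protein_id: str = "protein_id"
    position: str = "position"
    disorder: str = "disorder"
    anchor: str = "anchor"
    residue: str | None = "residue"
    organism: str | None = "organism"
    name: str | None = None


def read_e3_table(
    path: str | Path,
    column_map: E3ColumnMap | None = None,
    proteins: Sequence[ProteinRecord] | None = None,
    sheet: str | int = 0,
) -> list[AnnotatedProtein]:
    """Read an annotated E3 ligase table (XLSX or CSV).

    Sequences are reconstructed from the per-row residue column when
    mapped, otherwise taken from *proteins*. An empty table yields an
    empty list with a logged warning.
    """
    cmap = column_map or E3ColumnMap()
    p = Path(path)
    if p.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        frame = pd.read_excel(p, sheet_name=sheet)
    else:
        frame = pd.read_csv(p, sep=None, engine="python")
    if frame.empty:
        logger.warning("%s: empty E3 table; returning no proteins", path)
        return []

    required = {
        "protein_id": cmap.protein_id,
        "position": cmap.position,
        "disorder": cmap.disorder,
        "anchor": cmap.anchor,
    }
    unmapped = [f"{k} -> {v!r}" for k, v in required.items() if v not in frame.columns]
    if unmapped:
        raise ValueError(
            f"{path}: unmapped required column(s): {', '.join(unmapped)}; "
            f"available columns: {list(frame.columns)}"
        )

    renamed = frame.rename(columns={v: k for k, v in required.items()})

    if cmap.residue is not None and cmap.residue in frame.columns:
        by_id: dict[str, ProteinRecord] = {}
        for pid, g in renamed.groupby("protein_id", sort=False):
            g = g.sort_values("position", kind="stable")
            seq = "".join(str(r).upper() for r in g[cmap.residue])
            organism = "unknown"
            if cmap.organism and cmap.organism in g.columns:
                organism = str(g[cmap.organism].iloc[0])
            name = ""
            if cmap.name and cmap.name in g.columns:
                name = str(g[cmap.name].iloc[0])
            by_id[str(pid)] = ProteinRecord(
                id=str(pid), sequence=seq, name=name, organism=organism
            )
    elif proteins is not None:
        by_id = {p_.id: p_ for p_ in proteins}
    else:
        raise ValueError(
            f"{path}: no residue column mapped and no sequence records supplied"
        )
    renamed["protein_id"] = renamed["protein_id"].astype(str)
    return _assemble_annotated(renamed, by_id, str(path))


# ---------------------------------------------------------------------------
# Result tables

RESULT_COLUMNS = (
    "protein_id",
    "score",
    "center",
    "window_start",
    "window_end",
    "disorder_frac",
    "anchor_stretch_frac",
    "kfree_frac",
)


def write_results(
    path: str | Path,
    rows: Sequence[San1Result] | Sequence[InitialScore] | RankTable,
) -> None:
    """Write scoring results, initial scores or a rank table as TSV.

    Column order is fixed per row type; an empty list produces a
    header-only file. Window coordinates are written 1-based inclusive;
    proteins without a defined window leave the window columns empty.
    """
    if isinstance(rows, RankTable):
        frame = pd.DataFrame(
            [(e.protein_id, e.score, e.rank) for e in rows.entries],
            columns=["protein_id", "score", "rank"],
        )
    elif len(rows) and isinstance(rows[0], InitialScore):
        frame = pd.DataFrame(
            [(r.protein_id, r.disorder_frac, r.anchor_stretch, r.product) for r in rows],
            columns=["protein_id", "disorder_frac", "anchor_stretch", "product"],
        )
    else:
        out = []
        for r in rows:
            if r.best is None:
                out.append((r.protein_id, r.score, None, None, None, None, None, None))
            else:
                b = r.best
                out.append(
                    (
                        r.protein_id,
                        r.score,
                        b.center + 1,
                        b.window.start + 1,
                        b.window.end,
                        b.disorder_frac,
                        b.anchor_stretch_frac,
                        b.kfree_frac,
                    )
                )
        frame = pd.DataFrame(out, columns=list(RESULT_COLUMNS))
        for col in ("center", "window_start", "window_end"):
            frame[col] = frame[col].astype("Int64")
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back any TSV written by :func:`write_results` or
    :func:`write_profiles` as a DataFrame."""
    return pd.read_csv(path, sep="\t")


def write_overlaps(path: str | Path, overlaps: Sequence[OverlapResult]) -> None:
    frame = pd.DataFrame(
        [
            (
                o.params_b.stretch_min,
                o.params_b.stretch_max,
                o.params_b.window,
                o.n,
                o.preserved,
                len(o.top_a),
                len(o.top_b),
            )
            for o in overlaps
        ],
        columns=[
            "stretch_min",
            "stretch_max",
            "window",
            "top_n",
            "preserved",
            "top_base_size",
            "top_variant_size",
        ],
    )
    frame.to_csv(path, sep="\t", index=False)


def write_profiles(path: str | Path, profiles: Sequence[ScoreProfile]) -> None:
    """Write per-position score profiles (1-based center positions)."""
    rows = [
        pd.DataFrame(
            {
                "protein_id": np.repeat(p.protein_id, p.centers.size),
                "position": p.centers + 1,
                "disorder_frac": p.disorder_frac,
                "anchor_stretch_frac": p.anchor_stretch_frac,
                "kfree_frac": p.kfree_frac,
                "product": p.product,
            }
        )
        for p in profiles
        if p.centers.size
    ]
    frame = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "protein_id",
                "position",
                "disorder_frac",
                "anchor_stretch_frac",
                "kfree_frac",
                "product",
            ]
        )
    )
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_labels(path: str | Path, labels: dict[str, bool]) -> None:
    pd.DataFrame(
        [(k, int(v)) for k, v in labels.items()], columns=["protein_id", "planted"]
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, bool]:
    frame = pd.read_csv(path, sep="\t")
    return {str(r.protein_id): bool(r.planted) for r in frame.itertuples()}
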