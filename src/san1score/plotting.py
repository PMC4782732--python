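"""Per-protein profile figures: disorder and ANCHOR curves, lysine
tick marks, and the best-scoring window bar."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .features import lysine_positions
from .io_tables import write_profiles
from .records import AnnotatedProtein, ScoreParams
from .scoring import San1Result, score_profile

__all__ = ["render_profile"]


def render_profile(
    protein: AnnotatedProtein,
    result: San1Result,
    out_path: str | Path,
    params: ScoreParams | None = None,
    data_path: str | Path | None = None,
) -> Path:
    """Render the track/score profile figure for one protein.

    Draws the raw disorder (blue) and ANCHOR (red) tracks, black tick
    marks at every lysine, the sliding-window product where defined,
    and an orange bar under the best-scoring window. If *data_path* is
    given, the plotted per-position score profile is also exported as
    TSV (the testable data behind the figure).
    """
    params = params or ScoreParams()
    n = len(protein)
    positions = range(1, n + 1)

    fig, ax = plt.subplots(figsize=(9, 2.6))
    ax.plot(positions, protein.disorder.values, color="#2060c0", lw=0.9,
            label="consensus disorder")
    ax.plot(positions, protein.anchor.values, color="#c03020", lw=0.9,
            label="ANCHOR")

    profile = score_profile(protein, params)
    if profile.centers.size:
        ax.plot(profile.centers + 1, profile.product, color="#404040", lw=1.2,
                label="window product")

    for k in lysine_positions(protein.record.sequence):
        ax.plot([k + 1], [-0.06], marker="|", color="black", ms=6)

    if result.best is not None:
        w = result.best.window
        ax.plot([w.start + 1, w.end], [-0.12, -0.12], color="orange", lw=3,
                solid_capstyle="butt", label="best window")

    ax.set_xlim(1, n)
    ax.set_ylim(-0.18, 1.05)
    ax.set_xlabel("residue")
    ax.set_ylabel("score")
    ax.set_title(f"{protein.id}  similarity score {result.score:.3f}")
    ax.legend(loc="upper right", fontsize=7, ncol=2)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, metadata={"Date": None} if out_path.suffix == ".svg" else None)
    plt.close(fig)

    if data_path is not None:
        write_profiles(data_path, [profile])
    return out_path
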