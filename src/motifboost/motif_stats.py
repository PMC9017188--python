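"""Residue-frequency and enrichment analysis of phosphosite windows.

Logo-style matrices: per-position residue frequencies of a window set
(padding excluded), log2 enrichment of a foreground set over a background
set, pS/pT/pY content, and kinase-class composition via motif
classification.  The module's contract ends at matrices; image export is a
small matplotlib convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import AMINO_ACIDS, PAD, KinaseMotifModel, assign_kinase_class

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position residue frequencies (and raw counts) of a window set."""

    frequencies: pd.DataFrame  # index: positions -w..+w, columns: residues
    counts: pd.DataFrame
    n_windows: int

    @property
    def half_width(self) -> int:
        return int(self.frequencies.index.max())


def frequency_matrix(windows: Iterable[str]) -> FrequencyMatrix:
    """Count residues per position over equal-width windows; padding excluded.

    Frequencies at each position are normalized over the observed
    (non-padding) residues, so each row with at least one observation sums
    to 1.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no windows given")
    width = len(windows[0])
    if any(len(win) != width for win in windows):
        raise ValueError("windows must share one width")
    w = width // 2
    positions = list(range(-w, w + 1))
    counts = np.zeros((width, 20), dtype=int)
    for win in windows:
        for i, aa in enumerate(win):
            if aa != PAD:
                counts[i, _AA_INDEX[aa]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.divide(counts, totals, out=np.zeros_like(counts, dtype=float), where=totals > 0)
    cols = list(AMINO_ACIDS)
    return FrequencyMatrix(
        frequencies=pd.DataFrame(freqs, index=positions, columns=cols),
        counts=pd.DataFrame(counts, index=positions, columns=cols),
        n_windows=len(windows),
    )


def enrichment_matrix(
    foreground: FrequencyMatrix, background: FrequencyMatrix, pseudocount: float = 0.01
) -> pd.DataFrame:
    """log2((fg + pc) / (bg + pc)) per position x residue cell."""
    if foreground.half_width != background.half_width:
        raise ValueError("foreground/background widths differ")
    fg = foreground.frequencies
    bg = background.frequencies
    return np.log2((fg + pseudocount) / (bg + pseudocount))


def residue_content(residues: Iterable[str]) -> dict[str, float]:
    """Fractions of S, T and Y among phosphosite residues (sum to 1)."""
    vals = list(residues)
    bad = set(vals) - set("STY")
    if bad:
        raise ValueError(f"non-acceptor residues: {sorted(bad)}")
    n = len(vals)
    if n == 0:
        return {"S": 0.0, "T": 0.0, "Y": 0.0}
    return {aa: vals.count(aa) / n for aa in "STY"}


def class_composition(
    windows: Iterable[str],
    models: Sequence[KinaseMotifModel],
    score_floor: float = 0.0,
) -> dict[str, int]:
    """Tally of best-matching kinase per window; 'unassigned' when none."""
    tally: dict[str, int] = {m.name: 0 for m in models}
    tally["unassigned"] = 0
    for win in windows:
        hit = assign_kinase_class(win, models, score_floor=score_floor)
        tally[hit[0] if hit else "unassigned"] += 1
    return tally


def write_matrix(matrix: pd.DataFrame | FrequencyMatrix, path) -> None:
    """Write a position x residue matrix as a tab-separated table."""
    frame = matrix.frequencies if isinstance(matrix, FrequencyMatrix) else matrix
    frame.to_csv(path, sep="\t", index_label="position")


def plot_enrichment(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Heatmap rendering of an enrichment matrix (convenience wrapper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    vmax = float(np.nanmax(np.abs(matrix.to_numpy()))) or 1.0
    im = ax.imshow(
        matrix.to_numpy().T, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax
    )
    ax.set_xticks(range(len(matrix.index)), matrix.index)
    ax.set_yticks(range(len(matrix.columns)), matrix.columns, fontsize=6)
    ax.set_xlabel("position relative to phosphosite")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 enrichment")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
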