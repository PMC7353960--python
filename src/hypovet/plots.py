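"""Figure rendering for vetting reports.

All figures are written to files (never shown interactively). The whisker
plot screens for noisy hypotheses: one whisker per parametrization spanning
the min-max range of its sampling distribution with the median marked. The
overlap heatmaps screen for degeneracy: one panel per ordered hypothesis-
family pair, cell colour mapping the unidirectional overlap proportion on a
shared [0, 1] scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .settlement import HypothesisSpec
from .vetting import DistributionSummary, OverlapMatrix

__all__ = ["render_whisker_plot", "render_overlap_heatmaps", "render_full_heatmap"]

FAMILY_COLORS = {
    "null": "#666666",
    "habitat_preference": "#1b7837",
    "conspecific_attraction": "#762a83",
    "custom": "#2166ac",
}

FAMILY_SHORT = {
    "null": "RAND",
    "habitat_preference": "HP",
    "conspecific_attraction": "CA",
    "custom": "CUSTOM",
}


def render_whisker_plot(
    summaries: Sequence[DistributionSummary],
    path: Union[str, Path],
    families: Dict[str, str] | None = None,
) -> Path:
    """Min-max whisker per parametrization with the median marked.

    ``families`` maps spec name -> family for colour grouping; unknown
    names fall back to a neutral colour.
    """
    if len(summaries) == 0:
        raise ValueError("no summaries to plot")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    families = families or {}

    fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(summaries)), 4.5))
    for x, s in enumerate(summaries):
        color = FAMILY_COLORS.get(families.get(s.spec_name, ""), "#2166ac")
        ax.vlines(x, s.minimum, s.maximum, color=color, lw=2)
        ax.plot([x], [s.median], "o", color=color, ms=5)
    ax.set_xticks(range(len(summaries)))
    ax.set_xticklabels([s.spec_name for s in summaries], rotation=45, ha="right")
    ax.set_ylabel("response statistic")
    ax.set_title("Sampling-distribution ranges per parametrization")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _family_blocks(
    matrix: OverlapMatrix, specs: Sequence[HypothesisSpec]
) -> Dict[str, List[int]]:
    fam_of = {s.name: s.family for s in specs}
    blocks: Dict[str, List[int]] = {}
    for idx, name in enumerate(matrix.spec_names):
        blocks.setdefault(fam_of.get(name, "custom"), []).append(idx)
    return blocks


def render_overlap_heatmaps(
    matrix: OverlapMatrix,
    specs: Sequence[HypothesisSpec],
    out_dir: Union[str, Path],
    fmt: str = "png",
) -> List[Path]:
    """One heatmap panel per ordered family pair, e.g. p(HP|CA).

    Panel p(F|G) shows, for every parametrization of family F (rows)
    against every parametrization of family G (columns), the proportion of
    F's simulations lying within G's bracketed range. A shared [0, 1]
    colour scale is used across panels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blocks = _family_blocks(matrix, specs)
    paths: List[Path] = []
    for fam_i, rows in blocks.items():
        for fam_j, cols in blocks.items():
            if fam_i == fam_j:
                continue
            sub = matrix.entries[np.ix_(rows, cols)]
            fig, ax = plt.subplots(
                figsize=(1.2 + 0.8 * len(cols), 1.2 + 0.8 * len(rows))
            )
            im = ax.imshow(sub, vmin=0.0, vmax=1.0, cmap="viridis", aspect="auto")
            ax.set_xticks(range(len(cols)))
            ax.set_xticklabels(
                [matrix.spec_names[j] for j in cols], rotation=45, ha="right"
            )
            ax.set_yticks(range(len(rows)))
            ax.set_yticklabels([matrix.spec_names[i] for i in rows])
            label = f"p({FAMILY_SHORT[fam_i]}|{FAMILY_SHORT[fam_j]})"
            ax.set_title(label)
            fig.colorbar(im, ax=ax, label="overlap proportion")
            fig.tight_layout()
            p = out_dir / f"overlap_{FAMILY_SHORT[fam_i]}_given_{FAMILY_SHORT[fam_j]}.{fmt}"
            fig.savefig(p, dpi=150)
            plt.close(fig)
            paths.append(p)
    return paths


def render_full_heatmap(
    matrix: OverlapMatrix, path: Union[str, Path]
) -> Path:
    """Supplementary all-parametrization heatmap, diagonal included."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    k = len(matrix.spec_names)
    fig, ax = plt.subplots(figsize=(1.5 + 0.6 * k, 1.5 + 0.6 * k))
    im = ax.imshow(matrix.entries, vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(k))
    ax.set_xticklabels(matrix.spec_names, rotation=45, ha="right")
    ax.set_yticks(range(k))
    ax.set_yticklabels(matrix.spec_names)
    ax.set_xlabel("reference distribution j")
    ax.set_ylabel("source distribution i")
    ax.set_title("Unidirectional overlap p(i|j)")
    fig.colorbar(im, ax=ax, label="overlap proportion")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
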