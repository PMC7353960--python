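"""Spatial clustering metrics for settled point patterns.

When two hypotheses are degenerate on the primary response statistic, the
spatial arrangement of settlers may still tell them apart: conspecific
attraction piles agents around the first settler, while habitat preference
spreads them diffusely across the preferred habitat. Two standard
first-order metrics are provided.

The Clark–Evans aggregation index is

    R = mean observed nearest-neighbour distance / (0.5 / sqrt(lambda)),

where ``lambda = n_points / window_area`` is the point density and the
denominator is the expected nearest-neighbour distance under complete
spatial randomness. R < 1 indicates clustering, R near 1 randomness and
R > 1 overdispersion. No edge correction is applied: on small windows the
uncorrected index is biased upward, but the toolkit only uses it
*comparatively* between hypotheses simulated on the same window, where the
bias is shared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .landscape import Landscape
from .settlement import SettlementResult

__all__ = [
    "PointPattern",
    "from_settlement",
    "mean_nearest_neighbour_distance",
    "clark_evans_index",
]


@dataclass(frozen=True)
class PointPattern:
    """Planar points within a rectangular observation window."""

    points: np.ndarray          # (n, 2) continuous (x, y)
    window_area: float

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise ValueError("points must be an (n >= 1, 2) array of coordinates")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if self.window_area <= 0:
            raise ValueError("window_area must be positive")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def save_csv(self, path: Union[str, Path]) -> None:
        """CSV of x, y coordinates plus a JSON sidecar with the window area."""
        path = Path(path)
        pd.DataFrame(self.points, columns=["x", "y"]).to_csv(path, index=False)
        path.with_suffix(".json").write_text(
            json.dumps({"window_area": self.window_area}, indent=2) + "\n"
        )


def from_settlement(result: SettlementResult, landscape: Landscape) -> PointPattern:
    """Point pattern of settled cell centres; the window is the landscape."""
    if result.n_agents == 0:
        raise ValueError("empty settlement result")
    if result.landscape_ref != landscape.ref:
        raise ValueError("result was not produced on this landscape")
    pts = np.array(
        [(c + 0.5, r + 0.5) for r, c in result.settled], dtype=float
    )
    return PointPattern(points=pts, window_area=float(landscape.n_cells))


def mean_nearest_neighbour_distance(pattern: PointPattern) -> float:
    """Mean over points of the Euclidean distance to the nearest other point."""
    if pattern.n_points < 2:
        raise ValueError("need at least 2 points for nearest-neighbour distances")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=2)
    return float(np.mean(d[:, 1]))


def clark_evans_index(pattern: PointPattern) -> float:
    """Clark–Evans aggregation index R (no edge correction)."""
    if pattern.n_points < 2:
        raise ValueError("need at least 2 points for the Clark-Evans index")
    density = pattern.n_points / pattern.window_area
    expected_nn = 0.5 / np.sqrt(density)
    return mean_nearest_neighbour_distance(pattern) / expected_nn
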