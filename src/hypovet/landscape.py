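"""Two-habitat gridded landscapes.

A :class:`Landscape` is a rectangular grid of unit cells, each labelled
habitat ``A`` or habitat ``B``. Settlement models choose among cells, so the
landscape is the sample space of every simulation in this package.

Habitat assignment uses an *exact count*: exactly ``round(prop_a * n_cells)``
cells are labelled A (round half-up). This makes the expected proportion of
settlers on A under the random-settlement null exactly ``prop_a`` (the
per-iteration count is hypergeometric), which keeps analytic checks sharp.

Geometry convention: cells are indexed ``(row, col)`` from 0; the centre of
cell ``(row, col)`` sits at continuous coordinates ``(col + 0.5, row + 0.5)``
with x increasing along columns and y along rows. Cell edges have unit
length.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "Landscape",
    "LandscapeConfig",
    "generate_landscape",
    "LAYOUTS",
]

LAYOUTS = ("random", "blocked")

SeedLike = Union[int, np.random.SeedSequence]


@dataclass(frozen=True)
class Landscape:
    """A rectangular two-habitat grid.

    Attributes
    ----------
    habitat : numpy.ndarray
        Array of shape ``(n_rows, n_cols)`` with dtype ``<U1``, entries
        ``'A'`` or ``'B'``.
    cell_size : float
        Edge length of a cell; fixed at 1.0.
    """

    habitat: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        hab = np.asarray(self.habitat, dtype="<U1")
        if hab.ndim != 2 or hab.size < 1:
            raise ValueError("habitat must be a 2-D array with at least one cell")
        bad = ~np.isin(hab, ("A", "B"))
        if bad.any():
            raise ValueError(
                f"habitat labels must be 'A' or 'B'; found {np.unique(hab[bad])!r}"
            )
        if self.cell_size != 1.0:
            raise ValueError("cell_size is fixed at 1.0")
        hab.setflags(write=False)
        object.__setattr__(self, "habitat", hab)

    @property
    def n_rows(self) -> int:
        return self.habitat.shape[0]

    @property
    def n_cols(self) -> int:
        return self.habitat.shape[1]

    @property
    def n_cells(self) -> int:
        return self.habitat.size

    @property
    def is_a(self) -> np.ndarray:
        """Boolean mask of A cells, shape ``(n_rows, n_cols)``."""
        return self.habitat == "A"

    @property
    def n_a(self) -> int:
        return int(self.is_a.sum())

    @property
    def ref(self) -> str:
        """Short content hash identifying this landscape (dims + labels)."""
        h = hashlib.sha1()
        h.update(f"{self.n_rows}x{self.n_cols}:".encode())
        h.update(self.habitat.tobytes())
        return h.hexdigest()[:12]

    def cell_centers(self) -> np.ndarray:
        """Continuous (x, y) centres of all cells in row-major order, shape (n_cells, 2)."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        return np.column_stack((cols + 0.5, rows + 0.5)).astype(float)

    # -- plain-text interchange ------------------------------------------------

    def to_text(self) -> str:
        """One line per row, characters 'A'/'B'."""
        return "\n".join("".join(row) for row in self.habitat) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Landscape":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty landscape text")
        widths = {len(ln) for ln in lines}
        if len(widths) != 1:
            raise ValueError("all landscape rows must have equal length")
        hab = np.array([list(ln) for ln in lines], dtype="<U1")
        return cls(hab)

    def save_text(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load_text(cls, path: Union[str, Path]) -> "Landscape":
        return cls.from_text(Path(path).read_text())

    # -- CSV interchange -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns row, col, habitat."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        return pd.DataFrame(
            {"row": rows, "col": cols, "habitat": self.habitat.ravel()}
        )

    def save_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Landscape":
        n_rows = int(df["row"].max()) + 1
        n_cols = int(df["col"].max()) + 1
        hab = np.full((n_rows, n_cols), "", dtype="<U1")
        hab[df["row"].to_numpy(), df["col"].to_numpy()] = df["habitat"].to_numpy()
        if (hab == "").any():
            raise ValueError("CSV does not cover every cell of the grid")
        return cls(hab)

    @classmethod
    def load_csv(cls, path: Union[str, Path]) -> "Landscape":
        return cls.from_frame(pd.read_csv(Path(path)))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_landscape(
    n_rows: int,
    n_cols: int,
    prop_a: float,
    layout: str = "random",
    seed: SeedLike = 0,
) -> Landscape:
    """Generate a two-habitat landscape with an exact A-cell count.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; both must be positive.
    prop_a : float
        Target proportion of A cells, in [0, 1]. Exactly
        ``round(prop_a * n_rows * n_cols)`` cells (half-up) are labelled A.
    layout : {"random", "blocked"}
        ``random`` places the A cells at uniformly random distinct cells;
        ``blocked`` fills cells with A in row-major order from (0, 0),
        producing one contiguous band — a minimal stand-in for patchy
        habitat structure.
    seed : int or numpy.random.SeedSequence
        Seed for the random layout; ignored by the blocked layout except
        that identical inputs always give identical landscapes.
    """
    if int(n_rows) != n_rows or int(n_cols) != n_cols or n_rows < 1 or n_cols < 1:
        raise ValueError(
            f"grid dimensions must be positive integers, got {n_rows}x{n_cols}"
        )
    if not 0.0 <= prop_a <= 1.0:
        raise ValueError(f"prop_a must lie in [0, 1], got {prop_a}")
    if layout not in LAYOUTS:
        raise ValueError(f"layout must be one of {LAYOUTS}, got {layout!r}")

    n_rows, n_cols = int(n_rows), int(n_cols)
    n_cells = n_rows * n_cols
    n_a = _round_half_up(prop_a * n_cells)

    flat = np.full(n_cells, "B", dtype="<U1")
    if layout == "blocked":
        flat[:n_a] = "A"
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n_cells, size=n_a, replace=False)
        flat[idx] = "A"
    return Landscape(flat.reshape(n_rows, n_cols))


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters that define a landscape up to its random seed."""

    n_rows: int = 50
    n_cols: int = 50
    prop_a: float = 0.5
    layout: str = "blocked"

    def generate(self, seed: SeedLike) -> Landscape:
        return generate_landscape(
            self.n_rows, self.n_cols, self.prop_a, self.layout, seed
        )
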