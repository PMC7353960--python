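"""Individual-based settlement models.

Agents settle a landscape one at a time. Each draw selects one unoccupied
cell with probability proportional to a per-cell weight computed from the
current occupancy state; the chosen cell then joins the occupied set (single
occupancy per cell). Three candidate hypotheses are built in:

``null``
    Every unoccupied cell has weight 1 — random settlement with no
    influence of habitat or neighbours.
``habitat_preference``
    Unoccupied A cells get odds weight ``omega`` (>= 1), B cells weight 1.
    ``omega = 1`` is exactly the null model.
``conspecific_attraction``
    The first settler is random (uniform weights). Thereafter an unoccupied
    cell at Euclidean centre-to-centre distance ``d`` from its nearest
    occupied cell gets weight ``exp(-s * d)``. ``s = 0`` is exactly the
    null model; larger ``s`` concentrates settlement around earlier
    settlers.

User-defined hypotheses plug in through the :data:`WeightRule` contract: a
callable ``(landscape, occupied, params) -> weights`` returning one finite
non-negative weight per unoccupied cell in row-major cell order.

Selection is by inverse-CDF lookup on the cumulative weight vector in
row-major cell order with a seeded generator, so identical inputs and seed
reproduce identical settlement sequences bit for bit — in particular the
parameter-forced null limits (``omega=1``, ``s=0``) reproduce the null
model's sequences exactly under shared seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Tuple, Union

import json

import numpy as np
import pandas as pd

from .landscape import Landscape, SeedLike

__all__ = [
    "FAMILIES",
    "HypothesisSpec",
    "SettlementResult",
    "WeightRule",
    "null_spec",
    "habitat_preference_spec",
    "conspecific_attraction_spec",
    "default_hypothesis_grid",
    "weights_null",
    "weights_habitat_preference",
    "weights_conspecific_attraction",
    "simulate_settlement",
    "proportion_habitat_a",
]

FAMILIES = ("null", "habitat_preference", "conspecific_attraction", "custom")

Cell = Tuple[int, int]

#: Plug-in contract for custom hypotheses: ``(landscape, occupied, params)``
#: -> array of finite, non-negative weights, one per *unoccupied* cell in
#: row-major order, with at least one positive entry.
WeightRule = Callable[[Landscape, frozenset, Mapping[str, float]], np.ndarray]


@dataclass(frozen=True)
class HypothesisSpec:
    """One named parametrization of a candidate settlement hypothesis."""

    name: str
    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    weight_rule: Optional[WeightRule] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("hypothesis name must be non-empty")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "habitat_preference":
            omega = self.params.get("omega")
            if omega is None or omega < 1:
                raise ValueError(
                    f"habitat_preference requires omega >= 1, got {omega!r}"
                )
        elif self.family == "conspecific_attraction":
            s = self.params.get("s")
            if s is None or s < 0:
                raise ValueError(
                    f"conspecific_attraction requires s >= 0, got {s!r}"
                )
        elif self.family == "custom" and self.weight_rule is None:
            raise ValueError("custom hypotheses must supply a weight_rule")
        object.__setattr__(self, "params", dict(self.params))


def null_spec(name: str = "null") -> HypothesisSpec:
    return HypothesisSpec(name=name, family="null")

def habitat_preference_spec(omega: float, name: Optional[str] = None) -> HypothesisSpec:
    return HypothesisSpec(
        name=name or f"HP(omega={omega:g})",
        family="habitat_preference",
        params={"omega": float(omega)},
    )

def conspecific_attraction_spec(s: float, name: Optional[str] = None) -> HypothesisSpec:
    return HypothesisSpec(
        name=name or f"CA(s={s:g})",
        family="conspecific_attraction",
        params={"s": float(s)},
    )


def default_hypothesis_grid(
    omega_values: Sequence[float] = (1.5, 2, 4, 8, 16),
    s_values: Sequence[float] = (0.25, 0.5, 1, 2, 4),
    include_null: bool = True,
) -> list:
    """The default candidate set: one null model plus a habitat-preference
    parametrization per omega and a conspecific-attraction parametrization
    per s (11 parametrizations with the default grids)."""
    specs = []
    if include_null:
        specs.append(null_spec())
    specs.extend(habitat_preference_spec(w) for w in omega_values)
    specs.extend(conspecific_attraction_spec(s) for s in s_values)
    return specs


# ---------------------------------------------------------------------------
# Weight rules (reference implementations over the unoccupied cells)
# ---------------------------------------------------------------------------

def _free_mask(landscape: Landscape, occupied: Iterable[Cell]) -> np.ndarray:
    occ = list(occupied)
    mask = np.ones(landscape.n_cells, dtype=bool)
    if occ:
        rows, cols = zip(*occ)
        flat = np.asarray(rows) * landscape.n_cols + np.asarray(cols)
        if flat.min() < 0 or flat.max() >= landscape.n_cells:
            raise ValueError("occupied cell outside the landscape")
        mask[flat] = False
    if not mask.any():
        raise ValueError("landscape is full: no unoccupied cell remains")
    return mask


def weights_null(landscape: Landscape, occupied: Iterable[Cell]) -> np.ndarray:
    """Weight 1 for every unoccupied cell (row-major order)."""
    mask = _free_mask(landscape, occupied)
    return np.ones(int(mask.sum()))


def weights_habitat_preference(
    landscape: Landscape, occupied: Iterable[Cell], omega: float
) -> np.ndarray:
    """Weight ``omega`` for unoccupied A cells, 1 for unoccupied B cells."""
    if omega < 1:
        raise ValueError(f"omega must be >= 1 (preference *for* A), got {omega}")
    mask = _free_mask(landscape, occupied)
    return np.where(landscape.is_a.ravel()[mask], float(omega), 1.0)


def weights_conspecific_attraction(
    landscape: Landscape, occupied: Iterable[Cell], s: float
) -> np.ndarray:
    """``exp(-s * d)`` with d the distance to the nearest occupied cell.

    With no occupied cells the weights are uniform: the initial individual
    settles randomly.
    """
    if s < 0:
        raise ValueError(f"attraction strength s must be >= 0, got {s}")
    occ = list(occupied)
    mask = _free_mask(landscape, occ)
    n_free = int(mask.sum())
    if not occ:
        return np.ones(n_free)
    centers = landscape.cell_centers()
    occ_flat = [r * landscape.n_cols + c for r, c in occ]
    occ_xy = centers[occ_flat]
    free_xy = centers[mask]
    d = np.sqrt(
        ((free_xy[:, None, :] - occ_xy[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    return np.exp(-float(s) * d)


# ---------------------------------------------------------------------------
# Sequential simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SettlementResult:
    """One iteration's settled cells, in settlement order."""

    settled: Tuple[Cell, ...]
    habitats: Tuple[str, ...]
    landscape_ref: str
    seed: Optional[int]

    def __post_init__(self) -> None:
        if len(self.settled) != len(self.habitats):
            raise ValueError("settled and habitats must be parallel sequences")
        if len(set(self.settled)) != len(self.settled):
            raise ValueError("settled cells must be distinct (single occupancy)")

    @property
    def n_agents(self) -> int:
        return len(self.settled)

    def to_frame(self) -> pd.DataFrame:
        rows = [r for r, _ in self.settled]
        cols = [c for _, c in self.settled]
        return pd.DataFrame(
            {
                "order": np.arange(self.n_agents),
                "row": rows,
                "col": cols,
                "habitat": list(self.habitats),
            }
        )

    def save_csv(self, path: Union[str, Path]) -> None:
        """CSV of the settlement sequence plus a JSON sidecar with the
        landscape reference and seed."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"landscape_ref": self.landscape_ref, "seed": self.seed},
                indent=2,
            )
            + "\n"
        )


def _selection_index(cumw: np.ndarray, w: np.ndarray, u: float) -> int:
    """Inverse-CDF pick: first index whose cumulative weight exceeds u*total.

    ``side='right'`` can never land on a zero-weight (occupied) cell: such a
    cell's cumulative value equals its predecessor's, so it is never the
    first strict exceedance. Float round-off at u -> 1 is clamped back to
    the last positive-weight cell.
    """
    idx = int(np.searchsorted(cumw, u * cumw[-1], side="right"))
    if idx >= len(cumw):
        idx = int(np.flatnonzero(w > 0)[-1])
    return idx


def simulate_settlement(
    landscape: Landscape,
    spec: HypothesisSpec,
    n_agents: int,
    seed: SeedLike,
) -> SettlementResult:
    """Run one settlement iteration.

    Agents settle sequentially; each draw selects an unoccupied cell with
    probability proportional to the spec's weight rule evaluated against the
    current occupied set. Identical inputs and seed reproduce the identical
    result.
    """
    n_cells = landscape.n_cells
    if not 1 <= n_agents <= n_cells:
        raise ValueError(
            f"n_agents must be in [1, {n_cells}] for this landscape, got {n_agents}"
        )
    rng = np.random.default_rng(seed)
    n_cols = landscape.n_cols
    is_a_flat = landscape.is_a.ravel()
    free = np.ones(n_cells, dtype=bool)

    family = spec.family
    if family == "habitat_preference":
        base = np.where(is_a_flat, float(spec.params["omega"]), 1.0)
    elif family == "conspecific_attraction":
        s = float(spec.params["s"])
        centers = landscape.cell_centers()
        # distance from every cell to its nearest settled cell; updated
        # incrementally as agents settle
        nearest = np.full(n_cells, np.inf)

    settled: list = []
    w = np.empty(n_cells)
    for step in range(n_agents):
        if family == "null":
            np.copyto(w, 1.0)
        elif family == "habitat_preference":
            np.copyto(w, base)
        elif family == "conspecific_attraction":
            if not settled:
                np.copyto(w, 1.0)  # initial individual settles randomly
            else:
                np.exp(-s * nearest, out=w)
        else:  # custom plug-in rule
            occupied = frozenset(settled)
            free_w = np.asarray(
                spec.weight_rule(landscape, occupied, spec.params), dtype=float
            )
            if free_w.shape != (int(free.sum()),):
                raise ValueError(
                    f"weight rule of spec {spec.name!r} returned "
                    f"{free_w.shape} weights for {int(free.sum())} unoccupied cells"
                )
            w[:] = 0.0
            w[free] = free_w
        w[~free] = 0.0
        if not np.all(np.isfinite(w)) or (w < 0).any():
            raise ValueError(
                f"weight rule of spec {spec.name!r} produced non-finite or "
                "negative weights"
            )
        cumw = np.cumsum(w)
        if cumw[-1] <= 0:
            raise ValueError(
                f"weight rule of spec {spec.name!r} produced all-zero weights "
                f"at step {step}"
            )
        idx = _selection_index(cumw, w, rng.random())
        free[idx] = False
        cell = (idx // n_cols, idx % n_cols)
        settled.append(cell)
        if family == "conspecific_attraction":
            d_new = np.hypot(
                centers[:, 0] - centers[idx, 0], centers[:, 1] - centers[idx, 1]
            )
            np.minimum(nearest, d_new, out=nearest)

    habitats = tuple("A" if is_a_flat[r * n_cols + c] else "B" for r, c in settled)
    seed_out = int(seed) if isinstance(seed, (int, np.integer)) else None
    return SettlementResult(
        settled=tuple(settled),
        habitats=habitats,
        landscape_ref=landscape.ref,
        seed=seed_out,
    )


def proportion_habitat_a(
    result: SettlementResult, landscape: Optional[Landscape] = None
) -> float:
    """Proportion of settled agents on Habitat A cells — the default
    response statistic."""
    if result.n_agents == 0:
        raise ValueError("empty settlement result")
    if landscape is not None:
        if result.landscape_ref != landscape.ref:
            raise ValueError("result was not produced on this landscape")
    return sum(h == "A" for h in result.habitats) / result.n_agents
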