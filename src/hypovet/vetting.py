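"""Sampling distributions and identifiability diagnostics.

Hypothesis vetting asks, before any data are collected, whether the
candidate hypotheses are distinguishable at all. The unit of analysis is
the *simulated sampling distribution*: the vector of response-statistic
values obtained from many independent iterations of one hypothesis
parametrization. Two failure modes are quantified:

noisiness
    one hypothesis produces a wide or multimodal sampling distribution, so
    its parameters cannot be estimated precisely. Summarised here by the
    range width, variance and coefficient of variation (the spread relative
    to the magnitude of the estimate).

degeneracy
    two hypotheses produce overlapping sampling distributions, so no
    observation can uniquely implicate either. Summarised by the
    *unidirectional overlap* p(i|j): the proportion of distribution i's
    values lying inside a bracketed range of distribution j. It reads as
    the conditional probability that hypothesis i generates response data
    capable of being produced by hypothesis j, and is generally asymmetric
    because the distributions have unequal spreads.

No overlap level is automatically "too much"; the toolkit reports the
quantities and leaves the verdict to the researcher.

Seed policy: iteration ``i`` of a distribution built from ``base_seed``
uses the derived seed ``base_seed + i``; a :class:`numpy.random.SeedSequence`
on that integer is spawned into two independent streams, one for the
landscape draw and one for the settlement draws, so landscape layout and
settlement choices are never read from the same stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .landscape import Landscape, LandscapeConfig
from .settlement import (
    HypothesisSpec,
    SettlementResult,
    proportion_habitat_a,
    simulate_settlement,
)

__all__ = [
    "SamplingDistribution",
    "DistributionSummary",
    "OverlapMatrix",
    "iteration_seed",
    "iteration_streams",
    "build_sampling_distribution",
    "summarize_distribution",
    "unidirectional_overlap",
    "overlap_matrix",
    "distributions_to_frame",
    "summaries_to_frame",
]

OVERLAP_METHODS = ("range", "central_quantile")


@dataclass(frozen=True)
class SamplingDistribution:
    """Response-statistic values across iterations of one parametrization."""

    spec_name: str
    values: np.ndarray
    base_seed: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or len(vals) < 2:
            raise ValueError("a sampling distribution needs at least 2 values")
        if not np.all(np.isfinite(vals)):
            raise ValueError("sampling distribution values must be finite")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_iter(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DistributionSummary:
    """Location, spread and quantile summary of one sampling distribution."""

    spec_name: str
    minimum: float
    maximum: float
    range_width: float
    mean: float
    variance: float
    std: float
    cv: float          # NaN when the mean is 0
    cv_defined: bool
    q025: float
    q25: float
    median: float
    q75: float
    q975: float


def iteration_seed(base_seed: int, iteration: int) -> int:
    """Derived seed of one iteration."""
    return int(base_seed) + int(iteration)


def iteration_streams(
    base_seed: int, iteration: int
) -> Tuple[np.random.SeedSequence, np.random.SeedSequence]:
    """Independent (landscape, settlement) seed streams for one iteration."""
    ss = np.random.SeedSequence(iteration_seed(base_seed, iteration))
    land_ss, settle_ss = ss.spawn(2)
    return land_ss, settle_ss


def build_sampling_distribution(
    landscape_config: LandscapeConfig,
    spec: HypothesisSpec,
    n_agents: int,
    n_iter: int,
    base_seed: int,
    regenerate_landscape: bool = True,
    statistic: Callable[[SettlementResult, Landscape], float] = proportion_habitat_a,
    extra_statistics: Optional[
        Mapping[str, Callable[[SettlementResult, Landscape], float]]
    ] = None,
) -> "SamplingDistribution | tuple":
    """Run ``n_iter`` independent settlement iterations and collect the
    response statistic.

    By default a fresh landscape is generated each iteration (so landscape
    stochasticity is part of each hypothesis' sampling distribution); with
    ``regenerate_landscape=False`` one fixed landscape generated from
    ``base_seed`` is reused.

    ``extra_statistics`` maps names to additional per-iteration statistics
    (e.g. spatial clustering indices); when given, the return value is
    ``(distribution, {name: np.ndarray})``.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    fixed_landscape = None
    if not regenerate_landscape:
        fixed_landscape = landscape_config.generate(int(base_seed))

    values = np.empty(n_iter)
    extras: Dict[str, np.ndarray] = {
        name: np.empty(n_iter) for name in (extra_statistics or {})
    }
    for i in range(n_iter):
        land_ss, settle_ss = iteration_streams(base_seed, i)
        try:
            if fixed_landscape is None:
                landscape = landscape_config.generate(land_ss)
            else:
                landscape = fixed_landscape
            result = simulate_settlement(landscape, spec, n_agents, settle_ss)
            values[i] = statistic(result, landscape)
            for name, fn in (extra_statistics or {}).items():
                extras[name][i] = fn(result, landscape)
        except Exception as exc:
            raise RuntimeError(
                f"iteration {i} of spec {spec.name!r} failed: {exc}"
            ) from exc

    dist = SamplingDistribution(
        spec_name=spec.name, values=values, base_seed=int(base_seed)
    )
    if extra_statistics:
        return dist, extras
    return dist


def summarize_distribution(dist: SamplingDistribution) -> DistributionSummary:
    """Summary statistics of one sampling distribution.

    Variance is the sample variance (ddof=1); quantiles use linear
    interpolation between order statistics. The coefficient of variation is
    flagged undefined (NaN) when the mean is zero.
    """
    v = dist.values
    if len(v) < 2:
        raise ValueError("need at least 2 values to summarise")
    mean = float(np.mean(v))
    var = float(np.var(v, ddof=1))
    std = float(np.sqrt(var))
    cv_defined = mean != 0.0
    cv = std / mean if cv_defined else float("nan")
    q = np.quantile(v, [0.025, 0.25, 0.5, 0.75, 0.975], method="linear")
    return DistributionSummary(
        spec_name=dist.spec_name,
        minimum=float(np.min(v)),
        maximum=float(np.max(v)),
        range_width=float(np.max(v) - np.min(v)),
        mean=mean,
        variance=var,
        std=std,
        cv=cv,
        cv_defined=cv_defined,
        q025=float(q[0]),
        q25=float(q[1]),
        median=float(q[2]),
        q75=float(q[3]),
        q975=float(q[4]),
    )


def _bracket(
    reference: SamplingDistribution, method: str, alpha: float
) -> Tuple[float, float]:
    if method == "range":
        return float(np.min(reference.values)), float(np.max(reference.values))
    if method == "central_quantile":
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
        lo, hi = np.quantile(
            reference.values, [alpha / 2, 1 - alpha / 2], method="linear"
        )
        return float(lo), float(hi)
    raise ValueError(f"unknown overlap method {method!r}; use one of {OVERLAP_METHODS}")


def unidirectional_overlap(
    source: SamplingDistribution,
    reference: SamplingDistribution,
    method: str = "range",
    alpha: float = 0.05,
) -> float:
    """p(source | reference): proportion of the source distribution's values
    inside the reference's bracketed range (closed interval).

    ``method='range'`` brackets with the full empirical min-max range (the
    default); ``method='central_quantile'`` uses the central ``1 - alpha``
    quantile interval, a more stable bracket when extreme order statistics
    are unreliable.
    """
    lo, hi = _bracket(reference, method, alpha)
    v = source.values
    return float(np.mean((v >= lo) & (v <= hi)))


@dataclass(frozen=True)
class OverlapMatrix:
    """All ordered-pair unidirectional overlaps among k distributions.

    Entry (i, j) = p(i | j), the proportion of distribution i's values
    inside distribution j's bracket. Generally asymmetric; the diagonal is
    1 under the range method.
    """

    spec_names: Tuple[str, ...]
    entries: np.ndarray
    method: str
    alpha: float

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        k = len(self.spec_names)
        if entries.shape != (k, k):
            raise ValueError("entries must be a k x k matrix")
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)

    def to_frame(self) -> pd.DataFrame:
        """Square table: rows = source distribution i, columns = reference j."""
        return pd.DataFrame(
            self.entries, index=list(self.spec_names), columns=list(self.spec_names)
        )

    def to_pair_dict(self) -> Dict[str, float]:
        """JSON-friendly mapping ``"p(i|j)" -> overlap``."""
        out: Dict[str, float] = {}
        for i, si in enumerate(self.spec_names):
            for j, sj in enumerate(self.spec_names):
                out[f"p({si}|{sj})"] = float(self.entries[i, j])
        return out


def overlap_matrix(
    dists: Sequence[SamplingDistribution],
    method: str = "range",
    alpha: float = 0.05,
) -> OverlapMatrix:
    """Compute all k^2 ordered-pair unidirectional overlaps."""
    if len(dists) < 2:
        raise ValueError("need at least 2 distributions to compare")
    names = [d.spec_name for d in dists]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate distribution names: {names}")
    k = len(dists)
    entries = np.empty((k, k))
    brackets = [_bracket(d, method, alpha) for d in dists]
    for j, (lo, hi) in enumerate(brackets):
        for i, src in enumerate(dists):
            v = src.values
            entries[i, j] = np.mean((v >= lo) & (v <= hi))
    return OverlapMatrix(
        spec_names=tuple(names), entries=entries, method=method, alpha=float(alpha)
    )


def distributions_to_frame(dists: Sequence[SamplingDistribution]) -> pd.DataFrame:
    """Long-format export: columns spec_name, iteration, value."""
    frames = [
        pd.DataFrame(
            {
                "spec_name": d.spec_name,
                "iteration": np.arange(d.n_iter),
                "value": d.values,
            }
        )
        for d in dists
    ]
    return pd.concat(frames, ignore_index=True)


def summaries_to_frame(summaries: Sequence[DistributionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
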