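"""End-to-end vetting runs.

:func:`run_vetting` executes the computable core of the vetting workflow
for one config: build one sampling distribution per hypothesis
parametrization, summarise each for noisiness, compute the full
unidirectional overlap matrix for degeneracy, optionally collect auxiliary
spatial clustering metrics, render figures and write every table to disk.
Re-running the same config and seed regenerates byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import VettingConfig
from .settlement import HypothesisSpec, SettlementResult, simulate_settlement
from .spatial import clark_evans_index, from_settlement, mean_nearest_neighbour_distance
from .vetting import (
    DistributionSummary,
    OverlapMatrix,
    SamplingDistribution,
    build_sampling_distribution,
    distributions_to_frame,
    iteration_streams,
    overlap_matrix,
    summaries_to_frame,
    summarize_distribution,
)

__all__ = ["VettingReport", "run_vetting", "replay_iteration"]

SPATIAL_STATISTICS = {
    "mean_nn_distance": lambda res, land: mean_nearest_neighbour_distance(
        from_settlement(res, land)
    ),
    "clark_evans": lambda res, land: clark_evans_index(from_settlement(res, land)),
}


@dataclass
class VettingReport:
    """All artefacts of one vetting run."""

    config: VettingConfig
    distributions: List[SamplingDistribution]
    summaries: List[DistributionSummary]
    overlap: OverlapMatrix
    aux_summaries: Optional[pd.DataFrame]  # per-spec means of spatial metrics
    figure_paths: List[Path] = field(default_factory=list)
    output_dir: Optional[Path] = None

    def summary_frame(self) -> pd.DataFrame:
        return summaries_to_frame(self.summaries)


def run_vetting(
    config: VettingConfig,
    out_dir: Optional[Union[str, Path]] = None,
    figures: bool = True,
    progress: bool = False,
) -> VettingReport:
    """Run the full vetting computation for one config.

    When ``out_dir`` is given, writes ``distributions.csv``,
    ``summaries.csv``, ``overlap_matrix.csv``, ``overlap_matrix.json``,
    ``aux_summaries.csv`` (if spatial metrics are on), ``report.json``,
    ``seeds.csv`` and the figures under ``figures/``.
    """
    config.validate()
    specs = config.hypothesis_specs()
    land_cfg = config.landscape_config()
    extra = SPATIAL_STATISTICS if config.spatial_metrics else None

    dists: List[SamplingDistribution] = []
    aux_rows: List[dict] = []
    for spec in specs:
        if progress:
            print(f"  simulating {spec.name} ({config.n_iter} iterations)")
        out = build_sampling_distribution(
            land_cfg,
            spec,
            n_agents=config.n_agents,
            n_iter=config.n_iter,
            base_seed=config.base_seed,
            regenerate_landscape=config.regenerate_landscape,
            extra_statistics=extra,
        )
        if extra:
            dist, extras = out
            aux_rows.append(
                {
                    "spec_name": spec.name,
                    **{f"{k}_mean": float(np.mean(v)) for k, v in extras.items()},
                    **{f"{k}_std": float(np.std(v, ddof=1)) for k, v in extras.items()},
                }
            )
        else:
            dist = out
        dists.append(dist)

    summaries = [summarize_distribution(d) for d in dists]
    overlap = overlap_matrix(dists, method=config.overlap_method, alpha=config.alpha)
    aux = pd.DataFrame(aux_rows) if aux_rows else None

    report = VettingReport(
        config=config,
        distributions=dists,
        summaries=summaries,
        overlap=overlap,
        aux_summaries=aux,
    )

    if out_dir is not None:
        _write_outputs(report, Path(out_dir), figures=figures)
    return report


def _write_outputs(report: VettingReport, out_dir: Path, figures: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config = report.config

    distributions_to_frame(report.distributions).to_csv(
        out_dir / "distributions.csv", index=False
    )
    report.summary_frame().to_csv(out_dir / "summaries.csv", index=False)
    report.overlap.to_frame().to_csv(out_dir / "overlap_matrix.csv")
    (out_dir / "overlap_matrix.json").write_text(
        json.dumps(
            {
                "method": report.overlap.method,
                "alpha": report.overlap.alpha,
                "overlaps": report.overlap.to_pair_dict(),
            },
            indent=2,
        )
        + "\n"
    )
    if report.aux_summaries is not None:
        report.aux_summaries.to_csv(out_dir / "aux_summaries.csv", index=False)

    # every derived seed, so any single iteration can be replayed in isolation
    seed_rows = []
    for i in range(config.n_iter):
        land_ss, settle_ss = iteration_streams(config.base_seed, i)
        seed_rows.append(
            {
                "iteration": i,
                "iteration_seed": config.base_seed + i,
                "landscape_entropy": str(land_ss.entropy),
                "settlement_entropy": str(settle_ss.entropy),
            }
        )
    pd.DataFrame(seed_rows).to_csv(out_dir / "seeds.csv", index=False)

    figure_paths: List[Path] = []
    if figures:
        from .plots import (
            render_full_heatmap,
            render_overlap_heatmaps,
            render_whisker_plot,
        )

        specs = config.hypothesis_specs()
        fam = {s.name: s.family for s in specs}
        fig_dir = out_dir / "figures"
        figure_paths.append(
            render_whisker_plot(report.summaries, fig_dir / "whisker.png", fam)
        )
        figure_paths.extend(render_overlap_heatmaps(report.overlap, specs, fig_dir))
        figure_paths.append(
            render_full_heatmap(report.overlap, fig_dir / "overlap_full.png")
        )
    report.figure_paths = figure_paths
    report.output_dir = out_dir

    (out_dir / "report.json").write_text(
        json.dumps(
            {
                "hypovet_version": _version,
                "config": config.to_dict(),
                "n_parametrizations": config.n_parametrizations,
                "spec_names": list(report.overlap.spec_names),
                "files": sorted(
                    str(p.relative_to(out_dir))
                    for p in out_dir.rglob("*")
                    if p.is_file() and p.name != "report.json"
                ),
            },
            indent=2,
        )
        + "\n"
    )


def replay_iteration(
    config: VettingConfig, spec_name: str, iteration: int
) -> SettlementResult:
    """Re-run a single iteration of one parametrization in isolation.

    Uses the same per-iteration seed derivation as
    :func:`hypovet.vetting.build_sampling_distribution`, so the replayed
    result is identical to the one inside the full run.
    """
    config.validate()
    if not 0 <= iteration < config.n_iter:
        raise ValueError(
            f"iteration must lie in [0, {config.n_iter - 1}], got {iteration}"
        )
    by_name: Dict[str, HypothesisSpec] = {
        s.name: s for s in config.hypothesis_specs()
    }
    if spec_name not in by_name:
        raise ValueError(
            f"unknown spec {spec_name!r}; available: {sorted(by_name)}"
        )
    land_ss, settle_ss = iteration_streams(config.base_seed, iteration)
    if config.regenerate_landscape:
        landscape = config.landscape_config().generate(land_ss)
    else:
        landscape = config.landscape_config().generate(config.base_seed)
    return simulate_settlement(
        landscape, by_name[spec_name], config.n_agents, settle_ss
    )
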