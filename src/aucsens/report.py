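"""End-to-end analysis orchestration, report files, and plots.

``run_analysis`` wires the configuration, randomized ranking and optional
classical baseline together and writes a self-describing output directory:

    ranking.csv      param, A, display_value, classification, n_effective, ...
    ranking.json     same table plus run metadata (and optionally S samples)
    classical.csv    baseline ranking by R_cl (if requested)
    report.json      metadata sufficient to re-run the analysis bit-identically
    analysis.log     one machine-parsable key=value line per parameter
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .classical import ClassicalEntry, rank_classical
from .config import AnalysisSettings, load_model_config
from .errors import ValidationError
from .ode_core import OdeModel, SimulationConfig
from .randomized import Ranking, SensitivityResult, rank_parameters

__all__ = ["AnalysisReport", "run_analysis", "plot_ranking"]

log = logging.getLogger("aucsens")


def _tool_version() -> str:
    try:
        return metadata.version("aucsens")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class AnalysisReport:
    """Everything one analysis run produced, plus re-run metadata."""

    ranking: Ranking
    results: dict[str, SensitivityResult]
    classical: list[ClassicalEntry] | None
    run_metadata: dict
    timing: dict[str, float] = field(default_factory=dict)

    def metadata_json(self) -> dict:
        return {"run_metadata": self.run_metadata, "timing": self.timing}


def run_analysis(
    config_path: str | Path,
    out_dir: str | Path,
    include_classical: bool = False,
    include_samples: bool = False,
) -> AnalysisReport:
    """Run the full randomized OAT analysis described by a config file.

    Writes ranking CSV/JSON, a metadata report and a per-parameter log into
    ``out_dir``.  Deterministic for a fixed configuration (seed included).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model, sim, settings = load_model_config(config_path)
    return _run_loaded(model, sim, settings, out, include_classical, include_samples)


def _run_loaded(
    model: OdeModel,
    sim: SimulationConfig,
    settings: AnalysisSettings,
    out: Path,
    include_classical: bool,
    include_samples: bool,
) -> AnalysisReport:
    timing: dict[str, float] = {}
    t0 = time.perf_counter()
    ranking, results = rank_parameters(
        model, sim,
        dist=settings.distribution,
        n=settings.n_samples,
        seed=settings.seed,
        neutral_band=settings.neutral_band,
    )
    timing["randomized_ranking_s"] = time.perf_counter() - t0

    classical = None
    if include_classical:
        t0 = time.perf_counter()
        classical = rank_classical(model, sim)
        timing["classical_ranking_s"] = time.perf_counter() - t0

    run_metadata = {
        "tool_version": _tool_version(),
        "model": model.name,
        "output_variable": model.output_variable,
        "horizon_T": sim.horizon_T,
        "n_points": sim.n_points,
        "rtol": sim.rtol,
        "atol": sim.atol,
        "stiff_solver": sim.stiff_solver,
        "distribution": settings.distribution.to_dict(),
        "n_samples": settings.n_samples,
        "seed": settings.seed,
        "neutral_band": settings.neutral_band,
        "nominal_params": dict(model.nominal_params),
        "excluded_params": sorted(model.non_ranked_params),
        "unrankable_params": list(ranking.unrankable),
        "total_simulations": 1 + sum(
            r.n_effective + r.failed_runs for r in results.values()
        ),
    }
    report = AnalysisReport(
        ranking=ranking, results=results, classical=classical,
        run_metadata=run_metadata, timing=timing,
    )
    _write_outputs(report, out, include_samples)
    return report


def _write_outputs(report: AnalysisReport, out: Path, include_samples: bool) -> None:
    df = report.ranking.to_frame()
    df.to_csv(out / "ranking.csv", index=False)

    ranking_json = {
        "entries": df.to_dict("records"),
        "unrankable": report.ranking.unrankable,
        **report.metadata_json(),
    }
    if include_samples:
        ranking_json["samples"] = {
            p: {"alphas": r.alphas.tolist(), "s_values": r.s_values.tolist()}
            for p, r in report.results.items()
        }
    (out / "ranking.json").write_text(json.dumps(ranking_json, indent=2))

    if report.classical is not None:
        pd.DataFrame(
            [{"param": e.param_name, "R_cl": e.R_cl, "error": e.error} for e in report.classical]
        ).to_csv(out / "classical.csv", index=False)

    (out / "report.json").write_text(json.dumps(report.metadata_json(), indent=2))

    lines = [
        f"param={e.param_name} A={e.A:.6g} display={e.display_value:.6g} "
        f"class={e.classification} n_effective={e.n_effective} failed={e.failed_runs} "
        f"flagged={e.flagged}"
        for e in report.ranking.entries
    ]
    lines += [f"param={p} unrankable=true" for p in report.ranking.unrankable]
    lines.append(f"total_simulations={report.run_metadata['total_simulations']}")
    (out / "analysis.log").write_text("\n".join(lines) + "\n")
    for ln in lines:
        log.info(ln)


def plot_ranking(ranking: Ranking, out_path: str | Path, title: str | None = None):
    """Scatter of display values (A + 1) per parameter on a log axis.

    The horizontal threshold line at 1 marks no effect: points above it are
    parameters whose alteration amplifies the output, points below it
    suppress it.  Zero display values (complete suppression) are clipped to
    the bottom of the axis.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not ranking.entries:
        raise ValidationError("plot_ranking: empty ranking")
    names = [e.param_name for e in ranking.entries]
    vals = np.array([e.display_value for e in ranking.entries])
    floor = max(vals[vals > 0].min() / 10 if np.any(vals > 0) else 1e-3, 1e-6)
    clipped = np.maximum(vals, floor)

    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(names)), 4))
    ax.scatter(range(1, len(names) + 1), clipped, zorder=3)
    ax.axhline(1.0, color="red", lw=1, label="no effect (A + 1 = 1)")
    ax.set_yscale("log")
    ax.set_xticks(range(1, len(names) + 1))
    ax.set_xticklabels(names, rotation=90, fontsize=8)
    ax.set_ylabel("A + 1 (log scale)")
    ax.set_xlabel("parameter")
    ax.set_title(title or f"Drug-target ranking ({ranking.output_variable})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return Path(out_path)
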