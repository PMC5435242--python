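"""End-to-end orchestration: threshold sweeps, model-comparison sweeps,
subsampling variants, cost simulation, and report files.

Aggregation follows the per-dataset-first convention: every statistic is
computed separately for each connectivity matrix, and only then averaged
(with a standard deviation) across the collection.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .matrix_io import read_matrix
from .metrics import ConnectivityMatrix, binarize, degree, graph_summary, strength
from .selection import (
    ComparisonResult,
    SelectionSummary,
    compare_models,
    prepare_fit_data,
    summarize_selection,
)
from .simulation import delta_mean_strength, simulate_strength_means
from .subsampling import subsample
from .synthetic import SyntheticConfig, generate_collection

__all__ = [
    "SweepConfig",
    "METRIC_THRESHOLDS",
    "COMPARISON_THRESHOLDS",
    "load_collection",
    "metric_sweep",
    "comparison_sweep",
    "ccdf_table",
    "run_full_analysis",
]

logger = logging.getLogger("conncrit.pipeline")

#: Default r_c grid for the graph-metric sweep.
METRIC_THRESHOLDS = tuple(np.round(np.arange(0.0, 0.91, 0.1), 10))
#: Default r_c grid for the model-comparison sweep.
COMPARISON_THRESHOLDS = tuple(np.round(np.arange(0.2, 0.71, 0.1), 10))


@dataclass
class SweepConfig:
    """Settings for a full analysis run."""

    thresholds: tuple = METRIC_THRESHOLDS
    comparison_thresholds: tuple = COMPARISON_THRESHOLDS
    stat_kind: str = "strength"
    subsample_sizes: tuple | None = None
    seed: int = 0
    input: SyntheticConfig | str | Path | None = None
    n_sim_replicates: int = 200

    def __post_init__(self):
        for grid in (self.thresholds, self.comparison_thresholds):
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0 or np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError("thresholds must be a nonempty grid in [0, 1]")
            if np.any(np.diff(arr) <= 0):
                raise ConfigurationError("thresholds must be sorted ascending")
        if self.stat_kind not in ("degree", "strength"):
            raise ConfigurationError(f"unknown stat_kind {self.stat_kind!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = [float(t) for t in self.thresholds]
        d["comparison_thresholds"] = [float(t) for t in self.comparison_thresholds]
        if isinstance(self.input, SyntheticConfig):
            d["input"] = dataclasses.asdict(self.input)
        elif self.input is not None:
            d["input"] = str(self.input)
        if self.subsample_sizes is not None:
            d["subsample_sizes"] = [int(n) for n in self.subsample_sizes]
        return d


def load_collection(source) -> list[ConnectivityMatrix]:
    """Materialise a matrix collection from a synthetic config or a directory."""
    if isinstance(source, SyntheticConfig):
        return generate_collection(source)
    path = Path(source)
    if not path.is_dir():
        raise ConfigurationError(f"input {path} is not a directory of matrix files")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".txt", ".csv", ".tsv")
    )
    if not files:
        raise ConfigurationError(f"no matrix files (*.txt, *.csv, *.tsv) in {path}")
    return [read_matrix(p) for p in files]


def node_stats(matrix: ConnectivityMatrix, r_c: float, stat_kind: str):
    """Per-node degree or strength for one matrix at one threshold."""
    if stat_kind == "degree":
        return degree(binarize(matrix, r_c))
    if stat_kind == "strength":
        return strength(matrix, r_c)
    raise ConfigurationError(f"unknown stat_kind {stat_kind!r}")


def metric_sweep(
    collection: list[ConnectivityMatrix],
    thresholds=METRIC_THRESHOLDS,
    unreachable: str = "zero",
) -> pd.DataFrame:
    """Across-matrix mean/SD of every graph measure at each threshold.

    The returned frame carries one row per threshold with mean and SD
    columns per measure, the successive clustering change
    ``delta_transitivity = C(r_c) - C(r_c + step)``, the per-threshold mean
    cost normalised by its sweep maximum, and efficiency per normalised cost.
    """
    if not collection:
        raise ValidationError("metric_sweep needs a nonempty collection")
    thresholds = [float(t) for t in thresholds]
    rows = []
    for r_c in thresholds:
        per_matrix = []
        for m in collection:
            gs = graph_summary(m, r_c, unreachable=unreachable)
            s_mean = float(strength(m, r_c).values.mean())
            per_matrix.append(
                (
                    gs.connection_ratio,
                    s_mean,
                    gs.largest_component_fraction,
                    gs.transitivity,
                    gs.avg_path_length,
                    gs.efficiency,
                    gs.cost,
                )
            )
        arr = np.asarray(per_matrix, dtype=float)
        mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=0)
        rows.append(
            {
                "r_c": r_c,
                "connection_ratio_mean": mean[0],
                "connection_ratio_sd": sd[0],
                "strength_mean": mean[1],
                "strength_sd": sd[1],
                "largest_component_fraction_mean": mean[2],
                "largest_component_fraction_sd": sd[2],
                "transitivity_mean": mean[3],
                "transitivity_sd": sd[3],
                "avg_path_length_mean": mean[4],
                "avg_path_length_sd": sd[4],
                "efficiency_mean": mean[5],
                "efficiency_sd": sd[5],
                "cost_mean": mean[6],
                "cost_sd": sd[6],
            }
        )
    df = pd.DataFrame(rows)
    c = df["transitivity_mean"].to_numpy()
    df["delta_transitivity"] = np.append(c[:-1] - c[1:], np.nan)
    max_cost = df["cost_mean"].max()
    df["normalized_cost"] = df["cost_mean"] / max_cost if max_cost > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        df["efficiency_per_cost"] = np.where(
            df["normalized_cost"] > 0,
            df["efficiency_mean"] / df["normalized_cost"],
            np.nan,
        )
    return df


def _compare_collection(
    collection, r_c: float, stat_kind: str, subsample_n: int | None
) -> tuple[list[ComparisonResult], int]:
    results, skipped = [], 0
    for idx, m in enumerate(collection):
        try:
            sample = prepare_fit_data(node_stats(m, r_c, stat_kind))
            if subsample_n is not None:
                if subsample_n > sample.size:
                    raise InsufficientDataError(
                        f"subsample n={subsample_n} exceeds sample size {sample.size}"
                    )
                sample, _ = subsample(sample, subsample_n)
            results.append(compare_models(sample))
        except (InsufficientDataError, ValidationError) as exc:
            skipped += 1
            logger.info("matrix %d skipped at r_c=%.3g: %s", idx, r_c, exc)
    return results, skipped


def comparison_sweep(
    collection: list[ConnectivityMatrix],
    thresholds=COMPARISON_THRESHOLDS,
    stat_kind: str = "strength",
    subsample_sizes=None,
) -> list[SelectionSummary]:
    """Per-threshold model selection over a collection, optionally subsampled.

    For each threshold the per-matrix node statistics are prepared (zeros
    dropped), optionally reduced to ``n`` mid-quantile points, fitted by all
    three models, and summarised into selection ratios and mean-AICc gaps.
    Matrices with too few usable values are skipped and counted.
    """
    if not collection:
        raise ValidationError("comparison_sweep needs a nonempty collection")
    variants = [None] + [int(n) for n in (subsample_sizes or ())]
    summaries = []
    for r_c in (float(t) for t in thresholds):
        for sub_n in variants:
            results, skipped = _compare_collection(collection, r_c, stat_kind, sub_n)
            if not results:
                logger.warning(
                    "no fittable matrices at r_c=%.3g (subsample_n=%s)", r_c, sub_n
                )
                continue
            summaries.append(
                summarize_selection(
                    results,
                    r_c,
                    stat_kind=stat_kind,
                    subsample_n=sub_n,
                    n_skipped=skipped,
                )
            )
    return summaries


def ccdf_table(
    collection: list[ConnectivityMatrix],
    thresholds=COMPARISON_THRESHOLDS,
    stat_kind: str = "strength",
) -> pd.DataFrame:
    """Empirical complementary cumulative distribution per matrix/threshold.

    For each positive node statistic ``x`` the exported ``ccdf`` column is
    the fraction of values ``>= x`` (so the largest value maps to ``1/N``),
    the form plotted on log-log axes against the fitted model curves.
    """
    rows = []
    for idx, m in enumerate(collection):
        for r_c in (float(t) for t in thresholds):
            vals = node_stats(m, r_c, stat_kind).values
            vals = np.sort(vals[vals > 0])
            n = vals.size
            if n == 0:
                continue
            ccdf = 1.0 - np.arange(n) / n  # fraction of values >= vals[i]
            for v, c in zip(vals, ccdf):
                rows.append(
                    {
                        "matrix_id": idx,
                        "r_c": r_c,
                        "stat_kind": stat_kind,
                        "value": v,
                        "ccdf": c,
                    }
                )
    return pd.DataFrame(rows)


def _selection_frames(summaries: list[SelectionSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for model_id in s.selection_ratio:
            rows.append(
                {
                    "r_c": s.threshold,
                    "stat_kind": s.stat_kind,
                    "subsample_n": s.subsample_n,
                    "model": model_id,
                    "selection_ratio": s.selection_ratio[model_id],
                    "mean_delta_aic": s.mean_delta_aic[model_id],
                    "n_results": s.n_results,
                    "n_skipped": s.n_skipped,
                }
            )
    return pd.DataFrame(rows)


def _simulation_report(collection, config: SweepConfig) -> dict:
    """Fit restricted and truncated models at a reference threshold and
    compare simulated mean strengths with the empirical reference."""
    comp = list(config.comparison_thresholds)
    r_ref = float(comp[len(comp) // 2])
    per_matrix_means, fits = [], {"restricted": [], "truncated": []}
    for m in collection:
        try:
            sample = prepare_fit_data(strength(m, r_ref))
        except InsufficientDataError:
            continue
        per_matrix_means.append(float(sample.mean()))
        res = compare_models(sample)
        for mid in fits:
            if mid in res.fits:
                fits[mid].append(res.fits[mid].params)
    if not per_matrix_means:
        return {"reference_threshold": r_ref, "error": "no fittable matrices"}
    reference = float(np.mean(per_matrix_means))
    n_nodes = collection[0].n_regions
    report = {
        "reference_threshold": r_ref,
        "reference_mean_strength": reference,
        "n_nodes": n_nodes,
        "n_replicates": config.n_sim_replicates,
        "seed": config.seed,
        "models": {},
    }
    for mid, params_list in fits.items():
        if not params_list:
            continue
        # average the per-matrix fitted parameters (per-dataset-first)
        fields = {
            name: float(np.mean([getattr(p, name) for p in params_list]))
            for name in type(params_list[0]).__dataclass_fields__
        }
        sim = simulate_strength_means(
            mid,
            fields,
            n_nodes=n_nodes,
            n_replicates=config.n_sim_replicates,
            seed=config.seed,
        )
        delta = delta_mean_strength(sim, reference)
        report["models"][mid] = {
            "params": fields,
            "mean_of_means": sim.mean_of_means,
            "delta_mean": delta,
        }
    return report


def run_full_analysis(config: SweepConfig, out_dir) -> dict[str, Path]:
    """Run the complete analysis and write the report bundle.

    Writes ``metrics.csv`` (graph-metric sweep), ``selection.csv`` and
    ``selection.json`` (model comparison), ``ccdf.csv`` (plot-ready
    empirical complementary cumulatives), ``simulation.json`` (cost
    stability) and ``manifest.json`` (seed, version, config hash) under
    ``out_dir``; returns the path of each artifact.
    """
    if config.input is None:
        raise ConfigurationError("run_full_analysis requires an input source")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collection = load_collection(config.input)

    paths = {}
    metrics = metric_sweep(collection, thresholds=config.thresholds)
    paths["metrics"] = out_dir / "metrics.csv"
    metrics.to_csv(paths["metrics"], index=False)

    summaries = comparison_sweep(
        collection,
        thresholds=config.comparison_thresholds,
        stat_kind=config.stat_kind,
        subsample_sizes=config.subsample_sizes,
    )
    sel_df = _selection_frames(summaries)
    paths["selection"] = out_dir / "selection.csv"
    sel_df.to_csv(paths["selection"], index=False)
    paths["selection_json"] = out_dir / "selection.json"
    paths["selection_json"].write_text(
        json.dumps(sel_df.to_dict(orient="records"), indent=2)
    )

    paths["ccdf"] = out_dir / "ccdf.csv"
    ccdf_table(
        collection, thresholds=config.comparison_thresholds, stat_kind=config.stat_kind
    ).to_csv(paths["ccdf"], index=False)

    paths["simulation"] = out_dir / "simulation.json"
    paths["simulation"].write_text(
        json.dumps(_simulation_report(collection, config), indent=2)
    )

    cfg = config.to_dict()
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "n_matrices": len(collection),
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
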