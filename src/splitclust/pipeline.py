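"""End-to-end orchestration: exclusion -> transform -> screens -> clustering
-> slopes -> embedding (-> optional split simulation), with a run manifest.

Every artifact is a plain-text file (CSV or JSON) and every stage is
seeded, so a rerun with the same inputs and configuration reproduces the
artifacts byte for byte.  Heatmaps are exported as CSV matrices (and
optionally rendered to PNG); downstream checks never read pixels.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import compare_sets, screen_frame, univariate_screen
from .core import AnalysisConfig, Cohort, VariableSchema, default_schema, \
    exclude_incomplete, read_cohort
from .embedding import embed_2d
from .preprocessing import save_params, transform_cohort
from .simulation import masked_mean_correlation_frame, random_split_simulation
from .slopes import cluster_slope_table
from .stability import masked_heatmap_frame, stratified_analysis

__all__ = ["PipelineStageError", "run_pipeline"]

log = logging.getLogger("splitclust")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; names the stage and carries the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _report_payload(report) -> dict:
    return {
        "delta": report.delta,
        "tau": report.tau,
        "n_pairs": report.n_pairs,
        "n_consistent": report.n_consistent,
        "n_retained": report.n_retained,
        "pairs": report.table.round(10).to_dict(orient="records"),
    }


def run_pipeline(
    config: AnalysisConfig,
    cohort: Cohort | str | Path,
    out_dir: str | Path,
    schema: VariableSchema | None = None,
    include_split_simulation: bool = False,
    render: bool = False,
) -> dict:
    """Run the full analysis and write all artifacts under *out_dir*.

    Returns the run manifest (also written as ``manifest.json``) listing
    the configuration, seeds and every artifact path.  Any stage error
    aborts with a :class:`PipelineStageError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _stage(name):
        log.info("stage %s", name)

    try:
        _stage("load")
        if not isinstance(cohort, Cohort):
            cohort = read_cohort(cohort, schema or default_schema())
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineStageError("load", exc) from exc

    def run_stage(name, fn):
        _stage(name)
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(name, exc) from exc

    def do_exclude():
        complete = exclude_incomplete(cohort)
        _dump_json(
            [{"patient_id": str(pid), "missing": list(cols)}
             for pid, cols in complete.exclusion_log],
            out / "exclusion_log.json",
        )
        artifacts["exclusion_log"] = "exclusion_log.json"
        return complete

    complete = run_stage("exclude_incomplete", do_exclude)

    def do_comparability():
        rows = compare_sets(complete)
        _dump_json(
            [dataclasses.asdict(r) for r in rows], out / "comparability.json"
        )
        artifacts["comparability"] = "comparability.json"
        return rows

    run_stage("comparability", do_comparability)

    def do_transform():
        transformed, params = transform_cohort(
            complete, per_set=config.fit_transform_per_set
        )
        save_params(params, out / "transform_params.json")
        transformed.data.to_csv(out / "transformed.csv", index=False)
        artifacts["transform_params"] = "transform_params.json"
        artifacts["transformed_cohort"] = "transformed.csv"
        return transformed

    transformed = run_stage("transform", do_transform)

    def do_screen():
        frame = screen_frame(univariate_screen(transformed))
        frame.to_csv(out / "screen.csv", index=False)
        artifacts["screen"] = "screen.csv"

    run_stage("univariate_screen", do_screen)

    def do_stability():
        results = stratified_analysis(transformed, config)
        payload, clusters_payload = {}, {}
        for value, (report, clusters) in results.items():
            key = f"stratum_{value}"
            payload[key] = _report_payload(report)
            clusters_payload[key] = {
                "clusters": [sorted(c) for c in clusters.clusters],
                "residual_pairs": [list(p) for p in clusters.residual_pairs],
            }
            heat = masked_heatmap_frame(report)
            heat.to_csv(out / f"heatmap_{key}.csv")
            artifacts[f"heatmap_{key}"] = f"heatmap_{key}.csv"
            if render:
                _render_heatmap(heat, out / f"heatmap_{key}.png")
        _dump_json(payload, out / "stability.json")
        _dump_json(clusters_payload, out / "clusters.json")
        artifacts["stability"] = "stability.json"
        artifacts["clusters"] = "clusters.json"
        return results

    stability_results = run_stage("stability_clustering", do_stability)

    def do_slopes():
        seen, merged = set(), []
        for _, (_, clusters) in sorted(stability_results.items()):
            for c in clusters.clusters:
                if c not in seen:
                    seen.add(c)
                    merged.append(c)
        from .stability import ClusterSet

        table = cluster_slope_table(
            transformed, ClusterSet(merged, []), method=config.slope_p_method
        )
        table.to_csv(out / "slopes.csv", index=False)
        artifacts["slopes"] = "slopes.csv"

    run_stage("slopes", do_slopes)

    def do_embedding():
        from .stability import correlation_matrices

        frames = []
        for value, sub in transformed.strata().items():
            mats = correlation_matrices(sub, kind=config.correlation_kind)
            emb = embed_2d(
                mats.r_combined,
                rng_seed=config.rng_seed,
                variables=list(mats.variables),
                dissimilarity=config.embedding_dissimilarity,
            )
            frame = emb.coords.round(10).copy()
            frame.insert(0, "stratum", value)
            frame.insert(1, "stress", round(emb.stress, 10))
            frames.append(frame.rename_axis("variable").reset_index())
        pd.concat(frames, ignore_index=True).to_csv(
            out / "embedding.csv", index=False
        )
        artifacts["embedding"] = "embedding.csv"

    run_stage("embedding", do_embedding)

    if include_split_simulation:
        def do_sim():
            summaries = random_split_simulation(transformed, config)
            payload = {}
            for key, summary in summaries.items():
                payload[f"stratum_{key}"] = summary.table.round(10).to_dict(
                    orient="records"
                )
                masked_mean_correlation_frame(summary).to_csv(
                    out / f"sim_heatmap_stratum_{key}.csv"
                )
                artifacts[f"sim_heatmap_stratum_{key}"] = (
                    f"sim_heatmap_stratum_{key}.csv"
                )
            _dump_json(payload, out / "split_simulation.json")
            artifacts["split_simulation"] = "split_simulation.json"

        run_stage("split_simulation", do_sim)

    manifest = {
        "package": "splitclust",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_patients": len(complete),
        "n_training": complete.n_training,
        "n_validation": complete.n_validation,
        "artifacts": artifacts,
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest


def _render_heatmap(frame: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    data = np.ma.masked_invalid(frame.to_numpy(dtype=float))
    im = ax.imshow(data, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(frame.columns)), frame.columns, rotation=90)
    ax.set_yticks(range(len(frame.index)), frame.index)
    fig.colorbar(im, ax=ax, label="r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
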