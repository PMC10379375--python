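"""End-to-end orchestration: simulate/ingest -> extract -> score ->
compare -> classify, from one config and one seed.

Every stage consumes the previous stage's artifact, so each stage can be
re-run in isolation from its input CSVs with identical results.  The run
report echoes the configuration, logs every defaulted tunable, and
carries the retained-parameter list, the group-comparison table, the
cluster summary and the PCA1 loading report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import io as tio
from . import masking as msk
from . import stats as st
from .config import RunConfig
from .curves import AverageCurve, average_curves, select_representatives, smooth
from .errors import TimaskError
from .io import TICurve
from .params import TIParameters, extract
from .synthetic import SyntheticStudy, generate_study


@dataclass
class RunReport:
    """Everything needed to audit one pipeline run."""

    config: dict
    seeds: dict
    stage_counts: dict
    retained_parameters: list
    exclusions: list
    comparisons: pd.DataFrame
    cluster_table: pd.DataFrame
    cluster_test: dict
    loading_table: pd.DataFrame
    loading_top_ratio: float
    explained_variance_ratio: list
    version: str

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = self.comparisons.to_dict(orient="records")
        d["cluster_table"] = self.cluster_table.to_dict(orient="records")
        d["loading_table"] = self.loading_table.to_dict(orient="records")
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, default=str, **kw)

    def to_text(self) -> str:
        lines = [
            f"timask run report (version {self.version}, seed {self.config.get('seed')})",
            "",
            "stage counts: " + ", ".join(f"{k}={v}" for k, v in self.stage_counts.items()),
            "retained parameters: " + ", ".join(self.retained_parameters),
            "",
            "top-vs-bottom group comparison:",
            self.comparisons.to_string(index=False),
            "",
            "clusters (highest label = highest mean masking score):",
            self.cluster_table[["cluster", "n", "mean_masking_score"]].round(1).to_string(index=False),
            f"high-vs-rest Mann-Whitney: {self.cluster_test}",
            "",
            "PCA1 loadings by magnitude:",
            self.loading_table.to_string(index=False),
            f"top-two |loading| ratio: {self.loading_top_ratio:.2f}",
            "explained variance ratio: "
            + ", ".join(f"{v:.3f}" for v in self.explained_variance_ratio),
        ]
        return "\n".join(lines)


@dataclass
class PipelineResult:
    """Stage artifacts of one run plus the report."""

    report: RunReport
    study: SyntheticStudy | None
    matrix: st.ParameterMatrix
    phases: pd.DataFrame
    masking_results: list
    retained: list
    comparisons: list
    model: clf.ClusterModel
    cluster_summary: clf.ClusterSummary
    loading_report: clf.LoadingReport


def _average_curve_for_material(
    replicate_groups: dict[str, list[TICurve]], material_id: str, cfg: RunConfig
) -> AverageCurve:
    """Smooth, select representatives and average one material's curves.

    ``per_panelist`` averaging selects and averages within each panelist
    first, then averages the panelist curves; ``pooled`` selects across
    all of the material's curves at once.  When a group has fewer curves
    than ``n_representatives``, all of them are used.
    """
    kw = dict(eps_i=cfg.eps_i, min_dur_s=cfg.min_dur_s,
              eps_pl=cfg.eps_pl, min_plateau_s=cfg.min_plateau_s)

    def _select(curves: list[TICurve]) -> list[TICurve]:
        smoothed = [smooth(c, cfg.smooth_window_s) for c in curves]
        n_keep = min(cfg.n_representatives, len(smoothed))
        return select_representatives(smoothed, n_keep, presmoothed=True, **kw)

    if cfg.averaging == "per_panelist":
        per_panelist = []
        for pid in sorted(replicate_groups):
            per_panelist.append(average_curves(_select(replicate_groups[pid]), material_id))
        return average_curves(per_panelist, material_id)
    pooled = [c for pid in sorted(replicate_groups) for c in replicate_groups[pid]]
    return average_curves(_select(pooled), material_id)


def extract_parameter_matrix(
    curves: list[TICurve], cfg: RunConfig | None = None
) -> tuple[st.ParameterMatrix, pd.DataFrame]:
    """Curves -> materials x 14 parameter matrix + phase-annotation table."""
    cfg = cfg or RunConfig()
    groups: dict[str, dict[str, list[TICurve]]] = {}
    for c in curves:
        groups.setdefault(c.material_id, {}).setdefault(c.panelist_id, []).append(c)
    rows, phases = {}, []
    for mat in sorted(groups):
        avg = _average_curve_for_material(groups[mat], mat, cfg)
        p: TIParameters = extract(
            avg, eps_i=cfg.eps_i, min_dur_s=cfg.min_dur_s,
            eps_pl=cfg.eps_pl, min_plateau_s=cfg.min_plateau_s,
        )
        rows[mat] = p.as_dict()
        phases.append((mat, p.Tstart, p.TsPl, p.TePl, p.Tend))
    matrix = st.ParameterMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=list(tio.PARAMETER_NAMES))
    )
    matrix.data.index.name = "material_id"
    phase_df = pd.DataFrame(phases, columns=["material_id", "Tstart", "TsPl", "TePl", "Tend"])
    return matrix, phase_df


def run_pipeline(cfg: RunConfig, out_dir=None) -> PipelineResult:
    """Run all stages from one config; optionally write every artifact."""
    from . import __version__

    seeds = cfg.stage_seeds()

    # --- stage 1: simulate or ingest -------------------------------------
    study = None
    if cfg.synthetic is not None:
        study = generate_study(cfg.synthetic, seed=seeds["simulate"])
        curves, vas = study.curves, study.vas
    else:
        curves = tio.read_curves(cfg.curves_path)
        vas = tio.read_vas(cfg.vas_path)

    # --- stage 2: extract -------------------------------------------------
    matrix, phases = extract_parameter_matrix(curves, cfg)

    # --- stage 3: score ---------------------------------------------------
    masking_results = msk.score_materials(vas)

    # --- stage 4: prune + compare ----------------------------------------
    retained, exclusions = st.prune_correlated(matrix, cfg.r_threshold, cfg.prune_mode)
    comparisons = st.compare_top_bottom(
        matrix.select(retained), masking_results, k=cfg.top_bottom_k,
        alpha=cfg.alpha,
    )

    # --- stage 5: classify ------------------------------------------------
    pruned = matrix.select(retained)
    z = pruned if cfg.pca_on_raw else st.standardize(pruned)
    model = clf.fit_cluster_model(
        z, masking=masking_results, k=cfg.n_clusters, seed=seeds["kmeans"],
        n_init=cfg.kmeans_n_init, n_components=cfg.n_components,
        cluster_space=cfg.cluster_space, allow_unstandardized=cfg.pca_on_raw,
    )
    summary = clf.summarize_clusters(model.labels, masking_results, alpha=cfg.alpha)
    loadings = clf.loading_report(model)

    n_materials = len(matrix.data)
    counts = {
        "curves": len(curves),
        "materials": n_materials,
        "vas_records": len(vas),
        "masking_results": len(masking_results),
        "retained_parameters": len(retained),
        "comparisons": len(comparisons),
        "clustered_materials": int(model.labels.size),
    }
    if not (len(masking_results) == n_materials == model.labels.size):
        raise TimaskError(f"row loss between stages: {counts}")

    report = RunReport(
        config=cfg.to_dict(),
        seeds=seeds,
        stage_counts=counts,
        retained_parameters=list(retained),
        exclusions=[dataclasses.asdict(e) for e in exclusions],
        comparisons=st.comparisons_to_frame(comparisons),
        cluster_table=summary.table[["cluster", "n", "mean_masking_score"]].copy(),
        cluster_test={
            "high_cluster": summary.high_cluster, "U": summary.U,
            "p_two_tailed": summary.p_two_tailed, "significant": summary.significant,
            "note": summary.note,
        },
        loading_table=loadings.table,
        loading_top_ratio=loadings.top_ratio,
        explained_variance_ratio=[float(v) for v in model.explained_variance_ratio],
        version=__version__,
    )
    result = PipelineResult(
        report=report, study=study, matrix=matrix, phases=phases,
        masking_results=masking_results, retained=list(retained),
        comparisons=comparisons, model=model, cluster_summary=summary,
        loading_report=loadings,
    )
    if out_dir is not None:
        _write_artifacts(result, cfg, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if result.study is not None:
        result.study.write(out)
    tio.write_parameter_matrix(result.matrix, out / "params.csv")
    result.phases.to_csv(out / "phases.csv", index=False)
    pd.DataFrame(
        [(m.material_id, m.median_intensity, m.masking_score, m.n_ratings)
         for m in result.masking_results],
        columns=["material_id", "median_intensity", "masking_score", "n_ratings"],
    ).to_csv(out / "masking.csv", index=False)
    st.comparisons_to_frame(result.comparisons).to_csv(out / "comparison.csv", index=False)
    model = result.model
    model_doc = {
        "k": model.k, "seed": model.seed, "inertia": model.inertia,
        "explained_variance_ratio": [float(v) for v in model.explained_variance_ratio],
        "loadings": model.loadings.to_dict(),
        "labels": {str(k): int(v) for k, v in model.labels.items()},
    }
    (out / "model.json").write_text(json.dumps(model_doc, indent=2), encoding="utf-8")
    model.labels.rename_axis("material_id").to_frame().to_csv(out / "clusters.csv")
    result.loading_report.table.to_csv(out / "loading_report.csv", index=False)
    (out / "report.json").write_text(result.report.to_json(), encoding="utf-8")
    (out / "report.txt").write_text(result.report.to_text(), encoding="utf-8")
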