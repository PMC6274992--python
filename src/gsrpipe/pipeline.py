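"""End-to-end orchestration of the GSR workflow.

Reads the four inputs (expression TSV, annotation TSV, GMT, OBO),
reconstructs per-group functionomes against the shared control cohort,
extracts the immunofunctionome, and runs the staged inference through to
classification, writing every artifact under an output directory with
fixed names:

* ``group_means.tsv`` / ``group_means_immuno.tsv`` — per-stage summary
  (group, case mean/SD, control mean/SD, corrected case mean, p).
* ``deregulation.tsv`` — per-set per-stage statistics with q and rank.
* ``top_<k>.tsv`` — per-stage top rankings.
* ``venn.json`` — membership-signature partition of the top-k lists.
* ``progressive.txt`` — progressively deregulated set ids.
* ``core_auxiliary.json`` — similarity-merged core clusters + auxiliary.
* ``classification.json`` — binary and multiclass CV reports.
* ``dendrogram.newick`` — group-profile clustering.
* ``hist_<stage>.png`` — case vs control GSR histograms.
* ``run_log.json`` — per-stage counts (sets tested/skipped, samples).

Multi-dataset cohorts are handled in case/control pairings: each case
dataset is scored against the control pool on their common genes, case
scores are pooled, and each control's per-set score is averaged over the
pairings of a group (one row per control sample either way).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from gsrpipe import classify as _classify
from gsrpipe import dereg_stats as _stats
from gsrpipe import go_dag as _go
from gsrpipe import gsr_core as _core
from gsrpipe import io_formats as _io

logger = logging.getLogger(__name__)

STAGES = ("stageI", "stageII", "stageIII", "stageIV")


@dataclass
class PipelineConfig:
    """Paths, parameters and output directory for one pipeline run."""

    expression: str = ""
    annotation: str = ""
    gmt: str = ""
    obo: str = ""
    mapping: str = ""          # optional explicit set_id -> term_id TSV
    out_dir: str = "gsr_out"
    ancestors: tuple[str, ...] = _go.IMMUNE_ANCESTORS
    stage_order: tuple[str, ...] = STAGES
    k_top: int = 75            # intersection depth across stages
    k_table: int = 20          # per-stage ranking table depth
    alpha: float = 0.05
    tau: float = 0.5
    min_depth: int = 3
    cv_k: tuple[int, ...] = (5,)
    repeats: int = 10
    seed: int = 0
    control_scoring: str = "split"
    plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ancestors", "stage_order", "cv_k"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("ancestors", "stage_order", "cv_k"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


@dataclass
class FunctionomeBundle:
    """Per-group case functionomes plus matched control functionomes."""

    case_by_group: dict[str, _core.Functionome]
    control_by_group: dict[str, _core.Functionome]
    log: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    expr = _io.read_expression(config.expression)
    annot = _io.read_annotation(config.annotation)
    collection = _io.read_gmt(config.gmt)
    report = _io.reconcile_samples(expr, annot)
    if report.only_in_annotation:
        raise ValueError(
            f"annotated samples absent from expression: {report.only_in_annotation[:5]}"
        )
    if report.only_in_expression:
        logger.warning("unannotated expression samples ignored: %s",
                       report.only_in_expression[:5])
        annot = annot  # unannotated columns are simply never selected
    return expr, annot, collection


def build_functionomes(expr: _io.ExpressionMatrix, annot: pd.DataFrame,
                       collection: _io.GeneSetCollection,
                       stage_order: Sequence[str] = STAGES,
                       control_scoring: str = "split") -> FunctionomeBundle:
    """Reconstruct case and control functionomes for every stage group,
    pairing each case dataset with the shared control pool on their
    common genes."""
    ctrl_ids = list(annot.loc[annot["group"] == "control", "sample_id"])
    if not ctrl_ids:
        raise ValueError("annotation contains no control samples")
    ctrl_expr = expr.submatrix(samples=ctrl_ids)
    case_by_group: dict[str, _core.Functionome] = {}
    control_by_group: dict[str, _core.Functionome] = {}
    log: dict = {"n_controls": len(ctrl_ids), "pairings": []}
    for stage in stage_order:
        stage_annot = annot.loc[annot["group"] == stage]
        if stage_annot.empty:
            raise ValueError(f"annotation contains no samples for {stage!r}")
        case_frames = []
        ctrl_stack = []
        ctrl_scored_ids: list[str] | None = None
        for ds, sub in stage_annot.groupby("dataset_id"):
            ids = list(sub["sample_id"])
            case_expr = expr.submatrix(samples=ids)
            case_fn, ctrl_fn = _core.reconstruct_functionome(
                case_expr, ctrl_expr, collection,
                control_scoring=control_scoring)
            case_frames.append(case_fn.to_frame())
            ctrl_stack.append(ctrl_fn.gsr)
            ctrl_scored_ids = list(ctrl_fn.sample_ids)
            log["pairings"].append({
                "group": stage, "dataset": str(ds), "n_cases": len(ids),
                "n_common_genes": len(set(case_expr.gene_ids)
                                      & set(ctrl_expr.gene_ids)),
                "n_sets_skipped": len(case_fn.skipped_sets),
            })
        case_df = pd.concat(case_frames, axis=0)
        case_by_group[stage] = _core.Functionome.from_frame(case_df)
        with np.errstate(invalid="ignore"):
            mean_ctrl = np.nanmean(np.stack(ctrl_stack, axis=0), axis=0)
        control_by_group[stage] = _core.Functionome(
            ctrl_scored_ids, collection.set_ids, mean_ctrl)
    return FunctionomeBundle(case_by_group=case_by_group,
                             control_by_group=control_by_group, log=log)


def run_functionome(config: PipelineConfig) -> FunctionomeBundle:
    """Stage 1: reconstruct and write per-group functionomes."""
    expr, annot, collection = _load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = build_functionomes(expr, annot, collection,
                                stage_order=config.stage_order,
                                control_scoring=config.control_scoring)
    for stage, fn in bundle.case_by_group.items():
        fn.write_tsv(out / f"functionome_{stage}.tsv")
    next(iter(bundle.control_by_group.values())).write_tsv(
        out / "functionome_control.tsv")
    skipped = {s: r for fn in bundle.case_by_group.values()
               for s, r in fn.skipped_sets.items()}
    (out / "skipped_sets.json").write_text(
        json.dumps(skipped, indent=2) + "\n", encoding="utf-8")
    (out / "run_log.json").write_text(
        json.dumps(bundle.log, indent=2) + "\n", encoding="utf-8")
    return bundle


def _immuno_subset(bundle: FunctionomeBundle, dag: _go.GoDag, mapping,
                   ancestors: Sequence[str]) -> tuple[FunctionomeBundle, set[str]]:
    offspring = dag.offspring(list(ancestors))
    case = {g: _core.extract_immunofunctionome(fn, mapping, offspring)
            for g, fn in bundle.case_by_group.items()}
    ctrl = {g: _core.extract_immunofunctionome(fn, mapping, offspring)
            for g, fn in bundle.control_by_group.items()}
    return FunctionomeBundle(case, ctrl, dict(bundle.log)), offspring


def _group_means(bundle: FunctionomeBundle,
                 stage_order: Sequence[str]) -> pd.DataFrame:
    from scipy.stats import mannwhitneyu

    rows = []
    for g in stage_order:
        case = bundle.case_by_group[g].gsr
        ctrl = bundle.control_by_group[g].gsr
        cvals = case[np.isfinite(case)]
        nvals = ctrl[np.isfinite(ctrl)]
        p = mannwhitneyu(np.nanmean(case, axis=1), np.nanmean(ctrl, axis=1),
                         alternative="two-sided").pvalue
        rows.append({"group": g,
                     "case_mean": cvals.mean(), "case_sd": cvals.std(ddof=1),
                     "control_mean": nvals.mean(), "control_sd": nvals.std(ddof=1),
                     "p_value": float(p)})
    df = pd.DataFrame(rows)
    df["corrected_case_mean"] = _core.corrected_group_means(
        df["case_mean"].to_numpy(), df["control_mean"].to_numpy())
    return df[["group", "case_mean", "case_sd", "control_mean", "control_sd",
               "corrected_case_mean", "p_value"]]


def run_full(config: PipelineConfig) -> dict:
    """Run the whole workflow; returns a manifest of written artifacts.

    On a stage failure the bundle is marked partial and the failed stage
    recorded, but everything computed up to that point is kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"status": "complete", "artifacts": [], "failed_stage": None}

    def emit(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    stage = "inputs"
    try:
        if not config.obo:
            raise ValueError(
                "immunofunctionome extraction requires an OBO ontology; "
                "set 'obo' in the config")
        expr, annot, collection = _load_inputs(config)
        dag = _go.read_obo(config.obo)
        explicit = (_go.read_term_mapping(config.mapping)
                    if config.mapping else None)
        mapping = (_go.map_collection_to_terms(collection, dag, explicit)
                   if dag is not None else None)

        stage = "functionome"
        bundle = build_functionomes(expr, annot, collection,
                                    stage_order=config.stage_order,
                                    control_scoring=config.control_scoring)
        for g, fn in bundle.case_by_group.items():
            fn.write_tsv(emit(f"functionome_{g}.tsv"))
        next(iter(bundle.control_by_group.values())).write_tsv(
            emit("functionome_control.tsv"))
        (emit("run_log.json")).write_text(
            json.dumps(bundle.log, indent=2) + "\n", encoding="utf-8")
        _group_means(bundle, config.stage_order).to_csv(
            emit("group_means.tsv"), sep="\t", index=False, lineterminator="\n")

        stage = "immunofunctionome"
        if dag is None:
            raise ValueError("immunofunctionome requested but no OBO configured")
        immuno, offspring = _immuno_subset(bundle, dag, mapping,
                                           config.ancestors)
        (emit("offspring.txt")).write_text(
            "\n".join(sorted(offspring)) + "\n", encoding="utf-8")
        gm_imm = _group_means(immuno, config.stage_order)
        gm_imm.to_csv(emit("group_means_immuno.tsv"), sep="\t", index=False,
                      lineterminator="\n")

        stage = "deregulation"
        table = _stats.deregulation_table(immuno.case_by_group,
                                          immuno.control_by_group)
        table.to_csv(emit("deregulation.tsv"), sep="\t", index=False,
                     lineterminator="\n")
        tops = {g: _stats.top_k(table, g, config.k_top)
                for g in config.stage_order}
        table_top = pd.concat([
            table.loc[(table["group"] == g)
                      & table["set_id"].isin(tops[g][:config.k_table])]
            .sort_values("rank") for g in config.stage_order])
        table_top.to_csv(emit(f"top_{config.k_table}.tsv"), sep="\t",
                         index=False, lineterminator="\n")

        stage = "venn"
        venn = _stats.common_deregulated(tops, k=config.k_top)
        (emit("venn.json")).write_text(
            json.dumps(venn.to_json_dict(), indent=2) + "\n", encoding="utf-8")

        stage = "progressive"
        progressive = _stats.progressive_filter(table, config.stage_order,
                                                alpha=config.alpha)
        (emit("progressive.txt")).write_text(
            "\n".join(progressive) + ("\n" if progressive else ""),
            encoding="utf-8")

        stage = "core_auxiliary"
        core = _stats.extract_core_auxiliary(
            venn.common, progressive, dag, mapping,
            tau=config.tau, min_depth=config.min_depth)
        (emit("core_auxiliary.json")).write_text(
            json.dumps(core.to_json_dict(), indent=2) + "\n", encoding="utf-8")

        stage = "classification"
        reports = {}
        for g in config.stage_order:
            X, y = _stack_features(immuno, g)
            for k in config.cv_k:
                rep = _classify.cv_classify(X, y, k=k, repeats=config.repeats,
                                            seed=config.seed)
                reports[f"{g}_vs_control_k{k}"] = rep.to_json_dict()
        Xm, ym = _stack_multiclass(immuno, config.stage_order)
        for k in config.cv_k:
            rep = _classify.cv_classify(Xm, ym, k=k, repeats=config.repeats,
                                        seed=config.seed)
            reports[f"multiclass_k{k}"] = rep.to_json_dict()
        (emit("classification.json")).write_text(
            json.dumps(reports, indent=2) + "\n", encoding="utf-8")

        stage = "dendrogram"
        profiles = {}
        finite_cols = None
        for g in config.stage_order:
            m = np.nanmean(immuno.case_by_group[g].gsr, axis=0)
            profiles[g] = m
            ok = np.isfinite(m)
            finite_cols = ok if finite_cols is None else (finite_cols & ok)
        profiles = {g: v[finite_cols] for g, v in profiles.items()}
        dend = _classify.cluster_group_profiles(profiles)
        (emit("dendrogram.newick")).write_text(dend.to_newick() + "\n",
                                               encoding="utf-8")

        if config.plots:
            stage = "plots"
            _write_histograms(immuno, config.stage_order, out, manifest)
    except Exception as exc:  # noqa: BLE001 - surfaced with the stage name
        manifest["status"] = "partial"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.error("pipeline failed at stage %s: %s", stage, exc)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest


def _stack_features(bundle: FunctionomeBundle, group: str,
                    ) -> tuple[np.ndarray, list[str]]:
    case = bundle.case_by_group[group]
    ctrl = bundle.control_by_group[group]
    X = np.vstack([case.gsr, ctrl.gsr])
    y = [group] * len(case.sample_ids) + ["control"] * len(ctrl.sample_ids)
    return X, y


def _stack_multiclass(bundle: FunctionomeBundle, stage_order: Sequence[str],
                      ) -> tuple[np.ndarray, list[str]]:
    Xs, y = [], []
    for g in stage_order:
        fn = bundle.case_by_group[g]
        Xs.append(fn.gsr)
        y.extend([g] * len(fn.sample_ids))
    return np.vstack(Xs), y


def _write_histograms(bundle: FunctionomeBundle, stage_order: Sequence[str],
                      out: Path, manifest: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for g in stage_order:
        case = bundle.case_by_group[g].gsr
        ctrl = bundle.control_by_group[g].gsr
        fig, ax = plt.subplots(figsize=(5, 3.2))
        bins = np.linspace(0, 1, 41)
        ax.hist(ctrl[np.isfinite(ctrl)], bins=bins, density=True, alpha=0.6,
                label="control", color="tab:blue")
        ax.hist(case[np.isfinite(case)], bins=bins, density=True, alpha=0.6,
                label=g, color="tab:red")
        ax.set_xlabel("GSR index")
        ax.set_ylabel("density")
        ax.legend(frameon=False)
        fig.tight_layout()
        name = f"hist_{g}.png"
        fig.savefig(out / name, dpi=110)
        plt.close(fig)
        manifest["artifacts"].append(name)
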