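"""The gene-set regularity (GSR) index and functionome reconstruction.

For each gene set, the normal-control cohort defines a *rank template*:
for every unordered pair of member genes, the majority ordering of their
expression values across control samples. A sample's GSR index for the
set is the fraction of template pairs whose ordering the sample
reproduces — 1 means the sample's within-set expression ordering is
fully conserved relative to the control consensus, 0 means it is fully
reversed. Assembling the indices over a whole gene-set collection gives
the sample's functionome; restricting the columns to immune-related
ontology offspring gives the immunofunctionome.

This is a single-template variant of differential rank conservation
(DIRAC) scoring: one template, built from controls only, against which
both case and control samples are scored. Control samples can be scored
leave-one-out (the default) so that their scores are out-of-sample like
the cases', or in-sample against the full-cohort template.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from gsrpipe.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)


class SetSkipped(ValueError):
    """Gene set cannot be scored against this matrix (too few genes)."""

    def __init__(self, set_id: str, reason: str):
        self.set_id = set_id
        self.reason = reason
        super().__init__(f"{set_id}: {reason}")


def to_ranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n of an expression vector, average ranks on ties."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("expected a 1-d vector of length >= 2")
    return rankdata(v, method="average")


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row indices (i, j) of all unordered pairs i<j in canonical order."""
    idx = np.array(list(itertools.combinations(range(n), 2)), dtype=int)
    return idx[:, 0], idx[:, 1]


@dataclass
class RankTemplate:
    """Majority pairwise ordering of a gene set across the control cohort.

    ``genes_used`` is the lexicographically sorted intersection of the set
    with the matrix; ``pair_order[k]`` is True iff gene_i ranks strictly
    below gene_j in a majority of control samples, for the k-th pair
    (i < j) in canonical combination order; ``support[k]`` is the fraction
    of controls agreeing with the majority (in [0.5, 1]).
    """

    set_id: str
    genes_used: list[str]
    pair_order: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genes_used)
        n_pairs = n * (n - 1) // 2
        if n < 2:
            raise ValueError("template needs >= 2 genes")
        if len(self.pair_order) != n_pairs or len(self.support) != n_pairs:
            raise ValueError("pair arrays do not match C(n,2)")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_order)


def _pair_less(values: np.ndarray) -> np.ndarray:
    """Boolean (n_pairs x n_samples): value_i < value_j per canonical pair.

    Strict comparison: a tie never counts as "<", mirroring how average
    ranks leave tied genes unordered.
    """
    i, j = _pair_index(values.shape[0])
    return values[i, :] < values[j, :]


def build_rank_template(expr: ExpressionMatrix, control_ids: Sequence[str],
                        gene_set: GeneSet) -> RankTemplate:
    """Majority pairwise ordering of *gene_set* over the control samples.

    An exact 50/50 split on a pair is resolved deterministically in favor
    of the lexicographically first gene ranking lower.
    """
    if len(control_ids) == 0:
        raise ValueError("no control samples")
    genes = sorted(set(gene_set.members) & set(expr.gene_ids))
    if len(genes) < 2:
        raise SetSkipped(gene_set.set_id, "too_few_genes")
    sub = expr.submatrix(genes=genes, samples=list(control_ids))
    less = _pair_less(sub.values)  # pairs x controls
    n = less.shape[1]
    count = less.sum(axis=1)
    pair_order = count * 2 >= n  # ties (count == n/2) resolve to True
    support = np.maximum(count, n - count) / n
    return RankTemplate(gene_set.set_id, genes, pair_order, support)


def gsr_index(sample_values: Mapping[str, float] | Sequence[float],
              template: RankTemplate) -> float:
    """Fraction of template pairs matched by one sample's expression values.

    ``sample_values`` is either a gene -> value mapping covering
    ``template.genes_used`` or a vector aligned with it. A tied pair in the
    sample counts as a mismatch of a strict "<" template entry and as a
    match of a ">=" entry.
    """
    if isinstance(sample_values, Mapping):
        try:
            v = np.array([float(sample_values[g]) for g in template.genes_used])
        except KeyError as e:
            raise ValueError(f"sample lacks a value for gene {e.args[0]!r}") from e
    else:
        v = np.asarray(sample_values, dtype=float)
        if v.shape != (len(template.genes_used),):
            raise ValueError("value vector does not align with template genes")
    less = _pair_less(v[:, None])[:, 0]
    return float((less == template.pair_order).mean())


def _score_matrix(values: np.ndarray, pair_order: np.ndarray) -> np.ndarray:
    """GSR index of every column of a (genes_used x samples) value matrix."""
    less = _pair_less(values)
    return (less == pair_order[:, None]).mean(axis=0)


def _score_controls_loo(values: np.ndarray) -> np.ndarray:
    """Leave-one-out GSR of control columns: each control is scored against
    the majority template of the other n-1 controls (50/50 -> True)."""
    less = _pair_less(values)  # pairs x n
    n = less.shape[1]
    if n == 1:
        return np.ones(1)
    count = less.sum(axis=1, keepdims=True)
    loo_order = (count - less) * 2 >= (n - 1)
    return (less == loo_order).mean(axis=0)


@dataclass
class Functionome:
    """Samples x gene-sets matrix of GSR indices (NaN = set skipped)."""

    sample_ids: list[str]
    set_ids: list[str]
    gsr: np.ndarray
    skipped_sets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gsr = np.asarray(self.gsr, dtype=float)
        if self.gsr.shape != (len(self.sample_ids), len(self.set_ids)):
            raise ValueError("gsr shape does not match ids")
        finite = self.gsr[np.isfinite(self.gsr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("GSR indices must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gsr, index=self.sample_ids, columns=self.set_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   skipped: dict[str, str] | None = None) -> "Functionome":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float), skipped or {})

    def subset_sets(self, set_ids: Sequence[str]) -> "Functionome":
        keep = [s for s in self.set_ids if s in set(set_ids)]
        cols = [self.set_ids.index(s) for s in keep]
        return Functionome(self.sample_ids, keep, self.gsr[:, cols],
                           {k: v for k, v in self.skipped_sets.items() if k in keep})

    def subset_samples(self, sample_ids: Sequence[str]) -> "Functionome":
        rows = [self.sample_ids.index(s) for s in sample_ids]
        return Functionome(list(sample_ids), self.set_ids, self.gsr[rows, :],
                           dict(self.skipped_sets))

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", na_rep="NA",
                               lineterminator="\n")


def reconstruct_functionome(case_expr: ExpressionMatrix,
                            control_expr: ExpressionMatrix,
                            collection: GeneSetCollection,
                            control_scoring: str = "split",
                            min_genes: int = 2,
                            ) -> tuple[Functionome, Functionome]:
    """Score case and control samples against control-derived rank
    templates for all sets in *collection*.

    Each set is restricted to its members present in the genes common to
    the case/control pair; sets left with fewer than *min_genes* common
    genes get an all-NaN column and an entry in ``skipped_sets``.

    ``control_scoring`` selects how the control arm is handled:

    ``"split"`` (default)
        The control cohort is split deterministically (even positions
        build the template, odd positions are scored); cases and the
        scored controls are both out-of-sample against the *same*
        template, so under the null the two arms are exchangeable and
        per-set Mann-Whitney p-values are calibrated. The returned
        control functionome covers the scored half only.
    ``"loo"``
        Template from all controls; each control rescored leave-one-out.
        Removes the mean optimism but the two arms see slightly
        different templates, which overdisperses per-set differences.
    ``"insample"``
        Template from all controls; controls scored against it as-is.
        Control scores are optimistically biased — descriptive use only.
    """
    if control_scoring not in ("split", "loo", "insample"):
        raise ValueError("control_scoring must be 'split', 'loo' or 'insample'")
    common = sorted(set(case_expr.gene_ids) & set(control_expr.gene_ids))
    if not common:
        raise ValueError("case and control matrices share no genes")
    n_case, n_ctrl = len(case_expr.sample_ids), len(control_expr.sample_ids)
    if control_scoring == "split" and n_ctrl < 2:
        raise ValueError("split control scoring needs >= 2 control samples")
    if control_scoring == "split":
        tmpl_idx = np.arange(0, n_ctrl, 2)
        score_idx = np.arange(1, n_ctrl, 2)
        ctrl_out_ids = [control_expr.sample_ids[i] for i in score_idx]
    else:
        tmpl_idx = np.arange(n_ctrl)
        score_idx = np.arange(n_ctrl)
        ctrl_out_ids = list(control_expr.sample_ids)
    case_gsr = np.full((n_case, len(collection)), np.nan)
    ctrl_gsr = np.full((len(score_idx), len(collection)), np.nan)
    skipped: dict[str, str] = {}
    common_set = set(common)
    for k, gs in enumerate(collection):
        genes = sorted(gs.members & common_set)
        if len(genes) < min_genes:
            skipped[gs.set_id] = "too_few_genes"
            continue
        ctrl_vals = control_expr.values[control_expr.gene_rows(genes), :]
        case_vals = case_expr.values[case_expr.gene_rows(genes), :]
        less_tmpl = _pair_less(ctrl_vals[:, tmpl_idx])
        pair_order = less_tmpl.sum(axis=1) * 2 >= len(tmpl_idx)
        case_gsr[:, k] = _score_matrix(case_vals, pair_order)
        if control_scoring == "loo":
            ctrl_gsr[:, k] = _score_controls_loo(ctrl_vals)
        else:  # split and insample both score against the built template
            ctrl_gsr[:, k] = _score_matrix(ctrl_vals[:, score_idx], pair_order)
    if skipped:
        logger.info("skipped %d/%d sets (too few common genes)",
                    len(skipped), len(collection))
    ids = collection.set_ids
    return (Functionome(list(case_expr.sample_ids), ids, case_gsr, dict(skipped)),
            Functionome(ctrl_out_ids, ids, ctrl_gsr, dict(skipped)))


def extract_immunofunctionome(functionome: Functionome, term_mapping,
                              offspring_ids: Iterable[str]) -> Functionome:
    """Column subset of a functionome whose mapped ontology term lies in
    *offspring_ids* (column order preserved)."""
    offspring = set(offspring_ids)
    mapping = term_mapping.mapping if hasattr(term_mapping, "mapping") else term_mapping
    keep = [s for s in functionome.set_ids
            if s in mapping and mapping[s] in offspring]
    if not keep:
        raise ValueError(
            "no functionome column maps into the requested offspring set; "
            "check the term mapping and ancestor ids"
        )
    return functionome.subset_sets(keep)


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------


def corrected_group_means(raw_case_means: Sequence[float],
                          control_means: Sequence[float]) -> np.ndarray:
    """Rescale per-group case mean GSR by the control groups' averages.

    Each stage group is scored against a control cohort whose effective
    gene universe can differ slightly (platform-dependent), shifting the
    control baseline; the correction multiplies each raw case mean by
    (grand mean of control means) / (that group's control mean), making
    the groups comparable::

        corrected_g = raw_g * mean(controls) / control_g
    """
    raw = np.asarray(raw_case_means, dtype=float)
    ctrl = np.asarray(control_means, dtype=float)
    if raw.shape != ctrl.shape:
        raise ValueError("per-group vectors differ in length")
    if np.any(ctrl <= 0):
        raise ValueError("control means must be positive")
    return raw * ctrl.mean() / ctrl


def sc_control_ratio(case_mean_per_set: Sequence[float],
                     control_mean_per_set: Sequence[float]) -> np.ndarray:
    """Per-set case/control mean GSR ratio; < 1 indicates deregulation.
    A zero control mean yields NaN with a warning rather than an error."""
    case = np.asarray(case_mean_per_set, dtype=float)
    ctrl = np.asarray(control_mean_per_set, dtype=float)
    if case.shape != ctrl.shape:
        raise ValueError("per-set vectors differ in length")
    out = np.full_like(case, np.nan, dtype=float)
    ok = ctrl > 0
    if not ok.all():
        logger.warning("%d set(s) with zero control mean -> ratio NA", (~ok).sum())
    out[ok] = case[ok] / ctrl[ok]
    return out


def group_means_table(case_fn: Functionome, control_fn: Functionome,
                      groups: Mapping[str, str],
                      group_order: Sequence[str]) -> pd.DataFrame:
    """Per-stage summary of total GSR indices (Table-1 shape): case mean/SD,
    control mean/SD, corrected case mean, and a Mann-Whitney p-value on the
    pooled per-sample mean GSR.

    *groups* maps case sample_id -> group label; all control samples serve
    every group. Means are over all finite GSR entries of the group's
    samples; the p-value compares per-sample mean GSR between arms.
    """
    from scipy.stats import mannwhitneyu

    ctrl_vals = control_fn.gsr[np.isfinite(control_fn.gsr)]
    ctrl_sample_means = np.nanmean(control_fn.gsr, axis=1)
    rows = []
    for g in group_order:
        ids = [s for s in case_fn.sample_ids if groups.get(s) == g]
        if not ids:
            raise ValueError(f"no case samples in group {g!r}")
        sub = case_fn.subset_samples(ids)
        vals = sub.gsr[np.isfinite(sub.gsr)]
        case_sample_means = np.nanmean(sub.gsr, axis=1)
        p = mannwhitneyu(case_sample_means, ctrl_sample_means,
                         alternative="two-sided").pvalue
        rows.append({
            "group": g,
            "case_mean": vals.mean(), "case_sd": vals.std(ddof=1),
            "control_mean": ctrl_vals.mean(), "control_sd": ctrl_vals.std(ddof=1),
            "p_value": p,
        })
    df = pd.DataFrame(rows)
    df["corrected_case_mean"] = corrected_group_means(
        df["case_mean"].to_numpy(), df["control_mean"].to_numpy())
    return df[["group", "case_mean", "case_sd", "control_mean", "control_sd",
               "corrected_case_mean", "p_value"]]
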