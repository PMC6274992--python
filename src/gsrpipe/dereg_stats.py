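"""Staged deregulation inference over functionome columns.

Per gene set and stage group: Mann-Whitney U comparison of case vs
control GSR indices, Benjamini-Hochberg FDR correction, deterministic
p-value ranking, top-k intersection across the four stage groups (full
Venn partition), progressive-deregulation filtering on the case/control
ratio, and extraction of core vs auxiliary ontology terms by semantic
similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from gsrpipe.go_dag import GoDag
from gsrpipe.gsr_core import Functionome, sc_control_ratio

logger = logging.getLogger(__name__)


def mann_whitney_per_set(case_gsr: Sequence[float],
                         control_gsr: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value for one gene set's case vs control
    GSR indices.

    NaN observations are dropped per arm; an arm left empty yields NaN
    with a warning. The exact null distribution is used when both arms
    have <= 8 observations and no ties straddle them; otherwise the
    normal approximation with tie and continuity correction.
    """
    case = np.asarray(case_gsr, dtype=float)
    ctrl = np.asarray(control_gsr, dtype=float)
    case = case[np.isfinite(case)]
    ctrl = ctrl[np.isfinite(ctrl)]
    if case.size == 0 or ctrl.size == 0:
        logger.warning("empty arm after NA removal -> p = NA")
        return float("nan")
    if np.all(case == case[0]) and np.all(ctrl == ctrl[0]) and case[0] == ctrl[0]:
        return 1.0  # all observations identical: no evidence either way
    method = "auto"  # exact for small tie-free arms, else corrected normal
    return float(mannwhitneyu(case, ctrl, alternative="two-sided",
                              method=method).pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1.

    NaN p-values propagate to NaN q-values and do not count toward the
    number of tests m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return q
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def deregulation_table(case_fn_by_group: Mapping[str, Functionome],
                       control_fn_by_group: Mapping[str, Functionome],
                       ) -> pd.DataFrame:
    """Per-set, per-group deregulation statistics.

    For every group: per-set case mean, control mean, case/control ratio,
    two-sided Mann-Whitney p, BH q (within group), and deterministic rank
    (ascending p, ties broken by larger deviation of the ratio from 1,
    then set id).
    """
    frames = []
    for group, case_fn in case_fn_by_group.items():
        ctrl_fn = control_fn_by_group[group]
        if case_fn.set_ids != ctrl_fn.set_ids:
            raise ValueError(f"group {group!r}: case/control set ids differ")
        case_mean = np.nanmean(
            np.where(np.isfinite(case_fn.gsr), case_fn.gsr, np.nan), axis=0)
        ctrl_mean = np.nanmean(
            np.where(np.isfinite(ctrl_fn.gsr), ctrl_fn.gsr, np.nan), axis=0)
        p = np.array([
            mann_whitney_per_set(case_fn.gsr[:, k], ctrl_fn.gsr[:, k])
            if np.isfinite(case_fn.gsr[:, k]).any() else np.nan
            for k in range(len(case_fn.set_ids))
        ])
        df = pd.DataFrame({
            "set_id": case_fn.set_ids,
            "group": group,
            "case_mean": case_mean,
            "control_mean": ctrl_mean,
            "ratio": sc_control_ratio(case_mean, ctrl_mean),
            "p_value": p,
            "q_value": bh_fdr(p),
        })
        df["rank"] = _rank_order(df)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _rank_order(df: pd.DataFrame) -> np.ndarray:
    """1-based rank: ascending p, then larger |1 - ratio|, then set_id.
    NaN p-values rank last."""
    key = pd.DataFrame({
        "p": df["p_value"].fillna(np.inf),
        "dev": -(1.0 - df["ratio"]).abs().fillna(-np.inf),
        "set_id": df["set_id"],
    })
    order = key.sort_values(["p", "dev", "set_id"], kind="mergesort").index
    rank = np.empty(len(df), dtype=int)
    rank[np.asarray(order)] = np.arange(1, len(df) + 1)
    return rank


def rank_deregulated(table: pd.DataFrame, group: str) -> list[str]:
    """Set ids of *group* ordered by the deterministic p-value ranking."""
    sub = table.loc[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    return list(sub.sort_values("rank")["set_id"])


def top_k(table: pd.DataFrame, group: str, k: int) -> list[str]:
    """First *k* set ids of the group's ranking (whole list if shorter)."""
    ranked = rank_deregulated(table, group)
    if k > len(ranked):
        logger.warning("top_k: k=%d exceeds list length %d; using all",
                       k, len(ranked))
    return ranked[:k]


@dataclass
class VennPartition:
    """Membership-signature partition of several top-k lists.

    ``regions`` maps a signature (tuple of group names whose list contains
    the ids) to the sorted id list of that exclusive region; ``common`` is
    the all-groups region.
    """

    groups: list[str]
    regions: dict[tuple[str, ...], list[str]]

    @property
    def common(self) -> list[str]:
        return self.regions.get(tuple(self.groups), [])

    def sizes(self) -> dict[str, int]:
        return {"+".join(sig): len(ids) for sig, ids in self.regions.items()}

    def to_json_dict(self) -> dict:
        return {
            "groups": self.groups,
            "regions": {"+".join(sig): ids for sig, ids in self.regions.items()},
            "common": self.common,
        }


def common_deregulated(top_lists: Mapping[str, Sequence[str]],
                       k: int = 75) -> VennPartition:
    """Full Venn partition of the groups' top-*k* lists by membership
    signature; the all-groups intersection is the "common" output."""
    groups = list(top_lists)
    truncated: dict[str, set[str]] = {}
    for g, lst in top_lists.items():
        lst = list(lst)
        if k > len(lst):
            logger.warning("group %s: k=%d exceeds list length %d", g, k, len(lst))
        truncated[g] = set(lst[:k])
    universe = set().union(*truncated.values()) if truncated else set()
    regions: dict[tuple[str, ...], list[str]] = {}
    for sid in sorted(universe):
        sig = tuple(g for g in groups if sid in truncated[g])
        regions.setdefault(sig, []).append(sid)
    return VennPartition(groups=groups, regions=regions)


def progressive_filter(table: pd.DataFrame,
                       stage_order: Sequence[str],
                       alpha: float = 0.05,
                       eps: float = 0.0) -> list[str]:
    """Sets significant in every stage whose case/control ratio strictly
    decreases along *stage_order*.

    Keeps set ids with q < *alpha* in all stages and
    ratio_s > ratio_{s+1} + *eps* for each consecutive stage pair. Sets
    with NaN ratio or q in any stage are excluded and logged.
    """
    wide_r = table.pivot(index="set_id", columns="group", values="ratio")
    wide_q = table.pivot(index="set_id", columns="group", values="q_value")
    missing = [s for s in stage_order if s not in wide_r.columns]
    if missing:
        raise ValueError(f"stages absent from table: {missing}")
    r = wide_r[list(stage_order)].to_numpy(dtype=float)
    q = wide_q[list(stage_order)].to_numpy(dtype=float)
    has_na = ~(np.isfinite(r).all(axis=1) & np.isfinite(q).all(axis=1))
    if has_na.any():
        logger.info("progressive_filter: %d set(s) excluded for NA", has_na.sum())
    sig = (q < alpha).all(axis=1)
    mono = (r[:, :-1] > r[:, 1:] + eps).all(axis=1)
    keep = sig & mono & ~has_na
    return sorted(wide_r.index[keep])


@dataclass
class CoreAuxiliaryResult:
    """Core clusters (similarity-merged matched terms) and auxiliary terms.

    ``core_clusters`` are single-linkage components of the thresholded
    similarity graph over matched terms; ``core`` is their union;
    ``auxiliary`` are the surviving terms of either input matched to
    nothing in the other; ``excluded_upper_level`` are terms dropped for
    sitting too close to an ontology root.
    """

    core_clusters: list[list[str]]
    auxiliary: list[str]
    excluded_upper_level: list[str]
    similarity: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def core(self) -> list[str]:
        return sorted({t for cl in self.core_clusters for t in cl})

    def to_json_dict(self) -> dict:
        return {
            "core_clusters": self.core_clusters,
            "core": self.core,
            "auxiliary": self.auxiliary,
            "excluded_upper_level": self.excluded_upper_level,
            "similarity": {f"{a}|{b}": s for (a, b), s in self.similarity.items()},
        }


def extract_core_auxiliary(common_set: Sequence[str],
                           progressive_set: Sequence[str],
                           dag: GoDag,
                           term_mapping=None,
                           tau: float = 0.5,
                           min_depth: int = 3) -> CoreAuxiliaryResult:
    """Split deregulated functions into core and auxiliary elements.

    Inputs are the cross-stage common set and the progressive set (gene-set
    ids if *term_mapping* is given, else ontology term ids). Terms with
    depth < *min_depth* are excluded as non-specific upper-level terms.
    Core elements are terms of one input matched to a term of the other
    (identical, or ancestor-closure Jaccard similarity >= *tau*), merged
    into clusters by single linkage over the thresholded similarity graph;
    auxiliary elements are the remaining terms of the symmetric difference
    of the match relation.
    """
    def to_terms(ids: Sequence[str]) -> list[str]:
        if term_mapping is None:
            return list(dict.fromkeys(ids))
        mapping = (term_mapping.mapping if hasattr(term_mapping, "mapping")
                   else term_mapping)
        return list(dict.fromkeys(mapping[s] for s in ids if s in mapping))

    common_terms = to_terms(common_set)
    progressive_terms = to_terms(progressive_set)
    if not common_terms and not progressive_terms:
        logger.warning("extract_core_auxiliary: both inputs empty")
        return CoreAuxiliaryResult([], [], [])

    excluded = sorted({t for t in set(common_terms) | set(progressive_terms)
                       if dag.depth(t) < min_depth})
    common_terms = [t for t in common_terms if t not in set(excluded)]
    progressive_terms = [t for t in progressive_terms if t not in set(excluded)]

    sims: dict[tuple[str, str], float] = {}
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    edges: list[tuple[str, str]] = []
    for a in common_terms:
        for b in progressive_terms:
            s = 1.0 if a == b else dag.semantic_similarity(a, b)
            sims[(a, b)] = s
            if s >= tau:
                matched_a.add(a)
                matched_b.add(b)
                if a != b:
                    edges.append((a, b))

    # single-linkage clusters = connected components of the match graph
    core_nodes = matched_a | matched_b
    parent = {t: t for t in core_nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for t in core_nodes:
        comps.setdefault(find(t), []).append(t)
    core_clusters = sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])

    auxiliary = sorted((set(common_terms) - matched_a)
                       | (set(progressive_terms) - matched_b))
    return CoreAuxiliaryResult(core_clusters=core_clusters, auxiliary=auxiliary,
                               excluded_upper_level=excluded, similarity=sims)
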