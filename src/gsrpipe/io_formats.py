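"""Readers and writers for the text formats the pipeline touches.

GMT gene-set collections, genes x samples expression tables and sample
annotation tables, plus the validation rules applied on ingest: gene
symbols are matched case-insensitively (normalized to uppercase), and
expression profiles containing missing data are discarded — expression
values enter the analysis only through their within-sample ordering, so
the readers apply no scale normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (bad line, non-numeric cell, duplicate id)."""


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: accession/name, human-readable label, member symbols."""

    set_id: str
    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets with unique ids."""

    sets: list[GeneSet]
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate set ids: {sorted(dupes)}")
        self._by_id = {s.set_id: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._by_id[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._by_id

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>member1<TAB>member2...``.

    Member symbols are uppercased and deduplicated; empty member fields are
    dropped. Lines with fewer than three fields and duplicate set names are
    errors.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, label = fields[0], fields[1]
            if name in seen:
                raise FormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            seen.add(name)
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise FormatError(f"{path.name}:{lineno}: set {name!r} has no members")
            sets.append(GeneSet(set_id=name, label=label, members=members))
    return GeneSetCollection(sets=sets, source_tag=path.name)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members emitted in sorted order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.label, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression matrix.

    Invariants enforced on construction: unique gene symbols (uppercased),
    unique sample ids, no missing values, at least one gene and one sample.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = [g.upper() for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 1:
            raise ValueError("expression matrix needs >=1 gene and >=1 sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            raise ValueError(
                f"duplicate gene symbols: {sorted(set(dupes[dupes.duplicated()]))}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_rows(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices for *genes* (must all be present)."""
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def submatrix(self, genes: Sequence[str] | None = None,
                  samples: Sequence[str] | None = None) -> "ExpressionMatrix":
        g = list(genes) if genes is not None else self.gene_ids
        s = list(samples) if samples is not None else self.sample_ids
        rows = self.gene_rows(g)
        cols = np.array([self.sample_ids.index(x) for x in s], dtype=int)
        return ExpressionMatrix(g, s, self.values[np.ix_(rows, cols)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


def read_expression(path: str | Path,
                    missing_policy: str = "drop_samples") -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV (first row sample ids, first
    column gene symbols).

    ``missing_policy`` controls how profiles with missing data are handled:
    ``"drop_samples"`` (default) discards any sample column containing a
    missing cell and logs a warning; ``"strict"`` raises instead.
    Non-numeric cells and duplicate gene symbols are always errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.upper()
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path.name}: duplicate gene symbols {dupes}")
    # locate non-numeric cells before coercion so the error names coordinates
    numeric = df.apply(pd.to_numeric, errors="coerce")
    stripped = df.apply(lambda s: s.str.strip())
    bad = numeric.isna() & stripped.notna() & (stripped != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path.name}: non-numeric value {df.iloc[r, c]!r} at "
            f"gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    missing_cols = numeric.columns[numeric.isna().any(axis=0)]
    dropped: list[str] = []
    if len(missing_cols) > 0:
        if missing_policy == "strict":
            raise FormatError(
                f"{path.name}: missing data in samples {list(missing_cols)}"
            )
        dropped = [str(c) for c in missing_cols]
        logger.warning(
            "%s: discarding %d sample profile(s) with missing data: %s",
            path.name, len(dropped), dropped,
        )
        numeric = numeric.drop(columns=missing_cols)
        if numeric.shape[1] == 0:
            raise FormatError(f"{path.name}: all samples contained missing data")
    em = ExpressionMatrix(
        list(numeric.index), [str(c) for c in numeric.columns],
        numeric.to_numpy(dtype=float),
    )
    em.dropped_samples = dropped
    return em


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(Path(path), sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# Sample annotations
# ---------------------------------------------------------------------------

DEFAULT_GROUPS = ("control", "stageI", "stageII", "stageIII", "stageIV")


def read_annotation(path: str | Path,
                    allowed_groups: Iterable[str] = DEFAULT_GROUPS) -> pd.DataFrame:
    """Read a sample annotation TSV with columns ``sample_id``, ``group``,
    ``dataset_id`` (``platform_id`` optional); returns a frame indexed by
    sample_id. Unknown group labels are rejected against *allowed_groups*.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "dataset_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise FormatError(f"{path.name}: duplicate sample ids {dupes}")
    allowed = set(allowed_groups)
    bad = df.loc[~df["group"].isin(allowed)]
    if len(bad) > 0:
        rows = ", ".join(f"{r.sample_id}={r.group!r}" for r in bad.itertuples())
        raise FormatError(
            f"{path.name}: unknown group labels (allowed {sorted(allowed)}): {rows}"
        )
    return df.set_index("sample_id", drop=False)


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(Path(path), sep="\t", index=False, lineterminator="\n")


@dataclass
class ReconciliationReport:
    """Two-sided difference between annotation and expression sample ids."""

    only_in_annotation: list[str]
    only_in_expression: list[str]

    @property
    def ok(self) -> bool:
        return not self.only_in_annotation and not self.only_in_expression


def reconcile_samples(expr: ExpressionMatrix,
                      annot: pd.DataFrame) -> ReconciliationReport:
    """Report sample ids present on only one side of an expression/annotation
    pair; an empty report means the two agree."""
    e = set(expr.sample_ids)
    a = set(annot["sample_id"])
    return ReconciliationReport(sorted(a - e), sorted(e - a))
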