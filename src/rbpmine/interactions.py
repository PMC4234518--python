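"""Reading, filtering and matrix-building for pairwise trans-factor interactions.

The unit of data is one (trans-factor, target) interaction — a binding event
between a post-transcriptional regulator (an RNA-binding protein or a miRNA)
and an mRNA UTR or gene — optionally carrying the experimental evidence type
(PAR-CLIP, HITS-CLIP, RIP, ...) and the binding-site interval.  Interactions
are assembled into a Boolean targets × factors matrix ``C`` with
``C[i, j] = 1`` iff factor *j* binds target *i*; everything downstream
(cluster mining, enrichment, site classification) consumes that matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Evidence-type groupings used for technique-homogeneous sub-analyses.
#: Tags are matched case-insensitively after trimming.
EVIDENCE_PRESETS: dict[str, frozenset[str]] = {
    "par-clip": frozenset({"par-clip"}),
    "other-clip": frozenset({"clip", "clip-seq", "hits-clip", "iclip"}),
    "rip": frozenset({"rip"}),
}


def _norm_tag(tag: str) -> str:
    return tag.strip().lower()


@dataclass(frozen=True)
class Site:
    """A binding interval, 0-based half-open (BED convention)."""

    sequence_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class InteractionRecord:
    factor_id: str
    target_id: str
    evidence: str = "other"
    site: Site | None = None
    region: str | None = None  # one of {5UTR, 3UTR, gene} when known

    def __post_init__(self) -> None:
        if not self.factor_id or not self.target_id:
            raise ValueError("factor_id and target_id must be non-empty")


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a TSV interaction list.

    ``one_based`` marks 1-based inclusive coordinate dialects, converted to
    0-based half-open at parse time.
    """

    factor: str = "factor"
    target: str = "target"
    evidence: str | None = None
    sequence_id: str | None = None
    start: str | None = None
    end: str | None = None
    region: str | None = None
    one_based: bool = False
    sep: str = "\t"


@dataclass
class ParseReport:
    n_records: int = 0
    n_rejected: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)  # (line, message)


def read_interactions(
    path, dialect: Dialect = Dialect(), report: ParseReport | None = None
) -> list[InteractionRecord]:
    """Read an interaction list from a TSV file.

    One record per non-header line; duplicate (factor, target) pairs are
    preserved (deduplication happens at matrix build).  Malformed lines are
    skipped and reported with their line numbers in ``report``.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, comment="#")
    for col in (dialect.factor, dialect.target):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    has_coords = (
        dialect.sequence_id is not None
        and dialect.start is not None
        and dialect.end is not None
        and dialect.sequence_id in df.columns
    )
    if report is None:
        report = ParseReport()
    records: list[InteractionRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # 1-based, after the header line
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            site = None
            if has_coords and not pd.isna(row[dialect.sequence_id]):
                start = int(row[dialect.start])
                end = int(row[dialect.end])
                if dialect.one_based:
                    start -= 1  # 1-based inclusive -> 0-based half-open
                site = Site(str(row[dialect.sequence_id]), start, end)
            evidence = "other"
            if dialect.evidence and dialect.evidence in row and not pd.isna(row[dialect.evidence]):
                evidence = str(row[dialect.evidence])
            region = None
            if dialect.region and dialect.region in row and not pd.isna(row[dialect.region]):
                region = str(row[dialect.region])
            records.append(
                InteractionRecord(
                    factor_id=str(row[dialect.factor]),
                    target_id=str(row[dialect.target]),
                    evidence=evidence,
                    site=site,
                    region=region,
                )
            )
        except (ValueError, TypeError) as exc:
            report.n_rejected += 1
            report.errors.append((line_no, str(exc)))
    report.n_records = len(records)
    if report.n_rejected:
        logger.warning("rejected %d malformed line(s) in %s", report.n_rejected, path)
    return records


def filter_by_evidence(
    records: Iterable[InteractionRecord], allowed: Iterable[str]
) -> list[InteractionRecord]:
    """Keep records whose evidence tag is in ``allowed`` (case-insensitive)."""
    allowed_norm = {_norm_tag(t) for t in allowed}
    if not allowed_norm:
        raise ValueError("allowed evidence set must be non-empty")
    kept = [r for r in records if _norm_tag(r.evidence) in allowed_norm]
    if not kept:
        logger.warning("evidence filter %s removed every record", sorted(allowed_norm))
    return kept


def filter_by_expression(
    records: Iterable[InteractionRecord],
    expressed_targets: Iterable[str] | None = None,
    expressed_factors: Iterable[str] | None = None,
) -> list[InteractionRecord]:
    """Keep interactions whose target and/or factor is in an expressed set.

    Emulates restricting the interaction compendium to one biological system
    (e.g. a cell line) given its expressed transcripts and regulators.
    """
    if expressed_targets is None and expressed_factors is None:
        raise ValueError("provide at least one expression filter set")
    tset = set(expressed_targets) if expressed_targets is not None else None
    fset = set(expressed_factors) if expressed_factors is not None else None
    out = []
    for r in records:
        if tset is not None and r.target_id not in tset:
            continue
        if fset is not None and r.factor_id not in fset:
            continue
        out.append(r)
    return out


@dataclass
class InteractionMatrix:
    """Boolean targets × factors interaction matrix with labels.

    Rows and columns are lexicographically sorted so downstream outputs are
    deterministic.
    """

    C: np.ndarray  # bool, shape (n_targets, n_factors)
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=bool)
        if self.C.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")

    @property
    def n_targets(self) -> int:
        return self.C.shape[0]

    @property
    def n_factors(self) -> int:
        return self.C.shape[1]

    def column(self, factor_id: str) -> np.ndarray:
        return self.C[:, self.col_labels.index(factor_id)]

    def targets_of(self, factor_id: str) -> set[str]:
        col = self.column(factor_id)
        return {self.row_labels[i] for i in np.flatnonzero(col)}


def build_matrix(records: Sequence[InteractionRecord]) -> InteractionMatrix:
    """Build the Boolean interaction matrix; duplicates collapse to one 1."""
    if not records:
        raise ValueError("cannot build a matrix from zero records")
    targets = sorted({r.target_id for r in records})
    factors = sorted({r.factor_id for r in records})
    t_index = {t: i for i, t in enumerate(targets)}
    f_index = {f: j for j, f in enumerate(factors)}
    C = np.zeros((len(targets), len(factors)), dtype=bool)
    for r in records:
        C[t_index[r.target_id], f_index[r.factor_id]] = True
    return InteractionMatrix(C, targets, factors)


@dataclass
class MatrixSummary:
    n_targets: int
    n_factors: int
    n_interactions: int
    sparsity: float
    per_factor_targets: dict
    per_target_factors: dict

    @property
    def sparsity_rounded(self) -> float:
        return round(self.sparsity, 2)

    def to_json(self) -> str:
        d = {
            "n_targets": self.n_targets,
            "n_factors": self.n_factors,
            "n_interactions": self.n_interactions,
            "sparsity": self.sparsity,
            "sparsity_rounded": self.sparsity_rounded,
            "per_factor_targets": self.per_factor_targets,
            "per_target_factors": self.per_target_factors,
        }
        return json.dumps(d, indent=2)


def _vector_stats(v: np.ndarray) -> dict:
    return {
        "min": int(v.min()),
        "median": float(np.median(v)),
        "mean": float(v.mean()),
        "max": int(v.max()),
    }


def summarize(matrix: InteractionMatrix) -> MatrixSummary:
    """Interaction counts, sparsity and degree statistics of the matrix."""
    C = matrix.C
    ones = int(C.sum())
    return MatrixSummary(
        n_targets=matrix.n_targets,
        n_factors=matrix.n_factors,
        n_interactions=ones,
        sparsity=ones / (matrix.n_targets * matrix.n_factors),
        per_factor_targets=_vector_stats(C.sum(axis=0)),
        per_target_factors=_vector_stats(C.sum(axis=1)),
    )


# --- matrix round-trip I/O ---------------------------------------------------


def write_edge_list(matrix: InteractionMatrix, path) -> None:
    """Write C as a TSV edge list (factor, target), one line per interaction."""
    rows, cols = np.nonzero(matrix.C)
    df = pd.DataFrame(
        {
            "factor": [matrix.col_labels[j] for j in cols],
            "target": [matrix.row_labels[i] for i in rows],
        }
    ).sort_values(["factor", "target"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> InteractionMatrix:
    records = read_interactions(path, Dialect(factor="factor", target="target"))
    return build_matrix(records)


def write_sparse_triplets(matrix: InteractionMatrix, path) -> None:
    """Write C in MatrixMarket coordinate format (pattern, 1-based indices)."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(path, coo_matrix(matrix.C.astype(np.int8)), field="integer")


def map_targets(
    target_ids: Iterable[str], mapping: Mapping[str, str] | None
) -> set[str]:
    """Map target IDs (e.g. UTR IDs) to gene IDs; identity when no mapping."""
    if mapping is None:
        return set(target_ids)
    return {mapping[t] for t in target_ids if t in mapping}
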