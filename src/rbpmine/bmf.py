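"""Greedy approximate Boolean matrix factorization of interaction matrices.

Given the Boolean targets × factors matrix ``C``, the miner approximates it by
the Boolean product ``S ∘ B`` (addition saturates: 1 + 1 = 1) of a usage
matrix ``S`` (targets × clusters) and a basis matrix ``B`` (clusters ×
factors) minimizing the Hamming error ``|C − S∘B|``.  Each row of ``B`` is a
cluster of trans-factors that co-occur on common targets; clusters may
overlap and are ranked by coverage, the number of interactions they account
for.

Candidate basis rows come from pairwise association scores between factor
columns: the *unbalanced* score of seed *i* with *j* is the shared-target
count normalized by the seed's target count (asymmetric), the *balanced*
score is the cosine similarity of the two columns (symmetric).  A candidate
row collects all factors whose association with the seed is at least τ.
Selection is greedy with a ±1 cover gain: covering an uncovered 1 earns
``w_plus``, covering a 0 costs ``w_minus``.

The two-pass workflow re-mines after removing *recurrent* factors (those
appearing in more than one first-pass cluster), exposing combinations of
*sporadic* factors that the coverage-driven first pass overshadows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionMatrix, summarize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MinerConfig:
    k: int = 25
    tau: float = 0.6
    score_mode: str = "unbalanced"  # or "balanced"
    w_plus: float = 1.0
    w_minus: float = 1.0
    seed: int = 0  # reserved; the default algorithm is deterministic

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ValueError("tau must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.w_plus <= 0 or self.w_minus <= 0:
            raise ValueError("cover-gain weights must be positive")
        if self.score_mode not in ("unbalanced", "balanced"):
            raise ValueError("score_mode must be 'unbalanced' or 'balanced'")


@dataclass
class AssociationMatrix:
    scores: np.ndarray  # (m, m) in [0, 1]
    mode: str
    col_labels: list[str]


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: frozenset[str]
    coverage: int

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class FactorizationResult:
    B: np.ndarray  # bool, (k', m)
    S: np.ndarray  # bool, (n, k')
    clusters: list[Cluster]
    residual_error: int
    col_labels: list[str]
    row_labels: list[str]

    @property
    def k_returned(self) -> int:
        return self.B.shape[0]

    def clusters_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": [c.cluster_id for c in self.clusters],
                "members": [",".join(sorted(c.members)) for c in self.clusters],
                "size": [c.size for c in self.clusters],
                "coverage": [c.coverage for c in self.clusters],
                "is_singleton": [c.is_singleton for c in self.clusters],
            }
        )


def association_scores(C: InteractionMatrix, mode: str = "unbalanced") -> AssociationMatrix:
    """Pairwise factor-association scores from the column inner products.

    unbalanced: score[i, j] = |targets(i) ∩ targets(j)| / |targets(i)|
    balanced:   score[i, j] = |∩| / sqrt(|targets(i)| · |targets(j)|)

    All-zero factor columns get score 0 everywhere (including the diagonal).
    """
    M = C.C.astype(np.float64)
    if M.size == 0:
        raise ValueError("empty interaction matrix")
    inner = M.T @ M  # (m, m) shared-target counts
    deg = np.diag(inner).copy()
    zero = deg == 0
    if zero.any():
        logger.warning("%d factor column(s) have no targets", int(zero.sum()))
    safe = np.where(zero, 1.0, deg)
    if mode == "unbalanced":
        scores = inner / safe[:, None]
    elif mode == "balanced":
        scores = inner / np.sqrt(safe[:, None] * safe[None, :])
    else:
        raise ValueError("mode must be 'unbalanced' or 'balanced'")
    scores[zero, :] = 0.0
    scores[:, zero] = 0.0
    return AssociationMatrix(scores=scores, mode=mode, col_labels=list(C.col_labels))


def candidate_basis(assoc: AssociationMatrix, tau: float) -> np.ndarray:
    """τ-strong association matrix A: A[i, j] = 1 iff score[i, j] >= tau.

    Row *i* is the candidate cluster seeded by factor *i*; factors with at
    least one target keep a diagonal 1 (self-association is exactly 1).
    """
    if not (0 < tau <= 1):
        raise ValueError("tau must be in (0, 1]")
    # small tolerance so a score mathematically equal to tau is never lost
    # to floating-point round-off in the cosine/ratio computation
    return assoc.scores >= tau - 1e-12


def boolean_product(S: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Boolean matrix product with saturating addition (1 + 1 = 1)."""
    S = np.asarray(S, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if S.ndim != 2 or B.ndim != 2 or S.shape[1] != B.shape[0]:
        raise ValueError(f"dimension mismatch: {S.shape} ∘ {B.shape}")
    if S.shape[1] == 0:
        return np.zeros((S.shape[0], B.shape[1]), dtype=bool)
    return (S.astype(np.int64) @ B.astype(np.int64)) > 0


def reconstruction_error(C: np.ndarray, S: np.ndarray, B: np.ndarray) -> int:
    """Hamming distance |C − S∘B|: uncovered ones plus over-covered zeros."""
    C = np.asarray(C, dtype=bool)
    P = boolean_product(S, B)
    if P.shape != C.shape:
        raise ValueError("shape mismatch between C and S∘B")
    return int(np.sum(C != P))


def greedy_factorize(
    C: InteractionMatrix, A: np.ndarray, config: MinerConfig, id_prefix: str = "R"
) -> FactorizationResult:
    """Select up to k candidate basis rows greedily by cover gain.

    At each step every unused candidate row ``a`` of A is scored: the usage
    column sets ``s_i = 1`` iff ``w_plus·(uncovered ones of row i under a)
    − w_minus·(uncovered zeros of row i under a) > 0``; the candidate with
    the maximal total gain is taken (ties: lowest seed index).  Selection
    stops early when the best gain is ≤ 0, so fewer than k clusters may be
    returned.  Coverage is computed per cluster on the final (B, S) and the
    cluster list is sorted by coverage (descending), ties broken by the
    lexicographically smaller member set.
    """
    Cb = C.C.astype(bool)
    A = np.asarray(A, dtype=bool)
    n, m = Cb.shape
    if A.shape != (m, m):
        raise ValueError("candidate matrix A must be m×m for the same C")
    C1 = Cb.astype(np.float64)
    C0 = (~Cb).astype(np.float64)
    covered = np.zeros_like(Cb)
    chosen: list[int] = []
    chosen_rows: list[np.ndarray] = []
    usage_cols: list[np.ndarray] = []
    Af = A.astype(np.float64)
    nonempty = A.any(axis=1)
    for _ in range(config.k):
        U1 = np.where(covered, 0.0, C1)  # uncovered ones
        U0 = np.where(covered, 0.0, C0)  # uncovered (not over-covered) zeros
        # per-row gain of applying each candidate: (n, m_candidates)
        gains = config.w_plus * (U1 @ Af.T) - config.w_minus * (U0 @ Af.T)
        totals = np.where(gains > 0, gains, 0.0).sum(axis=0)
        totals[~nonempty] = -np.inf
        for idx in chosen:  # "unused" = not previously selected verbatim
            dup = (A == A[idx]).all(axis=1)
            totals[dup] = -np.inf
        best = int(np.argmax(totals))  # argmax takes the lowest index on ties
        if not np.isfinite(totals[best]) or totals[best] <= 0:
            break
        chosen.append(best)
        a = A[best]
        chosen_rows.append(a)
        s = gains[:, best] > 0
        usage_cols.append(s)
        covered |= np.outer(s, a)
    if chosen_rows:
        B = np.vstack(chosen_rows)
        S = np.stack(usage_cols, axis=1)
    else:
        B = np.zeros((0, m), dtype=bool)
        S = np.zeros((n, 0), dtype=bool)
    residual = reconstruction_error(Cb, S, B)

    # per-cluster coverage on the final (B, S): ones of C inside the rank-1 block
    order = []
    for l in range(B.shape[0]):
        cov = int(Cb[np.ix_(S[:, l], B[l])].sum())
        members = tuple(sorted(C.col_labels[j] for j in np.flatnonzero(B[l])))
        order.append((-cov, members, l))
    order.sort()
    clusters = []
    perm = []
    for rank, (neg_cov, members, l) in enumerate(order, start=1):
        clusters.append(
            Cluster(
                cluster_id=f"{id_prefix}{rank:02d}",
                members=frozenset(members),
                coverage=-neg_cov,
            )
        )
        perm.append(l)
    B = B[perm] if perm else B
    S = S[:, perm] if perm else S
    return FactorizationResult(
        B=B,
        S=S,
        clusters=clusters,
        residual_error=residual,
        col_labels=list(C.col_labels),
        row_labels=list(C.row_labels),
    )


def mine(
    C: InteractionMatrix, config: MinerConfig, id_prefix: str = "R"
) -> FactorizationResult:
    """association_scores → candidate_basis → greedy_factorize in one call."""
    assoc = association_scores(C, config.score_mode)
    A = candidate_basis(assoc, config.tau)
    return greedy_factorize(C, A, config, id_prefix=id_prefix)


def recurrent_factors(clusters: Iterable[Cluster]) -> set[str]:
    """Factors that appear in more than one cluster (singletons count)."""
    clusters = list(clusters)
    if not clusters:
        raise ValueError("need at least one cluster")
    counts: dict[str, int] = {}
    for c in clusters:
        for f in c.members:
            counts[f] = counts.get(f, 0) + 1
    return {f for f, n in counts.items() if n >= 2}


def count_singletons(clusters: Iterable[Cluster]) -> int:
    return sum(1 for c in clusters if c.is_singleton)


def factor_occurrences(clusters: Iterable[Cluster], factor_id: str) -> int:
    return sum(1 for c in clusters if factor_id in c.members)


def two_pass_mining(
    C: InteractionMatrix, config_pass1: MinerConfig, config_pass2: MinerConfig
) -> tuple[FactorizationResult, FactorizationResult]:
    """Mine, drop recurrent factors, re-mine the sporadic remainder.

    Pass-1 clusters get R-prefixed IDs, pass-2 (sporadic) clusters S-prefixed
    IDs.  Targets left without any interaction after the column removal are
    dropped before pass 2.
    """
    pass1 = mine(C, config_pass1, id_prefix="R")
    recurrent = recurrent_factors(pass1.clusters) if pass1.clusters else set()
    keep_cols = [j for j, f in enumerate(C.col_labels) if f not in recurrent]
    if not keep_cols:
        raise ValueError("every factor is recurrent: nothing left for pass 2")
    C2 = C.C[:, keep_cols]
    keep_rows = np.flatnonzero(C2.any(axis=1))
    if keep_rows.size == 0:
        raise ValueError(
            "all targets lose their interactions after removing recurrent factors"
        )
    reduced = InteractionMatrix(
        C2[keep_rows],
        [C.row_labels[i] for i in keep_rows],
        [C.col_labels[j] for j in keep_cols],
    )
    sporadic = mine(reduced, config_pass2, id_prefix="S")
    return pass1, sporadic


@dataclass
class ParamSurface:
    grid: dict  # (k, tau) -> average cluster size
    selected_tau: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"k": k, "tau": tau, "avg_cluster_size": v}
            for (k, tau), v in sorted(self.grid.items())
        ]
        return pd.DataFrame(rows)


def parameter_surface(
    C: InteractionMatrix,
    k_values: Sequence[int],
    tau_values: Sequence[float],
    mode: str = "unbalanced",
    select_at_k: int | None = None,
) -> ParamSurface:
    """Average cluster size over a (k, τ) grid, plus the τ-selection heuristic.

    The selected τ is the grid value whose average cluster size at
    ``select_at_k`` (default: the largest k in the grid) is closest to the
    mean number of factors bound per target; ties go to the larger τ.
    """
    if not k_values or not tau_values:
        raise ValueError("k and tau grids must be non-empty")
    assoc = association_scores(C, mode)
    grid: dict[tuple[int, float], float] = {}
    for tau in tau_values:
        A = candidate_basis(assoc, tau)
        for k in k_values:
            res = greedy_factorize(C, A, MinerConfig(k=k, tau=tau, score_mode=mode))
            sizes = [c.size for c in res.clusters]
            grid[(k, tau)] = float(np.mean(sizes)) if sizes else 0.0
    target_size = summarize(C).per_target_factors["mean"]
    k_sel = select_at_k if select_at_k is not None else max(k_values)
    best_tau, best_gap = None, np.inf
    for tau in sorted(tau_values):  # ascending: later (larger) tau wins ties
        gap = abs(grid[(k_sel, tau)] - target_size)
        if gap <= best_gap:
            best_tau, best_gap = tau, gap
    return ParamSurface(grid=grid, selected_tau=float(best_tau))


# --- cluster table I/O -------------------------------------------------------


def write_clusters(clusters: Iterable[Cluster], path) -> None:
    clusters = list(clusters)
    df = pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "members": [",".join(sorted(c.members)) for c in clusters],
            "size": [c.size for c in clusters],
            "coverage": [c.coverage for c in clusters],
            "is_singleton": [c.is_singleton for c in clusters],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_clusters(path) -> list[Cluster]:
    """Read a cluster table (cluster_id, comma-joined members[, coverage])."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "cluster_id" not in df.columns or "members" not in df.columns:
        raise ValueError("cluster table needs 'cluster_id' and 'members' columns")
    out = []
    for _, row in df.iterrows():
        members = frozenset(m.strip() for m in str(row["members"]).split(",") if m.strip())
        coverage = int(row["coverage"]) if "coverage" in df.columns and not pd.isna(row.get("coverage")) else 0
        out.append(Cluster(cluster_id=str(row["cluster_id"]), members=members, coverage=coverage))
    return out
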