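"""Cluster-level biology: intersection target sets and Jaccard overlaps.

A cluster's target set is the intersection of its members' target columns —
the genes bound by *every* trans-factor in the cluster.  Jaccard similarity
over target sets (or over member sets) quantifies how much two clusters
describe the same regulatory program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bmf import Cluster
from .interactions import InteractionMatrix, map_targets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetSet:
    cluster_id: str
    genes: frozenset[str]


def cluster_targets(
    cluster: Cluster,
    C: InteractionMatrix,
    mapping: Mapping[str, str] | None = None,
) -> TargetSet:
    """Targets bound by every member of the cluster (optionally gene-mapped)."""
    unknown = cluster.members - set(C.col_labels)
    if unknown:
        raise KeyError(f"cluster members not in matrix columns: {sorted(unknown)}")
    mask = np.ones(C.n_targets, dtype=bool)
    for f in cluster.members:
        mask &= C.column(f)
    targets = {C.row_labels[i] for i in np.flatnonzero(mask)}
    if not targets:
        logger.info("cluster %s has an empty intersection target set", cluster.cluster_id)
    return TargetSet(cluster.cluster_id, frozenset(map_targets(targets, mapping)))


def jaccard(setA: Iterable[str], setB: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    A, B = set(setA), set(setB)
    union = A | B
    if not union:
        logger.info("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(A & B) / len(union)


def overlap_matrix(
    sets: Mapping[str, Iterable[str]] | Sequence[TargetSet],
    top_n: int | None = None,
    exclude_singleton_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Symmetric pairwise-Jaccard matrix over named sets.

    ``sets`` may be a {name: id set} mapping or a list of TargetSet; the
    first ``top_n`` entries (in given order, usually coverage rank) are kept
    and IDs listed in ``exclude_singleton_ids`` are dropped first.
    """
    if isinstance(sets, Mapping):
        items = [(k, frozenset(v)) for k, v in sets.items()]
    else:
        items = [(ts.cluster_id, ts.genes) for ts in sets]
    drop = set(exclude_singleton_ids)
    items = [(k, v) for k, v in items if k not in drop]
    if top_n is not None:
        items = items[:top_n]
    if len(items) < 2:
        raise ValueError("need at least two sets for an overlap matrix")
    names = [k for k, _ in items]
    M = np.eye(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            M[i, j] = M[j, i] = jaccard(items[i][1], items[j][1])
    return pd.DataFrame(M, index=names, columns=names)


def match_clusters(
    clustersA: Sequence[Cluster],
    clustersB: Sequence[Cluster],
    over: str = "members",
    targetsA: Mapping[str, Iterable[str]] | None = None,
    targetsB: Mapping[str, Iterable[str]] | None = None,
) -> tuple[list[tuple[str, str, float]], float]:
    """Match every A cluster to its maximal-Jaccard B cluster.

    ``over='members'`` compares member sets; ``over='targets'`` compares the
    provided target sets (keyed by cluster_id).  Ties keep the first B
    cluster in list order.  Returns the match list and the mean best-Jaccard.
    """
    if not clustersA or not clustersB:
        raise ValueError("both cluster lists must be non-empty")
    if over == "members":
        getA = {c.cluster_id: c.members for c in clustersA}
        getB = {c.cluster_id: c.members for c in clustersB}
    elif over == "targets":
        if targetsA is None or targetsB is None:
            raise ValueError("targets mode needs targetsA and targetsB mappings")
        getA = {c.cluster_id: frozenset(targetsA[c.cluster_id]) for c in clustersA}
        getB = {c.cluster_id: frozenset(targetsB[c.cluster_id]) for c in clustersB}
    else:
        raise ValueError("over must be 'members' or 'targets'")
    matches = []
    for a in clustersA:
        best_id, best_j = None, -1.0
        for b in clustersB:
            jac = jaccard(getA[a.cluster_id], getB[b.cluster_id])
            if jac > best_j:
                best_id, best_j = b.cluster_id, jac
        matches.append((a.cluster_id, best_id, best_j))
    mean_best = float(np.mean([m[2] for m in matches]))
    return matches, mean_best
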