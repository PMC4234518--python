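"""Deterministic generators of planted-structure inputs.

Every downstream module is testable without any database download: planted
rank-1 interaction blocks emulate co-regulator clusters, motif-bearing site
sequences emulate CLIP-derived binding stretches, and a small balanced
ontology with a planted concentrated annotation emulates a GO enrichment
scenario.  All generators are byte-reproducible given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .interactions import InteractionMatrix
from .ontology import OntologyDAG
from .sites import RNA_ALPHABET, SiteSequence

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PlantedSpec:
    n_targets: int
    n_factors: int
    planted_clusters: tuple  # of (factor index tuple, target index tuple)
    noise_p01: float = 0.0  # P(true 0 flips to 1)
    noise_p10: float = 0.0  # P(true 1 flips to 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.planted_clusters:
            raise ValueError("at least one planted cluster required")
        if not (0 <= self.noise_p01 < 0.5 and 0 <= self.noise_p10 < 0.5):
            raise ValueError("noise probabilities must be in [0, 0.5)")
        for factors, targets in self.planted_clusters:
            if any(not 0 <= f < self.n_factors for f in factors):
                raise ValueError("planted factor index out of bounds")
            if any(not 0 <= t < self.n_targets for t in targets):
                raise ValueError("planted target index out of bounds")


def _factor_label(j: int) -> str:
    return f"F{j + 1:03d}"


def _target_label(i: int) -> str:
    return f"T{i + 1:05d}"


def planted_matrix(spec: PlantedSpec) -> tuple[InteractionMatrix, list[frozenset[str]]]:
    """Union of planted rank-1 blocks plus independent bit-flip noise.

    Returns the interaction matrix and the ground-truth clusters as sets of
    factor labels.  Overlapping blocks are allowed.
    """
    C = np.zeros((spec.n_targets, spec.n_factors), dtype=bool)
    truth = []
    for factors, targets in spec.planted_clusters:
        C[np.ix_(list(targets), list(factors))] = True
        truth.append(frozenset(_factor_label(f) for f in factors))
    if spec.noise_p01 > 0 or spec.noise_p10 > 0:
        rng = np.random.default_rng(spec.seed)
        u = rng.random(C.shape)
        flip = np.where(C, u < spec.noise_p10, u < spec.noise_p01)
        C = C ^ flip
    rows = [_target_label(i) for i in range(spec.n_targets)]
    cols = [_factor_label(j) for j in range(spec.n_factors)]
    return InteractionMatrix(C, rows, cols), truth


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def synthetic_sites(
    motif: str,
    rbp_id: str,
    n: int = 100,
    len_range: tuple[int, int] = (20, 70),
    structure_context: str = "none",
    seed: int = 0,
) -> list[SiteSequence]:
    """Random-background sites with a class motif planted at a random position.

    ``structure_context='stem'`` wraps the motif in a complementary hairpin
    (left arm + loop holding the motif + reverse-complement right arm), so
    part of the class signal is structural rather than purely sequential.
    Each site derives its own random stream from (seed, index), so adding
    sites never perturbs earlier ones.
    """
    motif = motif.upper().replace("T", "U")
    if set(motif) - RNA_ALPHABET:
        raise ValueError("motif must be over {A, C, G, U}")
    lo, hi = len_range
    if structure_context not in ("none", "stem", "loop"):
        raise ValueError("structure_context must be 'none', 'stem' or 'loop'")
    sites = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        length = int(rng.integers(lo, hi + 1))
        if structure_context == "stem":
            # hairpin: arm .. motif loop .. reverse-complement arm
            left = _random_rna(rng, 6)
            insert = left + motif + "".join(_COMPLEMENT[c] for c in reversed(left))
        else:
            insert = motif
        if len(insert) > length:
            if len(insert) > hi:
                raise ValueError("motif (with context) longer than max site length")
            length = len(insert)
        pos = int(rng.integers(0, length - len(insert) + 1))
        seq = _random_rna(rng, length)
        seq = seq[:pos] + insert + seq[pos + len(insert):]
        start = int(rng.integers(0, 1000))
        sites.append(
            SiteSequence(
                site_id=f"{rbp_id}_s{i:04d}",
                rbp_id=rbp_id,
                sequence=seq,
                source=(f"tx{rng.integers(0, max(1, n // 4)):04d}", start, start + length),
            )
        )
    return sites


def toy_ontology(
    depth: int = 3,
    branching: int = 2,
    n_genes: int = 30,
    planted: tuple[str, Sequence[str]] | None = None,
    n_part_of: int = 2,
    annotations_per_gene: int = 2,
    seed: int = 0,
    namespace: str = "BP",
) -> tuple[OntologyDAG, dict[str, set[str]]]:
    """Balanced is_a tree with a few part_of cross-edges and random annotations.

    ``planted=(term_id, genes)`` concentrates that term's annotation on the
    given gene subset, creating a genuine enrichment signal.  Term IDs are
    ``GO:<level><index>`` style synthetic identifiers; genes are g000..  The
    root is ``GO:R``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    root = "GO:R"
    g.add_node(root, name="root", namespace=namespace)
    levels = [[root]]
    counter = 0
    for lv in range(1, depth + 1):
        level_nodes = []
        for parent in levels[-1]:
            for _ in range(branching):
                term = f"GO:{counter:04d}"
                counter += 1
                g.add_node(term, name=f"term {term}", namespace=namespace)
                g.add_edge(term, parent, relation="is_a")
                level_nodes.append(term)
        levels.append(level_nodes)
    # part_of cross edges between non-adjacent branches (no cycles: child->up-level)
    for _ in range(n_part_of):
        if depth < 2:
            break
        child = levels[-1][int(rng.integers(len(levels[-1])))]
        target_lv = int(rng.integers(1, depth))
        parent = levels[target_lv][int(rng.integers(len(levels[target_lv])))]
        if parent not in nx.descendants(g, child) and child != parent:
            if child not in nx.descendants(g, parent):
                g.add_edge(child, parent, relation="part_of")
    dag = OntologyDAG(g)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    leaves = levels[-1]
    ann: dict[str, set[str]] = {gene: set() for gene in genes}
    for gene in genes:
        picks = rng.choice(len(leaves), size=min(annotations_per_gene, len(leaves)), replace=False)
        ann[gene] = {leaves[int(p)] for p in picks}
    if planted is not None:
        term, subset = planted
        if term not in dag.terms:
            raise KeyError(f"planted term {term} not in the generated ontology")
        for gene in subset:
            ann.setdefault(gene, set()).add(term)
    return dag, ann
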