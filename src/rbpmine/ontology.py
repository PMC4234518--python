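"""Gene Ontology structure, annotation propagation, enrichment and similarity.

The ontology is held as a networkx DiGraph with child→parent edges restricted
to ``is_a`` and ``part_of`` relations.  Gene annotations are propagated to all
ancestors (the true-path rule) before any testing.

Enrichment is a one-sided Fisher exact (hypergeometric upper tail) test for
over-representation, either *classic* (every term tested independently) or
with the *elim* decorrelation: terms are visited from the most specific DAG
level upward and, whenever a term tests significant, its study genes are
removed from the annotation sets of all its ancestors before those are
tested.  This suppresses the cascade of trivially significant ancestors that
a significant specific term otherwise drags along.

Term-to-term semantic similarity follows Wang's graph-based method (weighted
S-value propagation through the ancestor closure; is_a edges weigh 0.8,
part_of 0.6) and term-*list* similarity uses the best-match average (BMA)
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

NAMESPACES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}

#: Wang semantic-contribution factors per edge relation.
DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyDAG:
    """GO DAG: ``graph`` holds child→parent edges labeled by relation."""

    graph: nx.DiGraph
    roots: dict = field(default_factory=dict)  # namespace -> root term id

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")
        if not self.roots:
            for t in self.graph.nodes:
                if self.graph.out_degree(t) == 0:
                    self.roots[self.namespace(t)] = t

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str:
        return NAMESPACES.get(self.graph.nodes[term].get("namespace", "BP"), "BP")

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable through parent edges (term excluded)."""
        return set(nx.descendants(self.graph, term))

    def depths(self) -> dict[str, int]:
        """Longest path length from each term up to its namespace root."""
        if not hasattr(self, "_depths"):
            d: dict[str, int] = {}
            for t in reversed(list(nx.topological_sort(self.graph))):
                d[t] = max((1 + d[p] for p in self.graph.successors(t)), default=0)
            self._depths = d
        return self._depths

    def depth(self, term: str) -> int:
        return self.depths()[term]


def parse_obo(path) -> OntologyDAG:
    """Minimal OBO 1.2 reader: [Term] stanzas, is_a and part_of relations.

    Obsolete terms are skipped; other relationship types are ignored.
    """
    g = nx.DiGraph()
    term: dict | None = None

    def flush(t: dict | None) -> None:
        if not t or t.get("obsolete") or "id" not in t:
            return
        tid = t["id"]
        g.add_node(tid, name=t.get("name", tid), namespace=t.get("namespace", ""))
        for parent, rel in t.get("parents", []):
            g.add_edge(tid, parent, relation=rel)

    with open(path) as fh:
        in_term = False
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush(term if in_term else None)
                in_term = line == "[Term]"
                term = {"parents": []} if in_term else None
                continue
            if not in_term or not line or ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.strip()
            if key == "id":
                term["id"] = value
            elif key == "name":
                term["name"] = value
            elif key == "namespace":
                term["namespace"] = value
            elif key == "is_obsolete" and value.startswith("true"):
                term["obsolete"] = True
            elif key == "is_a":
                term["parents"].append((value.split("!")[0].strip(), "is_a"))
            elif key == "relationship":
                parts = value.split("!")[0].split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    term["parents"].append((parts[1], "part_of"))
        flush(term if in_term else None)
    # ensure referenced parents exist even without their own stanza
    for _, parent in list(g.edges):
        if "name" not in g.nodes[parent]:
            g.nodes[parent].setdefault("name", parent)
            g.nodes[parent].setdefault("namespace", "")
    return OntologyDAG(g)


def read_annotations(path, fmt: str = "auto") -> dict[str, set[str]]:
    """Read gene→term annotations from GAF 2.x or a two-column TSV.

    GAF lines with the NOT qualifier are dropped.  Returns the *direct*
    annotation map; propagation to ancestors happens in
    :func:`propagate_annotations`.
    """
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        first = True
        for raw in fh:
            if raw.startswith("!") or raw.startswith("#") or not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if fmt == "auto" and first:
                fmt = "gaf" if len(fields) >= 15 else "tsv"
            first = False
            if fmt == "gaf":
                if len(fields) < 5:
                    continue
                qualifier, gene, term = fields[3], fields[2], fields[4]
                if "NOT" in qualifier:
                    continue
            else:
                if len(fields) < 2:
                    continue
                gene, term = fields[0], fields[1]
            ann.setdefault(gene, set()).add(term)
    return ann


def propagate_annotations(
    annotations: Mapping[str, Iterable[str]], dag: OntologyDAG
) -> dict[str, set[str]]:
    """Extend each gene's term set with all ancestors (true-path rule)."""
    closure: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in closure:
            closure[term] = dag.ancestors(term) if term in dag.terms else set()
        return closure[term]

    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        full = set(terms)
        for t in terms:
            full |= anc(t)
        out[gene] = full
    return out


def terms_to_genes(propagated: Mapping[str, set[str]]) -> dict[str, set[str]]:
    t2g: dict[str, set[str]] = {}
    for gene, terms in propagated.items():
        for t in terms:
            t2g.setdefault(t, set()).add(gene)
    return t2g


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    p_value: float
    study_hits: int
    study_size: int
    background_hits: int
    background_size: int
    significant: bool


def _fisher_tail(study_hits: int, study_size: int, bg_hits: int, bg_size: int) -> float:
    """One-sided over-representation p: P[X >= study_hits], X ~ Hypergeom."""
    return float(hypergeom.sf(study_hits - 1, bg_size, bg_hits, study_size))


def fisher_enrichment(
    study: set[str],
    background: set[str],
    annotations: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
    alpha: float = 0.05,
    namespace: str | None = None,
) -> list[EnrichmentResult]:
    """Classic term-by-term over-representation test (no DAG decorrelation)."""
    if not study:
        raise ValueError("study set is empty")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    prop = propagate_annotations(annotations, dag)
    t2g = terms_to_genes(prop)
    results = []
    for term, genes in t2g.items():
        if namespace is not None and term in dag.terms and dag.namespace(term) != namespace:
            continue
        study_hits = len(genes & study)
        if study_hits == 0:
            continue
        bg_hits = len(genes & background)
        p = _fisher_tail(study_hits, len(study), bg_hits, len(background))
        results.append(
            EnrichmentResult(term, p, study_hits, len(study), bg_hits, len(background), p <= alpha)
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def elim_enrichment(
    study: set[str],
    background: set[str],
    annotations: Mapping[str, Iterable[str]],
    dag: OntologyDAG,
    alpha: float = 0.05,
    elim_alpha: float | None = None,
    namespace: str | None = None,
) -> list[EnrichmentResult]:
    """Over-representation with the elim DAG-decorrelation procedure.

    Terms are processed from the deepest DAG level (longest path to the
    namespace root) upward, ties in term-ID order.  When a term's p-value is
    ≤ ``elim_alpha`` (default: ``alpha``), its study genes are eliminated
    from the annotation sets of all its ancestors before those are tested.
    """
    if not study:
        raise ValueError("study set is empty")
    if not study <= background:
        raise ValueError("study set must be a subset of the background")
    if elim_alpha is None:
        elim_alpha = alpha
    prop = propagate_annotations(annotations, dag)
    t2g = terms_to_genes(prop)
    testable = [
        t
        for t, genes in t2g.items()
        if genes & study
        and (namespace is None or t not in dag.terms or dag.namespace(t) == namespace)
    ]
    depth = {t: dag.depth(t) if t in dag.terms else 0 for t in testable}
    order = sorted(testable, key=lambda t: (-depth[t], t))
    eliminated: dict[str, set[str]] = {t: set() for t in testable}
    results = []
    for term in order:
        genes = t2g[term] - eliminated.get(term, set())
        study_hits = len(genes & study)
        bg_hits = len(genes & background)
        p = _fisher_tail(study_hits, len(study), bg_hits, len(background))
        results.append(
            EnrichmentResult(term, p, study_hits, len(study), bg_hits, len(background), p <= alpha)
        )
        if p <= elim_alpha and term in dag.terms:
            marked = genes & study
            for anc in dag.ancestors(term):
                if anc in eliminated:
                    eliminated[anc] |= marked
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def emergent_enrichments(
    cluster_results: Iterable[EnrichmentResult],
    per_member_results: Mapping[str, Iterable[EnrichmentResult]],
) -> list[str]:
    """Terms significant for the cluster target set but for no single member.

    These are the cluster's *emergent* annotations: functions concentrated in
    the intersection targets that no individual factor's target list shows.
    """
    member_sig: set[str] = set()
    for results in per_member_results.values():
        member_sig |= {r.term_id for r in results if r.significant}
    return sorted(
        r.term_id for r in cluster_results if r.significant and r.term_id not in member_sig
    )


# --- Wang semantic similarity ------------------------------------------------


def _svalues(
    term: str, dag: OntologyDAG, weights: Mapping[str, float]
) -> dict[str, float]:
    """S-values of ``term`` over its ancestor closure (term itself = 1).

    S_A(t) = max over children c of t inside the closure of w(t←c) · S_A(c).
    """
    closure = {term} | dag.ancestors(term)
    s: dict[str, float] = {term: 1.0}
    # children-before-parents order within the closure
    sub = dag.graph.subgraph(closure)
    for t in nx.topological_sort(sub):
        if t == term:
            continue
        best = 0.0
        for c in sub.predecessors(t):
            w = weights.get(sub.edges[c, t].get("relation", "is_a"))
            if w is None:
                continue
            best = max(best, w * s.get(c, 0.0))
        s[t] = best
    return s


def wang_similarity(
    termA: str,
    termB: str,
    dag: OntologyDAG,
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
) -> float:
    """Wang's semantic similarity between two terms of the same namespace."""
    for t in (termA, termB):
        if t not in dag.terms:
            raise KeyError(f"unknown term {t}")
    if dag.namespace(termA) != dag.namespace(termB):
        raise ValueError("terms belong to different namespaces")
    if termA == termB:
        return 1.0
    sA = _svalues(termA, dag, weights)
    sB = _svalues(termB, dag, weights)
    common = set(sA) & set(sB)
    if not common:
        return 0.0
    return sum(sA[t] + sB[t] for t in common) / (sum(sA.values()) + sum(sB.values()))


@dataclass(frozen=True)
class SemanticSimilarity:
    value: float
    namespace: str
    method: str = "wang"
    combine: str = "bma"


def bma_similarity(
    termsA: Iterable[str],
    termsB: Iterable[str],
    dag: OntologyDAG,
    weights: Mapping[str, float] = DEFAULT_WANG_WEIGHTS,
) -> SemanticSimilarity:
    """Best-match-average combination of pairwise Wang similarities."""
    A, B = sorted(set(termsA)), sorted(set(termsB))
    if not A or not B:
        raise ValueError("both term lists must be non-empty")
    sim = {(a, b): wang_similarity(a, b, dag, weights) for a in A for b in B}
    row_best = [max(sim[(a, b)] for b in B) for a in A]
    col_best = [max(sim[(a, b)] for a in A) for b in B]
    value = (sum(row_best) + sum(col_best)) / (len(A) + len(B))
    return SemanticSimilarity(value=value, namespace=dag.namespace(A[0]))
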