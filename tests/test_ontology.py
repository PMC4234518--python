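"""Ontology parsing, annotation propagation, enrichment and semantic similarity."""

import math

import networkx as nx
import numpy as np
import pytest

from rbpmine.ontology import (
    EnrichmentResult,
    OntologyDAG,
    bma_similarity,
    elim_enrichment,
    emergent_enrichments,
    fisher_enrichment,
    parse_obo,
    propagate_annotations,
    read_annotations,
    terms_to_genes,
    wang_similarity,
)
from rbpmine.simulate import toy_ontology

OBO_TEXT = """format-version: 1.2

[Term]
id: GO:0000001
name: child term
namespace: biological_process
is_a: GO:0000002 ! parent term

[Term]
id: GO:0000002
name: parent term
namespace: biological_process
is_a: GO:0000003 ! root term

[Term]
id: GO:0000003
name: root term
namespace: biological_process

[Term]
id: GO:0000004
name: component
namespace: biological_process
relationship: part_of GO:0000002 ! parent term

[Term]
id: GO:0000005
name: dead term
namespace: biological_process
is_obsolete: true
"""


class TestOboAndAnnotations:
    def test_parse_obo(self, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(OBO_TEXT)
        dag = parse_obo(p)
        assert "GO:0000005" not in dag.terms  # obsolete dropped
        assert dag.parents("GO:0000001") == {"GO:0000002"}
        assert dag.graph.edges["GO:0000004", "GO:0000002"]["relation"] == "part_of"
        assert dag.ancestors("GO:0000001") == {"GO:0000002", "GO:0000003"}
        assert dag.depth("GO:0000001") == 2

    def test_read_two_column_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tGO:0000001\ng1\tGO:0000004\ng2\tGO:0000002\n")
        ann = read_annotations(p)
        assert ann == {"g1": {"GO:0000001", "GO:0000004"}, "g2": {"GO:0000002"}}

    def test_read_gaf_skips_not_qualifier(self, tmp_path):
        cols = ["DB", "ID1", "geneA", "", "GO:0000001"] + [""] * 12
        not_cols = ["DB", "ID2", "geneB", "NOT", "GO:0000001"] + [""] * 12
        p = tmp_path / "ann.gaf"
        p.write_text(
            "!gaf-version: 2.1\n" + "\t".join(cols) + "\n" + "\t".join(not_cols) + "\n"
        )
        ann = read_annotations(p)
        assert ann == {"geneA": {"GO:0000001"}}

    def test_propagation_matches_transitive_closure(self):
        """A gene annotated to a term is counted at every ancestor."""
        rng = np.random.default_rng(5)
        dag, ann = toy_ontology(depth=3, branching=2, n_genes=15, seed=5)
        prop = propagate_annotations(ann, dag)
        for gene, terms in ann.items():
            closure = set(terms)
            for t in terms:
                closure |= nx.descendants(dag.graph, t)  # independent oracle
            assert prop[gene] == closure


def hypergeom_tail_oracle(k: int, n_study: int, K: int, N: int) -> float:
    """P[X >= k] by explicit summation of hypergeometric point masses."""
    total = 0.0
    for x in range(k, min(n_study, K) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n_study - x) / math.comb(N, n_study)
        )
    return total


class TestFisherEnrichment:
    def _flat_dag(self, terms):
        g = nx.DiGraph()
        g.add_node("GO:R", name="root", namespace="BP")
        for t in terms:
            g.add_node(t, name=t, namespace="BP")
            g.add_edge(t, "GO:R", relation="is_a")
        return OntologyDAG(g)

    def test_forced_arithmetic(self):
        """bg 10 genes, 4 annotated; study 5 with all 4 -> p = 6/252."""
        dag = self._flat_dag(["GO:T"])
        background = {f"g{i}" for i in range(10)}
        ann = {f"g{i}": {"GO:T"} for i in range(4)}
        study = {"g0", "g1", "g2", "g3", "g9"}
        results = fisher_enrichment(study, background, ann, dag)
        rT = next(r for r in results if r.term_id == "GO:T")
        assert rT.p_value == pytest.approx(6 / 252)
        assert (rT.study_hits, rT.background_hits) == (4, 4)
        assert rT.significant

    def test_matched_frequency_is_not_significant(self):
        dag = self._flat_dag(["GO:T"])
        background = {f"g{i}" for i in range(40)}
        ann = {f"g{i}": {"GO:T"} for i in range(0, 40, 2)}  # 50% annotated
        study = {f"g{i}" for i in range(0, 20)}  # also 50% annotated
        (rT,) = [r for r in fisher_enrichment(study, background, ann, dag) if r.term_id == "GO:T"]
        assert rT.p_value >= 0.5

    def test_term_annotating_everything_p_one(self):
        dag = self._flat_dag(["GO:T"])
        background = {f"g{i}" for i in range(8)}
        ann = {g: {"GO:T"} for g in background}
        (rT,) = [r for r in fisher_enrichment({"g0", "g1"}, background, ann, dag) if r.term_id == "GO:T"]
        assert rT.p_value == pytest.approx(1.0)

    def test_empty_study_errors(self):
        dag = self._flat_dag(["GO:T"])
        with pytest.raises(ValueError):
            fisher_enrichment(set(), {"g"}, {}, dag)

    def test_matches_tail_sum_oracle_on_random_tables(self):
        rng = np.random.default_rng(17)
        dag = self._flat_dag(["GO:T"])
        for _ in range(30):
            N = int(rng.integers(8, 30))
            background = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N))
            annotated = rng.choice(N, size=K, replace=False)
            ann = {f"g{i}": {"GO:T"} for i in annotated}
            n_study = int(rng.integers(1, N))
            study = {f"g{i}" for i in rng.choice(N, size=n_study, replace=False)}
            res = [r for r in fisher_enrichment(study, background, ann, dag) if r.term_id == "GO:T"]
            if not res:
                continue
            k = res[0].study_hits
            assert res[0].p_value == pytest.approx(
                hypergeom_tail_oracle(k, n_study, K, N), rel=1e-9
            )


class TestElim:
    def test_parent_loses_significance_after_elimination(self, two_level_dag):
        """Parent annotated only through a significant child drops to p = 1."""
        background = {f"g{i}" for i in range(20)}
        ann = {f"g{i}": {"GO:C"} for i in range(4)}  # parent sees genes via child only
        study = {"g0", "g1", "g2", "g3"}
        classic = {r.term_id: r for r in fisher_enrichment(study, background, ann, two_level_dag)}
        elim = {r.term_id: r for r in elim_enrichment(study, background, ann, two_level_dag)}
        assert classic["GO:C"].p_value < 0.05
        assert classic["GO:P"].p_value < 0.05  # inherited, pre-decorrelation
        assert elim["GO:C"].p_value == classic["GO:C"].p_value
        assert elim["GO:P"].p_value == pytest.approx(1.0)
        assert elim["GO:P"].study_hits == 0

    def test_no_significant_child_equals_classic(self, two_level_dag):
        background = {f"g{i}" for i in range(10)}
        ann = {f"g{i}": {"GO:C"} for i in range(8)}
        study = {"g0", "g9"}
        classic = fisher_enrichment(study, background, ann, two_level_dag)
        elim = elim_enrichment(study, background, ann, two_level_dag)
        assert {(r.term_id, r.p_value) for r in classic} == {
            (r.term_id, r.p_value) for r in elim
        }

    def test_flat_dag_equals_classic(self):
        g = nx.DiGraph()
        g.add_node("GO:R", name="r", namespace="BP")
        for t in ("GO:A", "GO:B"):
            g.add_node(t, name=t, namespace="BP")
            g.add_edge(t, "GO:R", relation="is_a")
        dag = OntologyDAG(g)
        background = {f"g{i}" for i in range(12)}
        ann = {"g0": {"GO:A"}, "g1": {"GO:A"}, "g2": {"GO:B"}}
        study = {"g0", "g1", "g2"}
        classic = {(r.term_id, r.p_value) for r in fisher_enrichment(study, background, ann, dag) if r.term_id != "GO:R"}
        elim = {(r.term_id, r.p_value) for r in elim_enrichment(study, background, ann, dag) if r.term_id != "GO:R"}
        assert classic == elim

    def test_elim_never_below_recomputed_classic_on_reduced_sets(self):
        """Eliminating genes can only weaken an ancestor's evidence."""
        rng = np.random.default_rng(23)
        for seed in range(5):
            dag, ann = toy_ontology(depth=3, branching=2, n_genes=20, seed=seed)
            genes = sorted(ann)
            study = set(rng.choice(genes, size=8, replace=False))
            background = set(genes)
            classic = {r.term_id: r.p_value for r in fisher_enrichment(study, background, ann, dag)}
            elim = elim_enrichment(study, background, ann, dag)
            for r in elim:
                assert r.p_value >= classic[r.term_id] - 1e-12


class TestEmergent:
    def _res(self, term, p):
        return EnrichmentResult(term, p, 1, 1, 1, 1, p <= 0.05)

    def test_shared_term_excluded_unique_term_included(self):
        cluster = [self._res("GO:A", 0.01), self._res("GO:B", 0.02)]
        members = {"f1": [self._res("GO:A", 0.03)], "f2": [self._res("GO:C", 0.5)]}
        assert emergent_enrichments(cluster, members) == ["GO:B"]

    def test_planted_intersection_annotation_is_emergent(self):
        """An annotation concentrated in the shared targets emerges only
        cluster-wide."""
        dag, ann = toy_ontology(
            depth=2, branching=2, n_genes=24,
            planted=("GO:0002", [f"g{i:03d}" for i in range(6)]), seed=3,
        )
        background = {f"g{i:03d}" for i in range(24)}
        shared = {f"g{i:03d}" for i in range(6)}  # cluster intersection targets
        member_sets = {
            "fA": shared | {f"g{i:03d}" for i in range(6, 15)},
            "fB": shared | {f"g{i:03d}" for i in range(15, 24)},
        }
        cluster_res = elim_enrichment(shared, background, ann, dag)
        member_res = {
            f: elim_enrichment(s, background, ann, dag) for f, s in member_sets.items()
        }
        assert "GO:0002" in emergent_enrichments(cluster_res, member_res)


class TestWangSimilarity:
    def test_identical_terms(self, three_chain_dag):
        assert wang_similarity("GO:A", "GO:A", three_chain_dag) == 1.0

    def test_siblings_under_root(self, three_chain_dag):
        # closed form: common ancestor R only, S(R) = 0.8 both sides
        expected = (0.8 + 0.8) / (1.8 + 1.8)
        assert wang_similarity("GO:A", "GO:B", three_chain_dag) == pytest.approx(expected)

    def test_parent_child_closed_form(self, three_chain_dag):
        # sim(A, R) = (0.8 + 1) / (1.8 + 1)
        assert wang_similarity("GO:A", "GO:R", three_chain_dag) == pytest.approx(1.8 / 2.8)

    def test_four_node_dag_hand_propagation(self, two_level_dag):
        # sim(C, P): T_C = {C, P, R} with S_C = (1, 0.8, 0.64); T_P = {P, R}
        # with S_P = (1, 0.8); shared {P, R}:
        expected = (0.8 + 1 + 0.64 + 0.8) / ((1 + 0.8 + 0.64) + (1 + 0.8))
        assert wang_similarity("GO:C", "GO:P", two_level_dag) == pytest.approx(expected)

    def test_part_of_weight(self, tmp_path):
        p = tmp_path / "go.obo"
        p.write_text(OBO_TEXT)
        dag = parse_obo(p)
        # GO:0000004 -part_of-> GO:0000002: S-value of parent via 0.6 weight
        sim = wang_similarity("GO:0000004", "GO:0000002", dag)
        expected = (0.6 + 1 + 0.6 * 0.8 + 0.8) / ((1 + 0.6 + 0.48) + (1 + 0.8))
        assert sim == pytest.approx(expected)

    def test_symmetry(self, two_level_dag):
        assert wang_similarity("GO:C", "GO:R", two_level_dag) == pytest.approx(
            wang_similarity("GO:R", "GO:C", two_level_dag)
        )

    def test_cross_namespace_errors(self):
        g = nx.DiGraph()
        g.add_node("GO:X", name="x", namespace="BP")
        g.add_node("GO:Y", name="y", namespace="MF")
        dag = OntologyDAG(g)
        with pytest.raises(ValueError):
            wang_similarity("GO:X", "GO:Y", dag)


class TestBMA:
    def test_identity(self, three_chain_dag):
        assert bma_similarity(["GO:A", "GO:B"], ["GO:A", "GO:B"], three_chain_dag).value == 1.0

    def test_single_terms_equal_wang(self, three_chain_dag):
        bma = bma_similarity(["GO:A"], ["GO:B"], three_chain_dag)
        assert bma.value == pytest.approx(wang_similarity("GO:A", "GO:B", three_chain_dag))

    def test_two_by_two_combination(self, two_level_dag):
        A, B = ["GO:C", "GO:P"], ["GO:P", "GO:R"]
        table = {
            (a, b): wang_similarity(a, b, two_level_dag) for a in A for b in B
        }
        row_best = sum(max(table[(a, b)] for b in B) for a in A)
        col_best = sum(max(table[(a, b)] for a in A) for b in B)
        expected = (row_best + col_best) / 4
        assert bma_similarity(A, B, two_level_dag).value == pytest.approx(expected)

    def test_symmetric_and_bounded(self, two_level_dag):
        v1 = bma_similarity(["GO:C"], ["GO:P", "GO:R"], two_level_dag).value
        v2 = bma_similarity(["GO:P", "GO:R"], ["GO:C"], two_level_dag).value
        assert v1 == pytest.approx(v2)
        assert 0.0 <= v1 <= 1.0

    def test_empty_errors(self, two_level_dag):
        with pytest.raises(ValueError):
            bma_similarity([], ["GO:P"], two_level_dag)
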