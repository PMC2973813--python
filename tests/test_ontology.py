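import math

import numpy as np
import pytest

from parabuffer import ontology as onto
from parabuffer.synth import SynthConfig, generate_ontology

from conftest import (
    CHAIN_OBO,
    gaf_row,
    make_gaf,
    oracle_ancestors,
    oracle_go_div,
    oracle_term_counts,
)

ROOT, MID, LEAF = "GO:0000001", "GO:0000002", "GO:0000003"


class TestParseObo:
    def test_chain_topology(self, chain_dag):
        assert chain_dag.terms == {ROOT, MID, LEAF}
        assert chain_dag.root == ROOT
        assert chain_dag.ancestors(LEAF) == {LEAF, MID, ROOT}

    def test_obsolete_dropped(self):
        obo = CHAIN_OBO + "\n[Term]\nid: GO:0000009\nnamespace: biological_process\nis_a: GO:0000001\nis_obsolete: true\n"
        dag = onto.parse_obo(obo)
        assert "GO:0000009" not in dag.terms

    def test_part_of_and_is_a_edges(self, five_term_dag):
        # C has both an is_a and a part_of parent
        assert five_term_dag.parents["GO:0000004"] == {"GO:0000002", "GO:0000003"}
        # manual closure of D: D, C, A, B, root
        assert five_term_dag.ancestors("GO:0000005") == {
            "GO:0000005", "GO:0000004", "GO:0000002", "GO:0000003", "GO:0000001",
        }

    def test_alt_id_mapping(self):
        obo = CHAIN_OBO.replace("id: GO:0000003\n", "id: GO:0000003\nalt_id: GO:0099999\n")
        dag = onto.parse_obo(obo)
        assert dag.canonical("GO:0099999") == LEAF
        assert "GO:0099999" in dag

    def test_cycle_detected(self):
        obo = CHAIN_OBO + "\n[Term]\nid: GO:0000010\nnamespace: biological_process\nis_a: GO:0000011\n\n[Term]\nid: GO:0000011\nnamespace: biological_process\nis_a: GO:0000010\n"
        with pytest.raises(onto.CycleError, match="GO:00000"):
            onto.parse_obo(obo)

    def test_multiple_roots_rejected(self):
        obo = CHAIN_OBO + "\n[Term]\nid: GO:0000012\nnamespace: biological_process\n"
        with pytest.raises(onto.OntologyFormatError, match="root"):
            onto.parse_obo(obo)

    def test_non_bp_terms_excluded(self):
        obo = CHAIN_OBO + "\n[Term]\nid: GO:0000020\nnamespace: molecular_function\n"
        dag = onto.parse_obo(obo)
        assert "GO:0000020" not in dag.terms


class TestParseGaf:
    def test_propagation_on_chain(self, chain_dag):
        corpus = onto.parse_gaf(make_gaf([gaf_row("g1", LEAF)]), chain_dag)
        assert corpus.term_count[LEAF] == corpus.term_count[MID] == corpus.term_count[ROOT] == 1
        assert corpus.total == 1

    def test_iea_only_is_empty(self, chain_dag):
        gaf = make_gaf([gaf_row("g1", LEAF, evidence="IEA")])
        with pytest.raises(onto.OntologyFormatError, match="qualifying"):
            onto.parse_gaf(gaf, chain_dag)

    def test_non_p_aspect_excluded(self, chain_dag):
        gaf = make_gaf([gaf_row("g1", LEAF, aspect="F"), gaf_row("g2", MID)])
        corpus = onto.parse_gaf(gaf, chain_dag)
        assert "g1" not in corpus.gene_terms

    def test_not_qualifier_excluded(self, chain_dag):
        gaf = make_gaf([gaf_row("g1", LEAF, qualifier="NOT|involved_in"), gaf_row("g2", MID)])
        corpus = onto.parse_gaf(gaf, chain_dag)
        assert "g1" not in corpus.gene_terms

    def test_unknown_term_skipped_and_counted(self, chain_dag):
        gaf = make_gaf([gaf_row("g1", "GO:0777777"), gaf_row("g2", MID)])
        corpus = onto.parse_gaf(gaf, chain_dag)
        assert corpus.n_skipped_terms == 1
        assert "g1" not in corpus.gene_terms

    def test_duplicate_rows_count_once(self, chain_dag):
        gaf = make_gaf([gaf_row("g1", LEAF), gaf_row("g1", LEAF)])
        corpus = onto.parse_gaf(gaf, chain_dag)
        assert corpus.total == 1

    def test_ten_gene_fixture_matches_descendant_oracle(self, five_term_dag):
        rng = np.random.default_rng(0)
        terms = sorted(five_term_dag.terms)
        gene_terms = {
            f"g{i}": {terms[j] for j in rng.choice(5, size=rng.integers(1, 4), replace=False)}
            for i in range(10)
        }
        corpus = onto.AnnotationCorpus.from_gene_terms(five_term_dag, gene_terms)
        expected, total = oracle_term_counts(five_term_dag, gene_terms)
        assert corpus.total == total
        for t in five_term_dag.terms:
            assert corpus.term_count.get(t, 0) == expected[t]


class TestTermProbability:
    @pytest.fixture
    def chain_corpus(self, chain_dag):
        # 10 annotations: leaf x1, mid x4, root x5  -> p(leaf)=0.1, p(mid)=0.5
        rows = [gaf_row("gl", LEAF)]
        rows += [gaf_row(f"gm{i}", MID) for i in range(4)]
        rows += [gaf_row(f"gr{i}", ROOT) for i in range(5)]
        return onto.parse_gaf(make_gaf(rows), chain_dag)

    def test_root_probability_is_one(self, chain_corpus):
        assert onto.term_probability(chain_corpus, ROOT) == 1.0

    def test_leaf_ratio(self, chain_corpus):
        assert onto.term_probability(chain_corpus, LEAF) == pytest.approx(0.1)

    def test_mid_matches_enumeration(self, chain_dag, chain_corpus):
        counts, total = oracle_term_counts(chain_dag, chain_corpus.gene_terms)
        assert onto.term_probability(chain_corpus, MID) == pytest.approx(counts[MID] / total)

    def test_unannotated_term_errors(self, five_term_dag):
        corpus = onto.AnnotationCorpus.from_gene_terms(five_term_dag, {"g": {"GO:0000002"}})
        with pytest.raises(onto.UnannotatedTermError):
            onto.term_probability(corpus, "GO:0000005")


class TestTermSimilarity:
    @pytest.fixture
    def wide_setup(self):
        # root with two leaf children meeting only at the root
        obo = CHAIN_OBO.replace("is_a: GO:0000002", "is_a: GO:0000001")
        dag = onto.parse_obo(obo)
        corpus = onto.AnnotationCorpus.from_gene_terms(
            dag, {"ga": {MID}, "gb": {LEAF}}
        )
        return dag, corpus

    def test_root_only_overlap_gives_zero(self, wide_setup):
        dag, corpus = wide_setup
        score = onto.term_similarity(dag, corpus, MID, LEAF)
        assert score.similarity == 0.0
        assert score.mica == ROOT

    def test_self_similarity_is_one(self, chain_dag):
        # p(leaf) = 0.1 via 1 of 10 annotations
        rows = [gaf_row("gl", LEAF)] + [gaf_row(f"g{i}", ROOT) for i in range(9)]
        corpus = onto.parse_gaf(make_gaf(rows), chain_dag)
        assert onto.term_similarity(chain_dag, corpus, LEAF, LEAF).similarity == 1.0

    def test_chain_fixture_hand_value(self):
        # two leaves under mid: p(mid)=0.5, p(leaves)=0.2 each
        obo = CHAIN_OBO + "\n[Term]\nid: GO:0000004\nnamespace: biological_process\nis_a: GO:0000002\n"
        dag = onto.parse_obo(obo)
        rows = [gaf_row(f"ga{i}", LEAF) for i in range(2)]
        rows += [gaf_row(f"gb{i}", "GO:0000004") for i in range(2)]
        rows += [gaf_row("gm", MID)]
        rows += [gaf_row(f"gr{i}", ROOT) for i in range(5)]
        corpus = onto.parse_gaf(make_gaf(rows), dag)
        assert onto.term_probability(corpus, MID) == pytest.approx(0.5)
        assert onto.term_probability(corpus, LEAF) == pytest.approx(0.2)
        score = onto.term_similarity(dag, corpus, LEAF, "GO:0000004")
        expected = 2 * math.log(0.5) / (math.log(0.2) + math.log(0.2))
        assert score.similarity == pytest.approx(expected, abs=1e-12)
        assert score.mica == MID

    def test_subsumption_uses_reflexive_ancestors(self, chain_dag):
        rows = [gaf_row("gl", LEAF)] + [gaf_row(f"g{i}", MID) for i in range(3)] + [
            gaf_row(f"gr{i}", ROOT) for i in range(6)
        ]
        corpus = onto.parse_gaf(make_gaf(rows), chain_dag)
        # MICA of (leaf, mid) is mid itself
        assert onto.term_similarity(chain_dag, corpus, LEAF, MID).mica == MID


class TestGoDiv:
    def test_identical_nonroot_sets_give_zero(self, chain_dag):
        corpus = onto.AnnotationCorpus.from_gene_terms(
            chain_dag, {"ga": {LEAF}, "gb": {LEAF}, "gc": {ROOT}}
        )
        res = onto.go_div(chain_dag, corpus, "ga", "gb")
        assert res.status == "ok"
        assert res.score == pytest.approx(0.0)

    def test_root_only_overlap_gives_one(self):
        obo = CHAIN_OBO.replace("is_a: GO:0000002", "is_a: GO:0000001")
        dag = onto.parse_obo(obo)
        corpus = onto.AnnotationCorpus.from_gene_terms(dag, {"ga": {MID}, "gb": {LEAF}})
        assert onto.go_div(dag, corpus, "ga", "gb").score == pytest.approx(1.0)

    def test_unannotated_gene_flagged(self, chain_dag):
        corpus = onto.AnnotationCorpus.from_gene_terms(chain_dag, {"ga": {LEAF}})
        res = onto.go_div(chain_dag, corpus, "ga", "missing")
        assert res.status == "unannotated"
        assert res.score is None

    def test_cross_pair_fixture_matches_exhaustive_oracle(self, five_term_dag):
        terms = sorted(five_term_dag.terms)
        gene_terms = {
            "ga": {terms[1], terms[3], terms[4]},
            "gb": {terms[2], terms[4]},
            "pad": {terms[0]},
        }
        corpus = onto.AnnotationCorpus.from_gene_terms(five_term_dag, gene_terms)
        res = onto.go_div(five_term_dag, corpus, "ga", "gb")
        assert res.score == pytest.approx(
            oracle_go_div(five_term_dag, gene_terms, "ga", "gb"), abs=1e-12
        )


@pytest.fixture(scope="module")
def random_worlds():
    worlds = []
    for seed in range(10):
        cfg = SynthConfig(seed=seed, n_ontology_terms=30, n_genes=10)
        dag, gene_terms = generate_ontology(cfg)
        corpus = onto.AnnotationCorpus.from_gene_terms(dag, gene_terms)
        worlds.append((dag, gene_terms, corpus))
    return worlds


class TestProperties:
    """Invariants over randomly generated small ontologies."""

    def test_similarity_bounds_and_symmetry(self, random_worlds):
        rng = np.random.default_rng(1)
        for dag, _, corpus in random_worlds:
            annotated = [t for t, c in corpus.term_count.items() if c > 0]
            for _ in range(20):
                m, n = rng.choice(annotated, size=2)
                s_mn = onto.term_similarity(dag, corpus, m, n).similarity
                s_nm = onto.term_similarity(dag, corpus, n, m).similarity
                assert 0.0 <= s_mn <= 1.0
                assert s_mn == pytest.approx(s_nm, abs=1e-12)

    def test_go_div_bounds_and_symmetry(self, random_worlds):
        for dag, _, corpus in random_worlds:
            genes = sorted(corpus.gene_terms)[:6]
            for i, ga in enumerate(genes):
                for gb in genes[i + 1:]:
                    ab = onto.go_div(dag, corpus, ga, gb).score
                    ba = onto.go_div(dag, corpus, gb, ga).score
                    assert 0.0 <= ab <= 1.0
                    assert ab == pytest.approx(ba, abs=1e-12)

    def test_term_count_matches_descendant_oracle(self, random_worlds):
        for dag, gene_terms, corpus in random_worlds:
            expected, total = oracle_term_counts(dag, gene_terms)
            assert corpus.total == total
            for t in dag.terms:
                assert corpus.term_count.get(t, 0) == expected[t]

    def test_shared_specific_annotation_never_increases_go_div(self, random_worlds):
        for dag, gene_terms, corpus in random_worlds:
            genes = sorted(corpus.gene_terms)[:4]
            # deepest term = one with maximal ancestor set
            deep = max(dag.terms, key=lambda t: len(oracle_ancestors(dag, t)))
            for i, ga in enumerate(genes):
                for gb in genes[i + 1:]:
                    before = onto.go_div(dag, corpus, ga, gb).score
                    richer = {g: set(ts) for g, ts in gene_terms.items()}
                    richer[ga].add(deep)
                    richer[gb].add(deep)
                    corpus2 = onto.AnnotationCorpus.from_gene_terms(dag, richer)
                    after = onto.go_div(dag, corpus2, ga, gb).score
                    assert after <= before + 1e-12
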