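import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parabuffer import interactions as ia


def rec(a="A", b="B", score=-0.5, p=0.01):
    return ia.InteractionRecord(a, b, score, p)


class TestReadTable:
    def test_well_formed(self):
        tsv = "gene_a\tgene_b\tscore\tp_value\nA\tB\t-0.5\t0.01\nC\tD\t0.1\t0.5\nE\tF\t-0.2\t0.2\n"
        table = ia.read_interaction_table(tsv)
        assert len(table) == 3

    def test_symmetric_duplicates_collapse(self):
        tsv = "gene_a\tgene_b\tscore\tp_value\nA\tB\t-0.5\t0.01\nB\tA\t-0.3\t0.20\n"
        table = ia.read_interaction_table(tsv)
        assert len(table) == 1
        assert table.n_collapsed == 1
        # more significant record kept
        assert table.get("B", "A").p_value == 0.01

    def test_out_of_range_p_rejected(self):
        tsv = "gene_a\tgene_b\tscore\tp_value\nA\tB\t-0.5\t1.5\nC\tD\t0.1\t0.5\n"
        table = ia.read_interaction_table(tsv)
        assert len(table) == 1
        assert table.n_rejected == 1

    def test_non_numeric_raises_with_line(self):
        tsv = "gene_a\tgene_b\tscore\tp_value\nA\tB\toops\t0.01\n"
        with pytest.raises(ia.InteractionError, match="line 2"):
            ia.read_interaction_table(tsv)

    def test_empty_table_raises(self):
        with pytest.raises(Exception):
            ia.read_interaction_table("gene_a\tgene_b\tscore\tp_value\n")

    def test_lookup_symmetric(self):
        table = ia.InteractionTable([rec("X", "Y")])
        assert table.get("Y", "X") is table.get("X", "Y")
        assert ("Y", "X") in table


class TestClassify:
    def test_buffering(self):
        assert ia.classify_buffering(rec(score=-0.5, p=0.01)) is True

    def test_fails_p_criterion(self):
        assert ia.classify_buffering(rec(score=-0.5, p=0.20)) is False

    def test_fails_sign_criterion(self):
        assert ia.classify_buffering(rec(score=0.1, p=0.001)) is False

    def test_boundary_is_strict(self):
        assert ia.classify_buffering(rec(score=0.0, p=0.01)) is False
        assert ia.classify_buffering(rec(score=-0.1, p=0.05)) is False

    def test_gene_order_invariant(self):
        assert ia.classify_buffering(rec("A", "B")) == ia.classify_buffering(rec("B", "A"))


class TestSummary:
    def test_printed_count_fraction(self):
        pairs = [rec(a=f"a{i}", b=f"b{i}", score=-0.5, p=0.01) for i in range(105)]
        pairs += [rec(a=f"c{i}", b=f"d{i}", score=0.1, p=0.5) for i in range(161)]
        s = ia.buffering_summary(pairs)
        assert s.n_total == 266
        assert s.fraction == pytest.approx(105 / 266)
        assert round(s.percentage, 1) == 39.5

    def test_zero_buffering_mean_undefined(self):
        pairs = [rec(score=0.1, p=0.5) for _ in range(10)]
        s = ia.buffering_summary(pairs)
        assert s.fraction == 0.0
        assert s.mean_strength is None

    def test_empty_raises(self):
        with pytest.raises(ia.InteractionError):
            ia.buffering_summary([])

    def test_planted_rate_within_binomial_ci(self):
        rng = np.random.default_rng(0)
        flags = rng.random(200) < 0.30
        pairs = [
            rec(a=f"a{i}", b=f"b{i}", score=-0.5 if f else 0.1, p=0.01 if f else 0.5)
            for i, f in enumerate(flags)
        ]
        s = ia.buffering_summary(pairs)
        half_width = 1.96 * np.sqrt(0.3 * 0.7 / 200)
        assert abs(s.fraction - 0.30) <= half_width


@pytest.fixture(scope="module")
def mixed_table():
    rng = np.random.default_rng(42)
    n = 3000
    n_neg = round(0.07 * n)
    scores = np.abs(rng.normal(0, 0.1, n)) + 1e-9
    scores[:n_neg] *= -1
    rng.shuffle(scores)
    return ia.InteractionTable([
        ia.InteractionRecord(f"g{i}", f"h{i}", float(scores[i]), float(rng.uniform()))
        for i in range(n)
    ])


class TestRandomizationNull:
    def test_all_negative_degenerate(self):
        table = ia.InteractionTable([
            ia.InteractionRecord(f"a{i}", f"b{i}", -0.1, 0.5) for i in range(50)
        ])
        null = ia.randomization_null(table, n_controls=20, pairs_per_control=30, seed=1)
        assert np.all(null.control_percentages == 100.0)

    def test_background_rate_recovered(self, mixed_table):
        null = ia.randomization_null(mixed_table, n_controls=300, pairs_per_control=1000, seed=2)
        assert np.mean(null.control_percentages) == pytest.approx(7.0, abs=0.6)

    def test_deterministic_under_seed(self, mixed_table):
        a = ia.randomization_null(mixed_table, n_controls=10, pairs_per_control=100, seed=7)
        b = ia.randomization_null(mixed_table, n_controls=10, pairs_per_control=100, seed=7)
        np.testing.assert_array_equal(a.control_percentages, b.control_percentages)
        np.testing.assert_array_equal(a.control_mean_scores, b.control_mean_scores)

    def test_small_table_suggests_replacement(self, mixed_table):
        with pytest.raises(ia.InteractionError, match="replace"):
            ia.randomization_null(mixed_table, n_controls=5, pairs_per_control=10**6, seed=0)

    def test_concentrates_on_true_fraction(self, mixed_table):
        # as pairs_per_control approaches the table size the spread collapses
        true_frac = 100 * np.mean(mixed_table.scores() < 0)
        null = ia.randomization_null(mixed_table, n_controls=50, pairs_per_control=2900, seed=3)
        assert np.mean(null.control_percentages) == pytest.approx(true_frac, abs=0.2)
        assert np.std(null.control_percentages) < 0.2


class TestDuplicateShuffleNull:
    def test_pairing_structure_on_four_genes(self):
        genes = ["a", "b", "c", "d"]
        table = ia.InteractionTable([
            ia.InteractionRecord(x, y, -0.1, 0.5)
            for i, x in enumerate(genes) for y in genes[i + 1:]
        ])
        null = ia.duplicate_shuffle_null(genes, table, n_controls=25, seed=0)
        assert null.pairs_per_control == 2
        assert np.all(null.control_percentages == 100.0)

    def test_true_pair_regeneration_allowed(self):
        # only the true pairs are assayed; shuffles that recreate them count
        genes = ["a", "b", "c", "d"]
        table = ia.InteractionTable([
            ia.InteractionRecord("a", "b", -0.5, 0.01),
            ia.InteractionRecord("c", "d", 0.2, 0.6),
        ])
        null = ia.duplicate_shuffle_null(genes, table, n_controls=60, seed=1)
        assert null.n_dropped > 0  # most shuffles miss the table
        assert len(null.control_percentages) > 0

    def test_planted_rate_recovered(self):
        from parabuffer.synth import generate_duplicate_shuffle_fixture

        genes, table = generate_duplicate_shuffle_fixture(60, 0.066, seed=9)
        null = ia.duplicate_shuffle_null(genes, table, n_controls=400, seed=9)
        assert np.mean(null.control_percentages) == pytest.approx(6.6, abs=0.8)

    def test_too_few_genes(self, mixed_table):
        with pytest.raises(ia.InteractionError):
            ia.duplicate_shuffle_null(["a", "b"], mixed_table, n_controls=5, seed=0)


class TestEmpiricalP:
    def test_above_every_null_value(self):
        null = np.linspace(0, 10, 1000)
        assert ia.empirical_p(50.0, null, "greater") == pytest.approx(1 / 1001)

    def test_at_median(self):
        null = np.linspace(0, 10, 999)
        assert ia.empirical_p(5.0, null, "greater") == pytest.approx(0.5, abs=0.01)

    def test_observed_far_above_centered_null(self):
        rng = np.random.default_rng(0)
        null = rng.normal(7, 1, 1000)
        assert ia.empirical_p(39.5, null, "greater") == pytest.approx(1 / 1001)

    def test_invalid_side(self):
        with pytest.raises(ValueError):
            ia.empirical_p(1.0, np.ones(10), "both")

    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=60),
        st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_property(self, null, observed):
        p = ia.empirical_p(observed, np.array(null), "greater")
        assert 0 < p <= 1

    def test_monotone_in_observed(self):
        null = np.linspace(0, 1, 100)
        ps = [ia.empirical_p(x, null, "greater") for x in (0.1, 0.5, 0.9)]
        assert ps[0] >= ps[1] >= ps[2]
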