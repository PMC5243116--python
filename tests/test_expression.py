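"""FPKM, relative-expression clustering, dormancy/cold classifiers,
the simplified DE test, and contamination QC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from oracle import fisher_two_sided
from seedimprint.expression import (
    DORMANCY_ORDER,
    ExpressionMatrix,
    cold_response_class,
    contamination_fraction,
    de_test,
    dormancy_correlation_class,
    fpkm,
    fpkm_matrix,
    kmeans_cluster,
    relative_to_reference,
)
from seedimprint.simulate import simulate_expression_panel


class TestFpkm:
    def test_unit_scale(self):
        assert fpkm(1000, 1000, 1e6) == pytest.approx(1000.0)

    def test_zero_count(self):
        assert fpkm(0, 2000, 3e7) == 0.0

    @given(count=st.integers(1, 10**6), length=st.integers(100, 10**5),
           total=st.integers(10**5, 10**8))
    @settings(max_examples=50, deadline=None)
    def test_doubling_library_halves_fpkm(self, count, length, total):
        assert fpkm(count, length, 2 * total) == pytest.approx(fpkm(count, length, total) / 2)

    @given(count=st.integers(1, 10**6), length=st.integers(100, 10**5),
           total=st.integers(10**5, 10**8))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_joint_doubling(self, count, length, total):
        assert fpkm(2 * count, length, 2 * total) == pytest.approx(fpkm(count, length, total))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fpkm(10, 0, 1e6)
        with pytest.raises(ValueError):
            fpkm(10, 1000, 0)

    def test_matrix_form_matches_scalar(self):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [5, 7]}, index=["g1", "g2"])
        lengths = {"g1": 1500, "g2": 800}
        sizes = {"s1": 2e6, "s2": 1e6}
        out = fpkm_matrix(counts, lengths, sizes)
        assert out.loc["g1", "s1"] == pytest.approx(fpkm(10, 1500, 2e6))
        assert out.loc["g2", "s2"] == pytest.approx(fpkm(7, 800, 1e6))


class TestRelativeToReference:
    def _matrix(self, rows, samples=("ColxCvi", "CvixCol", "Col")):
        return ExpressionMatrix(values=pd.DataFrame(rows, columns=list(samples)))

    def test_reference_column_becomes_ones(self):
        m = self._matrix({"g1": [2.0, 4.0, 8.0], "g2": [5.0, 5.0, 10.0]}.values())
        m.values.index = ["g1", "g2"]
        rel = relative_to_reference(m, "ColxCvi")
        assert (rel.values["ColxCvi"] == 1.0).all()
        assert list(rel.values.loc["g1"]) == [1.0, 2.0, 4.0]

    def test_zero_reference_genes_dropped(self, caplog):
        m = self._matrix([[0.0, 4.0, 8.0], [5.0, 5.0, 10.0]])
        m.values.index = ["gz", "g2"]
        rel = relative_to_reference(m, "ColxCvi")
        assert rel.genes == ["g2"]

    def test_missing_reference_is_an_error(self):
        m = self._matrix([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="reference"):
            relative_to_reference(m, "nope")

    def test_negative_values_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionMatrix(values=pd.DataFrame([[-1.0]], columns=["s"]))


class TestKmeans:
    def test_recovers_separated_planted_clusters(self):
        panel, truth = simulate_expression_panel(n_genes=30, noise_sd=0.05, seed=11)
        result = kmeans_cluster(panel, k=3, seed=17)
        labels = [result.assignments[g] for g in panel.genes]
        assert adjusted_rand_score([truth[g] for g in panel.genes], labels) == 1.0

    def test_k_equal_one_centroid_is_column_mean(self):
        panel, _ = simulate_expression_panel(n_genes=12, noise_sd=0.2, seed=5)
        result = kmeans_cluster(panel, k=1, seed=17)
        assert set(result.assignments.values()) == {1}
        np.testing.assert_allclose(result.centroids[0],
                                   panel.values.mean(axis=0).to_numpy())

    def test_duplicate_rows_share_a_label(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]] * 4 + [[9.0, 9.0, 9.0, 9.0]] * 4,
                              columns=list(DORMANCY_ORDER),
                              index=[f"g{i}" for i in range(8)])
        result = kmeans_cluster(ExpressionMatrix(values=values), k=2, seed=17)
        assert len({result.assignments[f"g{i}"] for i in range(4)}) == 1
        # first gene's cluster is relabelled 1
        assert result.assignments["g0"] == 1

    def test_deterministic_under_fixed_seed(self):
        panel, _ = simulate_expression_panel(n_genes=40, noise_sd=0.3, seed=2)
        a = kmeans_cluster(panel, k=3, seed=17, restarts=10)
        b = kmeans_cluster(panel, k=3, seed=17, restarts=10)
        assert a.assignments == b.assignments and a.inertia == b.inertia

    def test_k_exceeding_genes_rejected(self):
        panel, _ = simulate_expression_panel(n_genes=5, seed=1)
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(panel, k=6)


class TestDormancyCorrelation:
    def test_strict_increase_is_negative_correlation(self):
        values = dict(zip(DORMANCY_ORDER, [1.0, 2.0, 3.0, 4.0]))
        assert dormancy_correlation_class(values) == "negative"

    def test_non_monotone_is_other(self):
        values = dict(zip(DORMANCY_ORDER, [4.0, 3.0, 3.0, 2.0]))
        assert dormancy_correlation_class(values) == "other"

    def test_exactly_one_of_24_orderings_is_negative(self):
        """Over all permutations of four distinct values, only the strictly
        increasing arrangement along falling dormancy classifies negative."""
        hits = sum(
            dormancy_correlation_class(dict(zip(DORMANCY_ORDER, perm))) == "negative"
            for perm in itertools.permutations([1.0, 2.0, 3.0, 4.0])
        )
        assert hits == 1

    def test_spearman_variant_agrees_on_monotone_profiles(self):
        values = dict(zip(DORMANCY_ORDER, [0.5, 1.0, 2.0, 4.0]))
        assert dormancy_correlation_class(values, method="spearman") == "negative"

    def test_missing_genotype_is_an_error(self):
        with pytest.raises(ValueError, match="missing genotype"):
            dormancy_correlation_class({"Cvi": 1.0, "Col": 2.0})


class TestColdResponse:
    @pytest.mark.parametrize(
        "control, cold, p, expected",
        [
            (10.0, 3.0, 0.01, "Down"),
            (10.0, 3.0, 0.20, "Unchanged"),
            (10.0, 25.0, 0.01, "Up"),
            (10.0, 19.0, 0.01, "Unchanged"),  # below the twofold bar
        ],
    )
    def test_twofold_rule(self, control, cold, p, expected):
        assert cold_response_class("g", control, cold, p).response == expected

    def test_zero_control_flags_infinite_fold(self):
        result = cold_response_class("g", 0.0, 5.0, 0.01)
        assert result.response == "Up" and math.isinf(result.fold_change)


class TestDeTest:
    def test_equal_normalized_counts_symmetric(self):
        log2fc, p = de_test(100, 100, 10**6, 10**6)
        assert log2fc == 0.0
        assert p == 1.0

    def test_extreme_case_matches_enumeration_oracle(self):
        lib = 10**6
        log2fc, p = de_test(100, 0, lib, lib)
        assert log2fc > 7
        assert p == pytest.approx(fisher_two_sided(100, lib - 100, 0, lib), abs=1e-9)

    @given(a=st.integers(0, 60), b=st.integers(0, 60))
    @settings(max_examples=40, deadline=None)
    def test_antisymmetry(self, a, b):
        lib = 10**5
        fc_ab, p_ab = de_test(a, b, lib, lib)
        fc_ba, p_ba = de_test(b, a, lib, lib)
        assert fc_ab == pytest.approx(-fc_ba)
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_counts_above_library_size_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            de_test(10, 5, 8, 100)


class TestContamination:
    def test_published_meg_read_counts_stay_below_two_percent(self):
        # testa vs partially dissected endosperm reads of the two testa-detected MEGs
        assert contamination_fraction(9, 603) == pytest.approx(100 * 9 / 603)
        assert contamination_fraction(9, 603) < 2.0
        assert contamination_fraction(3, 2154) == pytest.approx(100 * 3 / 2154)
        assert contamination_fraction(3, 2154) < 2.0

    def test_zero_testa_reads(self):
        assert contamination_fraction(0, 1000) == 0.0

    def test_zero_endosperm_reads_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            contamination_fraction(5, 0)
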