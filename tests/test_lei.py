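"""LEI statistic: HWE expansion, joint distribution, theta^2 and its invariances."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aimpanel import (
    MarkerFrequencyTable,
    PopulationPanel,
    hwe_expected_counts,
    joint_distribution,
    lei,
    lei_from_frequency_matrix,
    lei_table,
    lei_upper_bound,
)


def phi2_oracle(p: np.ndarray) -> float:
    """Pearson's mean-square contingency, cell-by-cell, as an independent check."""
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            e = row[i] * col[j]
            if e > 0:
                total += (p[i, j] - e) ** 2 / e
    return total


freq_arrays = st.integers(2, 6).flatmap(
    lambda k: st.tuples(
        st.lists(st.floats(0, 1), min_size=k, max_size=k),
        st.lists(st.floats(0.1, 1000), min_size=k, max_size=k),
    )
)


class TestHweExpectedCounts:
    @pytest.mark.parametrize(
        "f, c, expected",
        [
            (0.0, 10, (10, 0, 0)),
            (1.0, 10, (0, 0, 10)),
            (0.79, 100, (4.41, 33.18, 62.41)),
        ],
    )
    def test_expected_triples(self, f, c, expected):
        got = hwe_expected_counts(f, c)
        assert got == pytest.approx(expected, abs=1e-9)

    @given(f=st.floats(0, 1), c=st.floats(0.01, 1e6))
    @settings(max_examples=200)
    def test_triple_sums_to_sample_count(self, f, c):
        assert sum(hwe_expected_counts(f, c)) == pytest.approx(c, rel=1e-12)

    @pytest.mark.parametrize("f, c", [(-0.1, 1), (1.1, 1), (0.5, 0), (0.5, -2)])
    def test_domain_errors(self, f, c):
        with pytest.raises(ValueError):
            hwe_expected_counts(f, c)


class TestJointDistribution:
    def test_fully_separated_two_populations(self, pair_panel):
        joint = joint_distribution(np.array([0.0, 1.0]), pair_panel)
        assert joint.p == pytest.approx(
            np.array([[0.5, 0.0], [0.0, 0.0], [0.0, 0.5]])
        )

    def test_column_marginals_are_count_shares(self, trio_panel):
        panel = trio_panel.with_counts([99, 103, 108])
        joint = joint_distribution(np.array([0.3, 0.6, 0.9]), panel)
        assert joint.col_marginals == pytest.approx(panel.counts / panel.n)

    def test_row_marginals_hand_summed(self, trio_panel):
        joint = joint_distribution(np.array([0.79, 0.17, 0.99]), trio_panel)
        # mean over populations of (1-f)^2, 2f(1-f), f^2
        f = np.array([0.79, 0.17, 0.99])
        expected = np.array(
            [(1 - f) ** 2, 2 * f * (1 - f), f**2]
        ).mean(axis=1)
        assert joint.row_marginals == pytest.approx(expected)
        assert joint.row_marginals == pytest.approx([0.2444, 0.2113, 0.5444], abs=5e-5)

    @given(data=freq_arrays)
    @settings(max_examples=200, deadline=None)
    def test_normalization_and_marginals(self, data):
        freqs, counts = data
        k = len(freqs)
        panel = PopulationPanel([f"P{i}" for i in range(k)], np.array(counts))
        joint = joint_distribution(np.array(freqs), panel)
        assert joint.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert joint.row_marginals.sum() == pytest.approx(1.0, abs=1e-12)
        assert joint.col_marginals == pytest.approx(panel.counts / panel.n, abs=1e-12)

    def test_propagates_domain_error_with_population_name(self, trio_panel):
        with pytest.raises(ValueError, match="CHB"):
            joint_distribution(np.array([0.5, 1.5, 0.5]), trio_panel)


class TestLei:
    def test_equal_frequencies_give_zero(self, trio_panel):
        joint = joint_distribution(np.array([0.4, 0.4, 0.4]), trio_panel)
        assert lei(joint) == 0.0

    def test_two_population_maximum(self, pair_panel):
        joint = joint_distribution(np.array([0.0, 1.0]), pair_panel)
        assert lei(joint) == pytest.approx(1.0, abs=1e-12)

    def test_worked_three_population_value(self, trio_panel):
        joint = joint_distribution(np.array([0.79, 0.17, 0.99]), trio_panel)
        theta2 = lei(joint)
        assert theta2 == pytest.approx(0.7772, abs=5e-5)
        assert round(theta2, 2) == 0.78

    def test_symmetric_two_population_value_vs_oracle(self, pair_panel):
        joint = joint_distribution(np.array([0.6, 0.4]), pair_panel)
        assert lei(joint) == pytest.approx(0.0769, abs=5e-5)
        assert lei(joint) == pytest.approx(phi2_oracle(joint.p), abs=1e-12)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            panel = PopulationPanel(
                [f"P{i}" for i in range(k)], rng.uniform(0.5, 500, k)
            )
            joint = joint_distribution(rng.uniform(0, 1, k), panel)
            assert abs(lei(joint) - phi2_oracle(joint.p)) < 1e-10

    def test_scipy_chi2_oracle_on_counts(self, trio_panel):
        """theta^2 equals chi^2/n of the HWE expected-count table."""
        from scipy.stats import chi2_contingency

        panel = trio_panel.with_counts([99.0, 103.0, 108.0])
        f = np.array([0.79, 0.17, 0.99])
        counts = np.array(
            [hwe_expected_counts(fj, cj) for fj, cj in zip(f, panel.counts)]
        ).T
        chi2 = chi2_contingency(counts, correction=False).statistic
        joint = joint_distribution(f, panel)
        assert lei(joint) == pytest.approx(chi2 / panel.n, abs=1e-10)

    @given(data=freq_arrays)
    @settings(max_examples=300, deadline=None)
    def test_bounds(self, data):
        freqs, counts = data
        k = len(freqs)
        panel = PopulationPanel([f"P{i}" for i in range(k)], np.array(counts))
        theta2 = lei(joint_distribution(np.array(freqs), panel))
        assert -1e-9 <= theta2 <= lei_upper_bound(k) + 1e-9

    @pytest.mark.parametrize("f_common", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_zero_iff_equal_frequencies_forward(self, f_common, trio_panel):
        joint = joint_distribution(np.full(3, f_common), trio_panel)
        assert lei(joint) == 0.0

    def test_zero_iff_equal_frequencies_reverse(self, trio_panel):
        grid = np.linspace(0, 1, 11)
        for f1 in grid:
            for f2 in grid:
                if abs(f1 - f2) < 1e-12:
                    continue
                joint = joint_distribution(np.array([f1, f2, f1]), trio_panel)
                assert lei(joint) > 0.0

    def test_allele_label_invariance(self, trio_panel):
        rng = np.random.default_rng(3)
        for _ in range(50):
            f = rng.uniform(0, 1, 3)
            a = lei(joint_distribution(f, trio_panel))
            b = lei(joint_distribution(1.0 - f, trio_panel))
            assert a == pytest.approx(b, abs=1e-12)

    def test_population_permutation_invariance(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0, 1, 4)
        c = rng.uniform(1, 50, 4)
        labels = ["P0", "P1", "P2", "P3"]
        base = lei(joint_distribution(f, PopulationPanel(labels, c)))
        for _ in range(10):
            perm = rng.permutation(4)
            value = lei(
                joint_distribution(
                    f[perm], PopulationPanel([labels[i] for i in perm], c[perm])
                )
            )
            assert value == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("scale", [0.5, 10.0, 1234.5])
    def test_sample_scale_invariance(self, scale, trio_panel):
        f = np.array([0.2, 0.7, 0.5])
        base = lei(joint_distribution(f, trio_panel.with_counts([5, 8, 13])))
        scaled = lei(
            joint_distribution(f, trio_panel.with_counts(np.array([5, 8, 13]) * scale))
        )
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_monotone_along_symmetric_two_population_line(self, pair_panel):
        values = [
            lei(joint_distribution(np.array([t, 1.0 - t]), pair_panel))
            for t in np.linspace(0.5, 1.0, 51)
        ]
        diffs = np.diff(values)
        assert np.all(diffs >= -1e-12)
        assert values[0] == pytest.approx(0.0, abs=1e-12)
        assert values[-1] == pytest.approx(1.0, abs=1e-12)


class TestLeiTable:
    def test_per_marker_scores_in_order(self, worked_example_table):
        scores = lei_table(worked_example_table)
        assert [s.marker_id for s in scores] == ["rs7289657", "rs2294368"]
        assert scores[0].theta2 == 0.0
        assert scores[1].theta2 == pytest.approx(0.7772, abs=5e-5)
        assert all(s.k == 3 for s in scores)

    def test_missing_frequency_scores_missing(self, trio_panel, caplog):
        table = MarkerFrequencyTable(
            panel=trio_panel,
            ids=["ok", "gap"],
            freqs=np.array([[0.1, 0.5, 0.9], [0.1, np.nan, 0.9]]),
        )
        with caplog.at_level(logging.WARNING, logger="aimpanel.lei"):
            scores = lei_table(table)
        assert not scores[0].is_missing
        assert scores[1].is_missing
        assert "gap" in caplog.text

    def test_all_missing_warns_not_raises(self, trio_panel, caplog):
        table = MarkerFrequencyTable(
            panel=trio_panel,
            ids=["a", "b"],
            freqs=np.full((2, 3), np.nan),
        )
        with caplog.at_level(logging.WARNING, logger="aimpanel.lei"):
            scores = lei_table(table)
        assert all(s.is_missing for s in scores)
        assert "no scores computed" in caplog.text

    def test_count_scale_invariance(self, worked_example_table):
        base = [s.theta2 for s in lei_table(worked_example_table)]
        table10 = MarkerFrequencyTable(
            panel=worked_example_table.panel.with_counts(np.array([10.0, 10.0, 10.0])),
            ids=worked_example_table.ids,
            freqs=worked_example_table.freqs,
        )
        scaled = [s.theta2 for s in lei_table(table10)]
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_vectorized_matches_scalar_path(self, trio_panel):
        rng = np.random.default_rng(11)
        F = rng.uniform(0, 1, size=(50, 3))
        c = rng.uniform(1, 100, 3)
        panel = trio_panel.with_counts(c)
        vec = lei_from_frequency_matrix(F, c)
        scalar = [lei(joint_distribution(F[i], panel)) for i in range(50)]
        assert vec == pytest.approx(scalar, abs=1e-12)

    def test_single_population_is_an_error(self):
        with pytest.raises(ValueError):
            PopulationPanel(("only",))
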