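"""Unit tests for upstream kinase activity inference."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from kinoforge.containers import IntensityMatrix, ValidationError
from kinoforge.kinome import (
    KinasePeptideMap,
    _q_score,
    kinase_statistic,
    peptide_differential,
    permutation_scores,
    rank_kinases,
)
from tests.conftest import two_group_labels


def _matrix_from_rows(rows: dict, n1: int, n2: int) -> IntensityMatrix:
    groups = two_group_labels(n1, n2)
    return IntensityMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=groups.index),
        groups, scale="log2",
    )


class TestPeptideDifferential:
    def test_identical_groups_give_null_statistics(self):
        m = _matrix_from_rows({"P1": [3.0, 4.0, 5.0] * 2}, 3, 3)
        stats = peptide_differential(m)
        assert stats.loc["P1", "t"] == 0.0
        assert stats.loc["P1", "p"] == 1.0

    def test_group_swap_negates_every_t(self, small_intensity):
        stats = peptide_differential(small_intensity)
        swapped = peptide_differential(small_intensity.swap_groups())
        np.testing.assert_allclose(stats["t"], -swapped["t"], rtol=1e-12)
        np.testing.assert_allclose(stats["p"], swapped["p"], rtol=1e-12)

    def test_adjusted_p_dominates_raw_p(self, small_intensity):
        stats = peptide_differential(small_intensity)
        assert (stats["p_adj"] >= stats["p"] - 1e-15).all()
        assert stats["p_adj"].between(0, 1).all()

    def test_single_sample_group_rejected(self):
        groups = pd.Series(["treated", "treated", "control"],
                           index=["T1", "T2", "C1"])
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"],
                              columns=groups.index)
        with pytest.raises(ValidationError):
            IntensityMatrix(values, groups, scale="log2")


class TestKinaseStatistic:
    def test_single_peptide_forced_by_formula(self):
        # mean diff 1.0 over sqrt(0.5 + 0.5) = 1.0
        stats = pd.DataFrame(
            {"mean_treated": [3.0], "mean_control": [2.0],
             "var_treated": [0.5], "var_control": [0.5]},
            index=["P1"],
        )
        kmap = KinasePeptideMap([("K", "P1")])
        assert kinase_statistic(stats, kmap, "K") == pytest.approx(1.0)

    def test_opposite_standardized_differences_cancel(self):
        stats = pd.DataFrame(
            {"mean_treated": [3.0, 2.0], "mean_control": [2.0, 3.0],
             "var_treated": [0.5, 0.5], "var_control": [0.5, 0.5]},
            index=["P1", "P2"],
        )
        kmap = KinasePeptideMap([("K", "P1"), ("K", "P2")])
        assert kinase_statistic(stats, kmap, "K") == pytest.approx(0.0)

    def test_group_swap_negates_tau(self, small_intensity, small_map):
        stats = peptide_differential(small_intensity)
        swapped = peptide_differential(small_intensity.swap_groups())
        for kinase in small_map.kinases:
            tau = kinase_statistic(stats, small_map, kinase)
            assert kinase_statistic(swapped, small_map, kinase) == pytest.approx(-tau)

    def test_variance_floor_keeps_tau_finite(self, caplog):
        stats = pd.DataFrame(
            {"mean_treated": [3.0], "mean_control": [2.0],
             "var_treated": [0.0], "var_control": [0.0]},
            index=["P1"],
        )
        kmap = KinasePeptideMap([("K", "P1")])
        with caplog.at_level("WARNING"):
            tau = kinase_statistic(stats, kmap, "K")
        assert np.isfinite(tau) and tau > 0
        assert "variance floor" in caplog.text

    def test_too_few_peptides_rejected(self, small_intensity, small_map):
        stats = peptide_differential(small_intensity)
        with pytest.raises(ValidationError):
            kinase_statistic(stats, small_map, "KC", min_peptides=3)


class TestPermutationScores:
    @pytest.mark.parametrize(
        "m,M,expected",
        [(0, 100, 2.0), (100, 100, 0.0), (5, 100, 1.3010299956639813)],
    )
    def test_q_formula(self, m, M, expected):
        assert _q_score(m, M) == pytest.approx(expected, abs=1e-12)

    def test_q_bounds_hold_for_both_modes(self, small_intensity, small_map):
        for mode in ("samples", "peptides"):
            for kinase in small_map.kinases:
                score = permutation_scores(small_intensity, small_map, kinase,
                                           mode, M=50, seed=3)
                assert 0.0 <= score.q <= np.log10(50) + 1e-12

    def test_exhaustive_sample_permutations_match_enumeration(self):
        """Independent oracle: recompute tau for every label assignment."""
        rng = np.random.default_rng(21)
        groups = two_group_labels(3, 3)
        values = pd.DataFrame(rng.normal(10, 1, (6, 6)),
                              index=[f"P{i}" for i in range(6)],
                              columns=groups.index)
        matrix = IntensityMatrix(values, groups, scale="log2")
        kmap = KinasePeptideMap([("K", "P0"), ("K", "P1"), ("K", "P2")])

        def tau_for(cols1, cols2):
            X = values.to_numpy()
            d = (X[:, cols1].mean(1) - X[:, cols2].mean(1)) / np.sqrt(
                X[:, cols1].var(1, ddof=1) + X[:, cols2].var(1, ddof=1)
            )
            return d[:3].mean()

        tau_obs = tau_for([0, 1, 2], [3, 4, 5])
        m_oracle = sum(
            abs(tau_for(list(c), [i for i in range(6) if i not in c])) > abs(tau_obs)
            for c in combinations(range(6), 3)
        )
        score = permutation_scores(matrix, kmap, "K", "samples", exhaustive=True)
        assert score.M == 20
        assert score.m == m_oracle
        assert score.tau == pytest.approx(tau_obs)

    def test_peptide_mode_whole_chip_set_is_degenerate(self, small_intensity):
        # a kinase mapped to every chip peptide: every random subset IS the
        # chip, tau_p == tau always, so m = 0 and Q hits the 1/M floor
        kmap = KinasePeptideMap([("K", f"P{i:02d}") for i in range(1, 11)])
        score = permutation_scores(small_intensity, kmap, "K", "peptides",
                                   M=40, seed=0)
        assert score.m == 0
        assert score.q == pytest.approx(np.log10(40))


class TestRankKinases:
    def test_single_kinase_gets_rank_one(self, small_intensity):
        kmap = KinasePeptideMap([("K", "P01"), ("K", "P02"), ("K", "P03")])
        scores, _ = rank_kinases(small_intensity, kmap, M=20, seed=0)
        assert list(scores["rank"]) == [1]

    def test_ties_broken_by_abs_tau_then_id(self, small_intensity, small_map):
        # M=1 forces every Q to 0, so all combined scores tie exactly
        scores, _ = rank_kinases(small_intensity, small_map, M=1, seed=0,
                                 min_peptides=2)
        assert (scores["combined_score"] == 0).all()
        taus = scores["tau"].abs().to_numpy()
        assert (np.diff(taus) <= 1e-15).all()

    def test_min_peptides_skips_small_sets(self, small_intensity, small_map):
        scores, skipped = rank_kinases(small_intensity, small_map, M=10, seed=0,
                                       min_peptides=3)
        assert skipped == ["KC"]
        assert set(scores["kinase_id"]) == {"KA", "KB"}

    def test_no_scorable_kinase_is_an_error(self, small_intensity):
        kmap = KinasePeptideMap([("K", "P01")])
        with pytest.raises(ValidationError):
            rank_kinases(small_intensity, kmap, M=10, seed=0, min_peptides=3)

    def test_deterministic_given_seed(self, small_intensity, small_map):
        a, _ = rank_kinases(small_intensity, small_map, M=30, seed=9,
                            min_peptides=2)
        b, _ = rank_kinases(small_intensity, small_map, M=30, seed=9,
                            min_peptides=2)
        pd.testing.assert_frame_equal(a, b)

    def test_direction_follows_tau_sign(self, small_intensity, small_map):
        scores, _ = rank_kinases(small_intensity, small_map, M=20, seed=1,
                                 min_peptides=2)
        for _, row in scores.iterrows():
            expected = "activated" if row["tau"] > 0 else "inhibited"
            assert row["direction"] == expected
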