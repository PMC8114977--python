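"""Tests for differential expression and methylation calling."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinoforge.containers import BetaMatrix, ExpressionMatrix, ValidationError
from kinoforge._stats import bh_adjust
from kinoforge.differential import (
    call_dmps,
    detection_filter,
    differential_expression,
    m_inverse,
    m_transform,
    moderated_ttest,
    quantile_normalize,
)
from tests.conftest import two_group_labels


class TestDetectionFilter:
    def _with_detection(self, matrix, probe, n_fail):
        dp = matrix.detection_p.copy()
        dp.loc[probe, dp.columns[:n_fail]] = 0.06
        return ExpressionMatrix(matrix.values, matrix.groups, scale=matrix.scale,
                                detection_p=dp, probe_gene_map=matrix.probe_gene_map)

    def test_probe_undetected_in_six_samples_removed(self, small_expression):
        m = self._with_detection(small_expression, "ILMN_001", 6)
        filtered, report = detection_filter(m)
        assert "ILMN_001" not in filtered.values.index
        assert report.removed_probes == ("ILMN_001",)

    def test_probe_undetected_in_five_samples_retained(self, small_expression):
        m = self._with_detection(small_expression, "ILMN_001", 5)
        filtered, report = detection_filter(m)
        assert "ILMN_001" in filtered.values.index
        assert report.n_removed == 0

    def test_all_probes_pass_is_identity(self, small_expression):
        filtered, report = detection_filter(small_expression)
        pd.testing.assert_frame_equal(filtered.values, small_expression.values)
        assert report.n_removed == 0

    def test_missing_detection_table(self, small_expression, caplog):
        m = ExpressionMatrix(small_expression.values, small_expression.groups)
        with caplog.at_level("WARNING"):
            filtered, _ = detection_filter(m)
        assert "skipped" in caplog.text
        with pytest.raises(ValidationError):
            detection_filter(m, strict=True)


class TestQuantileNormalize:
    def _raw(self, values, n1, n2):
        groups = two_group_labels(n1, n2)
        return ExpressionMatrix(
            pd.DataFrame(values, columns=groups.index), groups, scale="raw"
        )

    def test_hand_computed_rank_means(self):
        # columns [1,2,3] and [4,5,6] -> both become [2.5, 3.5, 4.5]
        m = self._raw(np.array([[1.0, 4, 1, 4], [2, 5, 2, 5], [3, 6, 3, 6]]), 2, 2)
        out = quantile_normalize(m)
        expected = np.log2([[2.5], [3.5], [4.5]]) * np.ones((1, 4))
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_identical_columns_are_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = self._raw(np.tile(col[:, None], 4), 2, 2)
        out = quantile_normalize(m)
        np.testing.assert_allclose(2.0 ** out.values.to_numpy(),
                                   np.tile(col[:, None], 4), rtol=1e-12)

    def test_columns_share_sorted_vector_and_total_sum(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(4, 50, (40, 6))
        m = self._raw(vals, 3, 3)
        out = 2.0 ** quantile_normalize(m).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 6):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        assert out.sum() == pytest.approx(vals.sum(), rel=1e-9)

    def test_negative_intensities_rejected(self):
        m = self._raw(np.array([[1.0, -2, 1, 1], [2, 5, 2, 2]]), 2, 2)
        with pytest.raises(ValidationError):
            quantile_normalize(m)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_limma_normalize_quantiles(self, tmp_path):
        """Independent oracle: limma::normalizeQuantiles on the same matrix."""
        rng = np.random.default_rng(12)
        vals = rng.gamma(3, 40, (30, 6))
        np.savetxt(tmp_path / "mat.tsv", vals, delimiter="\t")
        script = tmp_path / "qn.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.table("{tmp_path}/mat.tsv", sep="\\t"))\n'
            f'write.table(normalizeQuantiles(x), "{tmp_path}/qn.tsv", '
            'sep="\\t", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "qn.tsv", sep="\t").to_numpy()
        m = self._raw(vals, 3, 3)
        mine = 2.0 ** quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(mine, oracle, rtol=1e-10)


class TestModeratedT:
    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: limma lmFit + eBayes moderated t."""
        rng = np.random.default_rng(42)
        X = rng.normal(8, 1, (60, 10)) * np.sqrt(rng.gamma(3, 0.4, (60, 1)))
        np.savetxt(tmp_path / "mat.tsv", X, delimiter="\t")
        script = tmp_path / "mod.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.table("{tmp_path}/mat.tsv", sep="\\t"))\n'
            'design <- cbind(Intercept=1, Treat=c(rep(1,5), rep(0,5)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]), '
            f'"{tmp_path}/out.tsv", sep="\\t", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        t, p = moderated_ttest(X[:, :5], X[:, 5:])
        np.testing.assert_allclose(t, oracle["t"], rtol=1e-9)
        np.testing.assert_allclose(p, oracle["p"], rtol=1e-9)

    def test_homoscedastic_rows_shrink_to_common_variance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.3, (500, 12))
        t, p = moderated_ttest(X[:, :6], X[:, 6:])
        from scipy.stats import kstest
        assert kstest(p, "uniform").pvalue > 0.01


class TestMTransform:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert m_transform(beta) == pytest.approx(m, abs=1e-12)

    @given(st.floats(min_value=1.1e-3, max_value=1 - 1.1e-3))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, beta):
        assert m_inverse(m_transform(beta)) == pytest.approx(beta, abs=1e-12)

    def test_out_of_range_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            m = m_transform(np.array([0.0, 1.0]))
        assert "clipped" in caplog.text
        np.testing.assert_allclose(m, [m_transform(1e-3), m_transform(1 - 1e-3)])


class TestDifferentialExpression:
    def test_significance_gates(self, small_expression):
        records = differential_expression(small_expression)
        recomputed = (records["p_adj"] < 0.05) & (records["logfc"].abs() > 0.4)
        assert (records["significant"] == recomputed).all()

    def test_label_swap_flips_logfc_preserves_p(self, small_expression):
        a = differential_expression(small_expression)
        b = differential_expression(small_expression.swap_groups())
        np.testing.assert_allclose(a["logfc"], -b["logfc"], rtol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-12)

    def test_gene_symbols_attached(self, small_expression):
        records = differential_expression(small_expression)
        assert records.loc["ILMN_001", "gene"] == "G1"

    def test_raw_scale_rejected(self, small_expression):
        raw = ExpressionMatrix(small_expression.values.abs(),
                               small_expression.groups, scale="raw")
        with pytest.raises(ValidationError):
            differential_expression(raw)

    def test_planted_logfc_recovery(self):
        """Estimator err SD is noise*sqrt(2/n); +-0.35 is the ~2 sigma band."""
        from kinoforge.simulate import SimulationConfig, simulate_expression_and_qpcr

        hits = trials = 0
        for seed in range(40):
            cfg = SimulationConfig(seed=seed)
            expr, _, _, truth = simulate_expression_and_qpcr(cfg)
            records = differential_expression(expr)
            planted = truth[truth["feature_id"].str.startswith("GENE")]
            est = records.groupby("gene")["logfc"].mean()
            for _, row in planted.iterrows():
                trials += 1
                hits += abs(est[row["feature_id"]] - row["effect"]) <= 0.35
        assert hits / trials >= 0.93


class TestCallDmps:
    def test_significance_gates_and_direction(self, small_beta):
        records = call_dmps(small_beta)
        recomputed = (records["p_adj"] < 0.1) & (records["delta_beta"].abs() >= 0.05)
        assert (records["significant"] == recomputed).all()
        assert (records["direction"] == np.where(records["delta_beta"] > 0,
                                                 "hyper", "hypo")).all()

    def test_label_swap_flips_delta_beta_preserves_p(self, small_beta):
        a = call_dmps(small_beta)
        b = call_dmps(small_beta.swap_groups())
        np.testing.assert_allclose(a["delta_beta"], -b["delta_beta"], rtol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], rtol=1e-10)

    def test_null_simulation_calls_almost_nothing(self):
        from kinoforge.simulate import SimulationConfig, simulate_methylome

        cfg = SimulationConfig(seed=13, n_probes=2000, planted_dmp_fraction=0.0)
        betas, _, _ = simulate_methylome(cfg)
        records = call_dmps(betas)
        # with no signal, BH at FDR 0.1 plus the effect gate keeps calls near zero
        assert records["significant"].sum() <= 5


class TestBhAdjust:
    def test_textbook_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 50))
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        oracle = np.minimum.accumulate(stepped[::-1])[::-1].clip(0, 1)
        np.testing.assert_allclose(bh_adjust(p)[order], oracle, atol=1e-12)
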