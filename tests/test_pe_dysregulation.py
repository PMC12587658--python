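"""DEG filtering, BH, batch adjustment, relative abundance, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from ervcre import pe_dysregulation as pe
from ervcre import synthetic_data as synth
from ervcre.formats_io import ExpressionMatrix


def _expr(values, conditions, batches):
    df = pd.DataFrame(values)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    df.index = [f"g{i}" for i in range(df.shape[0])]
    meta = pd.DataFrame(
        {"condition": conditions, "batch": batches}, index=df.columns
    )
    return ExpressionMatrix(df, meta)


class TestFilterDegs:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "padj"])

    def test_empty_table(self):
        assert len(pe.filter_degs(self._table([]))) == 0

    def test_strict_boundaries(self):
        t = self._table(
            [
                ("at_alpha", 2.0, 0.01, 0.05),
                ("at_lfc", 1.0, 0.001, 0.01),
                ("passes", 1.01, 0.001, 0.049),
                ("neg_passes", -1.5, 0.001, 0.01),
            ]
        )
        kept = pe.filter_degs(t)
        assert set(kept["gene"]) == {"passes", "neg_passes"}

    def test_non_absolute_mode_drops_downregulated(self):
        t = self._table([("up", 2.0, 0.001, 0.01), ("down", -2.0, 0.001, 0.01)])
        assert list(pe.filter_degs(t, absolute=False)["gene"]) == ["up"]

    def test_subset_and_idempotent(self):
        cfg = synth.SimulationConfig(seed=6)
        a, _, _ = synth.make_de_tables(cfg)
        once = pe.filter_degs(a)
        twice = pe.filter_degs(once)
        assert set(once["gene"]) <= set(a["gene"])
        pd.testing.assert_frame_equal(once, twice)


class TestBhAdjust:
    def test_hand_stepup(self):
        np.testing.assert_allclose(
            pe.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(pe.bh_adjust([0.3]), [0.3])

    def test_matches_direct_formula_on_random_vectors(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 30))
            p = rng.uniform(1e-6, 1.0, size=m)
            got = pe.bh_adjust(p)
            order = np.argsort(p)
            expected = np.empty(m)
            for rank_pos, i in enumerate(order):
                j_over = [
                    m * p[order[jj]] / (jj + 1) for jj in range(rank_pos, m)
                ]
                expected[i] = min(1.0, min(j_over))
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = np.sort(rng.uniform(0, 1, 50))
        q = pe.bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pe.bh_adjust([0.5, 0.0])


class TestBatchCenter:
    def test_single_batch_identity(self, rng):
        expr = _expr(rng.normal(4, 1, (10, 8)), ["PE"] * 4 + ["control"] * 4, [1] * 8)
        out, diag = pe.batch_center(expr)
        np.testing.assert_allclose(
            out.values.to_numpy(), expr.values.to_numpy(), atol=1e-9
        )

    def test_batch_shift_removed(self, rng):
        n = 40
        values = rng.normal(4, 1, (20, n))
        batches = [1 if i % 2 == 0 else 2 for i in range(n)]
        values[:, np.array(batches) == 2] += 2.0
        expr = _expr(values, ["PE"] * 20 + ["control"] * 20, batches)
        out, diag = pe.batch_center(expr)
        adj = out.values.to_numpy()
        b = np.array(batches)
        per_gene_diff = adj[:, b == 1].mean(axis=1) - adj[:, b == 2].mean(axis=1)
        assert np.abs(per_gene_diff).max() < 0.05
        assert diag["batch_pc1_r2_after"] < diag["batch_pc1_r2_before"]

    def test_condition_signal_survives(self, rng):
        # condition effect orthogonal to batch must not be removed
        n = 40
        conditions = ["PE"] * 20 + ["control"] * 20
        batches = [1 if i % 2 == 0 else 2 for i in range(n)]
        values = rng.normal(4, 0.5, (5, n))
        values[0, :20] += 1.5  # PE-linked signal on gene 0
        values[:, np.array(batches) == 2] += 2.0
        expr = _expr(values, conditions, batches)
        out, _ = pe.batch_center(expr)
        cond = np.array(conditions) == "PE"
        before = values[0, cond].mean() - values[0, ~cond].mean()
        adj = out.values.to_numpy()
        after = adj[0, cond].mean() - adj[0, ~cond].mean()
        assert after == pytest.approx(before, rel=0.1)

    def test_tiny_batch_rejected(self, rng):
        expr = _expr(rng.normal(0, 1, (3, 5)), ["PE"] * 5, [1, 1, 1, 1, 2])
        with pytest.raises(ValueError, match="fewer than 2"):
            pe.batch_center(expr)


class TestRelativeAbundance:
    def test_constant_gene_all_ones(self):
        expr = _expr([[3.0, 3.0, 3.0]], ["PE"] * 3, [1] * 3)
        np.testing.assert_allclose(pe.relative_abundance(expr).to_numpy(), 1.0)

    def test_hand_ratios_linear_scale(self):
        expr = _expr([[1.0, 2.0]], ["PE", "control"], [1, 1])
        # log2 input -> linear 2 and 4, mean 3 -> ratios 2/3, 4/3
        ra = pe.relative_abundance(expr)
        np.testing.assert_allclose(ra.to_numpy()[0], [2 / 3, 4 / 3])

    def test_per_gene_mean_is_one(self, rng):
        expr = _expr(rng.normal(4, 1, (30, 12)), ["PE"] * 6 + ["control"] * 6, [1] * 12)
        ra = pe.relative_abundance(expr)
        np.testing.assert_allclose(ra.mean(axis=1), 1.0, atol=1e-9)


class TestFlagHigh:
    def test_constant_gene_empty(self):
        expr = _expr([[2.0, 2.0, 2.0, 2.0]], ["PE"] * 4, [1] * 4)
        assert pe.flag_high(pe.relative_abundance(expr), "g0") == set()

    def test_infinite_threshold_empty(self, rng):
        expr = _expr(rng.normal(4, 1, (3, 6)), ["PE"] * 6, [1] * 6)
        ra = pe.relative_abundance(expr)
        assert pe.flag_high(ra, "g0", threshold=math.inf) == set()

    def test_unknown_gene_rejected(self, rng):
        expr = _expr(rng.normal(4, 1, (3, 6)), ["PE"] * 6, [1] * 6)
        with pytest.raises(KeyError, match="nope"):
            pe.flag_high(pe.relative_abundance(expr), "nope")

    def test_planted_high_samples_recovered(self):
        cfg = synth.SimulationConfig(seed=11)
        truth = synth.GroundTruth(
            gene_ids=[f"GENE{i:03d}" for i in range(30)],
            erv_ids=[f"ERV{i:04d}" for i in range(60)],
        )
        expr = synth.make_expression(cfg, truth)
        adjusted, _ = pe.batch_center(expr)
        flagged = pe.flag_high(pe.relative_abundance(adjusted), "EPS8L1")
        planted = truth.pe_high_samples | truth.control_high_samples
        agreement = len(flagged & planted) / len(planted)
        assert agreement >= 0.9


class TestHypergeomEnrichment:
    def test_k_zero_is_one(self):
        assert pe.hypergeom_enrichment(pe.EnrichmentInput(10, 5, 5, 0)) == 1.0

    def test_single_term_tail(self):
        p = pe.hypergeom_enrichment(pe.EnrichmentInput(10, 5, 5, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_no_overflow_at_large_n(self):
        p = pe.hypergeom_enrichment(pe.EnrichmentInput(10_000, 5_000, 100, 80))
        assert 0 < p < 1e-8

    def test_matches_scipy_on_cohort_scale(self):
        inp = pe.EnrichmentInput(46, 19, 24, 14)
        assert pe.hypergeom_enrichment(inp) == pytest.approx(
            float(scipy_hypergeom.sf(inp.k - 1, inp.N, inp.K, inp.n)), rel=1e-10
        )

    @given(
        N=st.integers(2, 50),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_exchange_symmetric_in_K_and_n(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        p1 = pe.hypergeom_enrichment(pe.EnrichmentInput(N, K, n, k))
        p2 = pe.hypergeom_enrichment(pe.EnrichmentInput(N, n, K, k))
        assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-300)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            pe.EnrichmentInput(10, 5, 5, 6)


class TestCommonDegCorrelation:
    def test_disjoint_tables(self):
        a = pd.DataFrame(
            {"gene": ["x"], "log2fc": [2.0], "pvalue": [0.001], "padj": [0.01]}
        )
        b = pd.DataFrame(
            {"gene": ["y"], "log2fc": [2.0], "pvalue": [0.001], "padj": [0.01]}
        )
        n, rho, p = pe.common_deg_correlation(a, b)
        assert n == 0 and math.isnan(rho)

    def test_self_comparison_rho_one(self):
        a, _, _ = synth.make_de_tables(synth.SimulationConfig(seed=7))
        n, rho, _ = pe.common_deg_correlation(a, a)
        assert n >= 4
        assert rho == 1.0

    def test_planted_common_set_and_correlation(self):
        cfg = synth.SimulationConfig(seed=7, n_common_degs=25)
        a, b, common = synth.make_de_tables(cfg)
        n, rho, p = pe.common_deg_correlation(a, b)
        assert n == 25
        assert rho >= 0.8
        assert p < 0.01


def test_wilcoxon_de_detects_condition_shift(rng):
    values = rng.normal(4, 0.5, (20, 24))
    values[0, :12] += 2.0
    expr = _expr(values, ["PE"] * 12 + ["control"] * 12, [1] * 24)
    df = pe.wilcoxon_de(expr)
    top = df.sort_values("padj").iloc[0]
    assert top["gene"] == "g0"
    assert top["padj"] < 0.01
    assert top["log2fc"] == pytest.approx(2.0, abs=0.5)
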