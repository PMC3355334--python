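"""Reference-panel generation, regularization, and partial-effect estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eqtlspike as eq
from eqtlspike.panel import PanelConfig, fit_haplotype_effects

from conftest import SMALL_PANEL_CONFIG, manual_panel


class TestGenerate:
    def test_same_seed_bit_identical(self):
        a = eq.generate_reference_panel(PanelConfig(**SMALL_PANEL_CONFIG))
        b = eq.generate_reference_panel(PanelConfig(**SMALL_PANEL_CONFIG))
        assert np.array_equal(a.ref_expression, b.ref_expression)
        assert np.array_equal(a.effects_array, b.effects_array)
        for g in a.genes:
            assert np.array_equal(a.hap_alleles[g], b.hap_alleles[g])
            assert np.array_equal(a.pool_freqs[g], b.pool_freqs[g])
        assert [s.snp_id for s in a.snps] == [s.snp_id for s in b.snps]
        assert a.causal_snp == b.causal_snp

    def test_invariants(self, small_panel):
        p = small_panel
        assert np.allclose(p.ref_correlation, p.ref_correlation.T)
        assert np.allclose(np.diag(p.ref_correlation), 1.0)
        gene_of = {s.snp_id: s.gene for s in p.snps}
        for gene, snp in p.causal_snp.items():
            assert gene_of[snp] == gene
        for gene in p.genes:
            assert abs(p.pool_freqs[gene].sum() - 1.0) < 1e-9
            # every pooled haplotype has a defined partial effect
            for k in range(p.hap_alleles[gene].shape[0]):
                assert np.isfinite(p.partial_effects[(gene, k)])

    def test_realized_frequency_closed_form(self, small_panel):
        """Per-SNP allele frequencies equal pool-frequency-weighted haplotype averages."""
        p = small_panel
        summary = eq.summarize_maf(p)
        mafs = []
        for snp in p.snps:  # brute-force recount from the Haplotype objects
            f = sum(h.pool_frequency * h.alleles[_col(p, snp)] for h in p.pools[snp.gene])
            mafs.append(min(f, 1 - f))
            assert abs(min(f, 1 - f) - snp.maf) < 1e-9
        mafs = np.array(mafs)
        assert abs(summary.mean_maf - mafs.mean()) < 1e-12
        assert summary.n_monomorphic == int((mafs <= 0).sum())

    def test_realized_matches_drawn_targets(self, small_panel):
        """Haplotype pools realize the drawn MAF targets within rounding error."""
        p = small_panel
        realized = np.concatenate(
            [np.minimum(p.pool_freqs[g] @ p.hap_alleles[g], 1 - p.pool_freqs[g] @ p.hap_alleles[g]) for g in p.genes]
        )
        poly = p.target_maf > 0
        assert np.array_equal(realized > 0, poly)  # monomorphic status preserved exactly
        err = realized[poly] - p.target_maf[poly]
        assert np.abs(err).mean() < 0.05  # K=8 pool: coarse but unbiased rounding
        assert abs(err.mean()) < 0.02

    def test_single_haplotype_pool_is_monomorphic(self):
        cfg = PanelConfig(
            n_genes=2, snps_per_gene=[6, 6], haplotypes_per_gene=1,
            n_ref_subjects_study1=10, n_ref_subjects_study2=10, seed=3,
        )
        panel = eq.generate_reference_panel(cfg)
        s = eq.summarize_maf(panel)
        assert s.n_monomorphic == s.n_snps and s.mean_maf == 0.0
        rng = np.random.default_rng(0)
        a = eq.draw_subject_haplotypes(panel, rng)
        b = eq.draw_subject_haplotypes(panel, rng)
        assert a.doses(panel) == b.doses(panel)  # single pool: everyone identical

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            PanelConfig(n_genes=0)
        with pytest.raises(ValueError):
            PanelConfig(haplotypes_per_gene=0)
        with pytest.raises(ValueError):
            PanelConfig(maf_monomorphic_fraction=1.0)


def _col(panel, snp):
    ids = [s.snp_id for s in panel.snps if s.gene == snp.gene]
    return ids.index(snp.snp_id)


class TestSummarizeMaf:
    def test_two_equifrequent_haplotypes_differing_at_one_snp(self):
        panel = manual_panel(
            [
                {"name": "G1", "alleles": [[0, 0], [0, 1]], "freqs": [0.5, 0.5],
                 "effects": [0.1, -0.1], "causal_col": 1},
                {"name": "G2", "alleles": [[0, 1], [0, 1]], "freqs": [0.5, 0.5],
                 "effects": [0.2, -0.2], "causal_col": 1},
            ]
        )
        s = eq.summarize_maf(panel)
        mafs = {snp.snp_id: snp.maf for snp in panel.snps}
        assert mafs["G1_snp1"] == pytest.approx(0.5)  # split 50/50 -> MAF 0.5 by symmetry
        assert mafs["G1_snp0"] == 0.0
        assert s.n_monomorphic == 3  # G1_snp0, G2_snp0, and G2_snp1 (carried by all -> MAF 0)
        assert s.max_maf == pytest.approx(0.5)


class TestRegularize:
    def test_hand_computed_column(self):
        a = pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0]})
        b = pd.DataFrame({"g": [0.0, 1.0, -1.0, 0.5]})
        pooled = eq.regularize_expression(a, b)
        # sample SD of [1,2,3,4] is 1.29099; z-scores as hand-computed
        np.testing.assert_allclose(
            pooled["g"].to_numpy()[:4], [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-6
        )
        assert len(pooled) == 8

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        pooled = eq.regularize_expression(df, df)
        np.testing.assert_allclose(pooled.to_numpy()[:40], x, atol=1e-12)

    def test_per_study_moments(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(2, 5, (30, 4)), columns=list("wxyz"))
        b = pd.DataFrame(rng.normal(-1, 0.2, (20, 4)), columns=list("wxyz"))
        pooled = eq.regularize_expression(a, b)
        for part in (pooled.iloc[:30], pooled.iloc[30:]):
            assert np.abs(part.mean()).max() < 1e-12
            np.testing.assert_allclose(part.std(ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_column_errors_with_names(self):
        a = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [5.0, 5.0, 5.0]})
        b = pd.DataFrame({"g1": [1.0, 2.0, 3.0], "g2": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="g2.*study_a"):
            eq.regularize_expression(a, b)

    def test_mismatched_columns(self):
        a = pd.DataFrame({"g1": [1.0, 2.0]})
        b = pd.DataFrame({"g2": [1.0, 2.0]})
        with pytest.raises(ValueError, match="same gene columns"):
            eq.regularize_expression(a, b)


class TestPartialEffects:
    def test_zero_noise_exact_recovery(self):
        rng = np.random.default_rng(5)
        truth = np.array([0.5, -0.5, 0.2, -0.2])
        counts = np.zeros((30, 4))
        draws = rng.integers(0, 4, size=(30, 2))
        np.add.at(counts, (np.repeat(np.arange(30), 2), draws.ravel()), 1)
        y = counts @ truth
        coef, observed, deficient = fit_haplotype_effects(counts, y)
        assert observed.all() and not deficient
        np.testing.assert_allclose(coef, truth - truth.mean(), atol=1e-10)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(6)
        truth = rng.normal(0, 0.5, size=5)
        n = 200
        counts = np.zeros((n, 5))
        draws = rng.integers(0, 5, size=(n, 2))
        np.add.at(counts, (np.repeat(np.arange(n), 2), draws.ravel()), 1)
        sigma = 0.3
        y = counts @ truth + rng.normal(0, sigma, n)
        coef, _, _ = fit_haplotype_effects(counts, y)
        # conservative per-coefficient SE: sigma / sqrt(copies observed)
        se = sigma / np.sqrt(counts.sum(0))
        assert np.all(np.abs(coef - (truth - truth.mean())) < 3 * (se + se.mean()))

    def test_unobserved_haplotype_flagged_missing(self):
        counts = np.zeros((20, 3))
        counts[:, 0] = 1
        counts[:, 1] = 1  # haplotype 2 never drawn
        y = counts[:, 0] * 1.0 - counts[:, 1] * 1.0
        coef, observed, _ = fit_haplotype_effects(counts, y)
        assert not observed[2]
        assert np.isnan(coef[2]) and np.isfinite(coef[:2]).all()

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            K = rng.integers(2, 6)
            n = 40
            counts = np.zeros((n, K))
            draws = rng.integers(0, K, size=(n, 2))
            np.add.at(counts, (np.repeat(np.arange(n), 2), draws.ravel()), 1)
            y = rng.normal(size=n)
            obs = counts.sum(0) > 0
            Xo = counts[:, obs]
            oracle = np.linalg.solve(Xo.T @ Xo, Xo.T @ y)
            coef, observed, _ = fit_haplotype_effects(counts, y)
            np.testing.assert_allclose(coef[observed], oracle - oracle.mean(), atol=1e-8)

    def test_panel_estimates_track_truth(self, small_panel):
        """Estimated effects correlate with the generating effects per gene
        (standardization makes the scale gene-specific, so compare shapes)."""
        est = eq.estimate_partial_effects(small_panel)
        good = 0
        for g, gene in enumerate(small_panel.genes):
            truth = small_panel.effects_array[g]
            fitted = np.array([est.effects[(gene, k)] for k in range(truth.size)])
            mask = np.isfinite(fitted)
            if mask.sum() < 3 or np.std(truth[mask]) == 0:
                continue
            r = np.corrcoef(truth[mask] - truth[mask].mean(), fitted[mask])[0, 1]
            good += r > 0.8
        assert good >= 12  # almost every gene


@given(st.integers(0, 2**31 - 1))
def test_maf_targets_within_bounds(seed):
    """Drawn MAF mixture respects the [0, 0.5] support for any seed."""
    from eqtlspike.panel import _draw_target_mafs

    rng = np.random.default_rng(seed)
    maf = _draw_target_mafs(rng, 200, PanelConfig())
    assert maf.min() >= 0.0 and maf.max() <= 0.5
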