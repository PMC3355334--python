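"""Spiked-in network: tensor, covariance repair, MVN sampling, titration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import eqtlspike as eq
from eqtlspike.network import (
    _CovarianceCache,
    apply_network,
    build_default_network,
    nearest_spd,
    person_covariance,
    sample_network_expression,
    spike_in,
    titrate_weight,
)
from eqtlspike.shuffle import SimulationConfig, simulate_cohort


@pytest.fixture(scope="module")
def spec(small_panel):
    return build_default_network(small_panel.genes, small_panel.causal_snp)


class TestDefaultNetwork:
    def test_exactly_eight_genes_carry_structure(self, spec):
        G = len(spec.genes)
        off = ~np.eye(G, dtype=bool)
        has_edge = [np.any(spec.tensor[i][off[i]] != 0) for i in range(G)]
        assert sum(has_edge) == 8
        assert len(spec.network_genes) == 8
        assert set(spec.network_genes) == {spec.genes[i] for i in range(G) if has_edge[i]}

    def test_genotype_conditional_edges(self, spec):
        i = spec.genes.index("PCDH19")
        j = spec.genes.index("CDH11")
        assert spec.tensor[i, j, 2, 2] != 0.0
        assert spec.tensor[i, j, 0, 0] == 0.0
        assert spec.tensor[i, j, 0, 2] == 0.0  # either dose 0 switches the edge off

    def test_tensor_swap_symmetry(self, spec):
        t = spec.tensor
        assert np.array_equal(t, np.transpose(t, (1, 0, 3, 2)))

    def test_conditional_slices_need_repair(self, spec):
        """Dose configurations activating the conditional edges give an
        indefinite raw matrix — the repair step is not vacuous."""
        doses = np.zeros(len(spec.genes), dtype=int)
        for g in ("PCDH19", "CDH11", "CDH19"):
            doses[spec.genes.index(g)] = 2
        raw = person_covariance(spec, doses)
        assert np.linalg.eigvalsh(raw)[0] < -1e-6


class TestPersonCovariance:
    def test_lookup_oracle(self, spec):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=len(spec.genes))
        M = person_covariance(spec, d)
        for i in range(len(spec.genes)):
            for j in range(len(spec.genes)):
                expected = spec.tensor[i, j, d[i], d[j]] if i != j else spec.variances[i]
                assert M[i, j] == pytest.approx(expected, abs=1e-12)

    def test_function_of_doses_only(self, spec):
        d = np.ones(len(spec.genes), dtype=int)
        assert np.array_equal(person_covariance(spec, d), person_covariance(spec, d.copy()))

    def test_all_zero_doses_conditional_block_off(self, spec):
        d = np.zeros(len(spec.genes), dtype=int)
        M = person_covariance(spec, d)
        i = spec.genes.index("PCDH19")
        off = np.delete(M[i], i)
        assert np.all(off == 0.0)

    def test_missing_dose_errors(self, spec):
        with pytest.raises(ValueError):
            person_covariance(spec, {g: 0 for g in spec.genes[:-1]})


class TestNearestSpd:
    def test_identity_fixed_point(self):
        r = nearest_spd(np.eye(5))
        assert np.array_equal(r.matrix, np.eye(5))
        assert r.frobenius_shift == 0.0

    def test_psd_input_unchanged(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(6, 6))
        psd = A @ A.T
        r = nearest_spd(psd)
        np.testing.assert_allclose(r.matrix, psd, atol=1e-10)

    def test_indefinite_input_repair_optimal(self):
        """3x3 with eigenvalues (1.5, 0.6, -0.1): PSD output, no farther than
        the one-shot eigenvalue-clipping bound."""
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        w = np.array([1.5, 0.6, -0.1])
        A = (Q * w) @ Q.T
        A = (A + A.T) / 2
        r = nearest_spd(A)
        assert np.linalg.eigvalsh(r.matrix)[0] >= -1e-8
        clip = (Q * np.clip(w, 0, None)) @ Q.T
        clip_dist = np.linalg.norm(clip - A, ord="fro")  # = 0.1, the optimum
        assert r.frobenius_shift <= clip_dist + 1e-8
        assert r.frobenius_shift == pytest.approx(0.1, abs=1e-8)

    def test_asymmetric_input_rejected(self):
        A = np.eye(3)
        A[0, 1] = 1e-3
        with pytest.raises(ValueError, match="symmetric"):
            nearest_spd(A)

    @given(st.integers(0, 10_000))
    def test_output_always_psd(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 4))
        A = (A + A.T) / 2
        r = nearest_spd(A)
        assert np.linalg.eigvalsh(r.matrix)[0] >= -1e-8
        assert np.max(np.abs(r.matrix - r.matrix.T)) < 1e-12


class TestSampler:
    def test_zero_covariance_returns_mean(self):
        mean = np.arange(5.0)
        draw = sample_network_expression(mean, np.zeros((5, 5)), np.random.default_rng(0))
        np.testing.assert_array_equal(draw, mean)

    def test_moment_recovery_2x2(self):
        mean = np.array([1.0, -1.0])
        cov = np.array([[1.0, 0.5], [0.5, 2.0]])
        rng = np.random.default_rng(3)
        draws = np.array([sample_network_expression(mean, cov, rng) for _ in range(10_000)])
        se = np.sqrt(np.diag(cov) / 10_000)
        assert np.all(np.abs(draws.mean(0) - mean) < 4 * se)
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=0.1)

    def test_diagonal_covariance_uncorrelated(self):
        rng = np.random.default_rng(4)
        cov = np.diag([1.0, 2.0, 0.5])
        draws = np.array([sample_network_expression(np.zeros(3), cov, rng) for _ in range(10_000)])
        corr = np.corrcoef(draws.T)
        assert np.max(np.abs(corr[~np.eye(3, dtype=bool)])) < 0.05

    def test_deterministic_given_rng_state(self):
        cov = np.array([[1.0, 0.3], [0.3, 1.0]])
        a = sample_network_expression(np.zeros(2), cov, np.random.default_rng(9))
        b = sample_network_expression(np.zeros(2), cov, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestSpikeIn:
    def test_weight_zero_bit_identical(self):
        base = np.random.default_rng(0).normal(size=15)
        draw = np.random.default_rng(1).normal(size=15)
        assert np.array_equal(spike_in(base, draw, 0.0), base)

    def test_zero_draw_identity(self):
        base = np.arange(15.0)
        assert np.array_equal(spike_in(base, np.zeros(15), 2.0), base)

    def test_weighted_addition(self):
        b = np.array([1.0, -1.0])
        d = np.array([2.0, 4.0])
        np.testing.assert_array_equal(spike_in(b, d, 0.5), [2.0, 1.0])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            spike_in(np.zeros(2), np.zeros(2), -0.1)


class TestApplyNetwork:
    def test_cache_hit_identical_matrix(self, spec, small_panel):
        cache = _CovarianceCache(spec)
        d = np.array([1] * len(spec.genes))
        r1, L1 = cache.factor(d)
        r2, L2 = cache.factor(d.copy())
        assert r1 is r2 and np.array_equal(L1, L2)

    def test_weight_zero_final_equals_baseline(self, small_panel, spec):
        cfg = SimulationConfig(n_subjects=15, seed=3)
        subjects = simulate_cohort(small_panel, cfg)
        apply_network(subjects, small_panel, spec, seed=4, weight=0.0)
        for s in subjects:
            assert np.array_equal(s.expr_final, s.expr_baseline)

    def test_spiked_blocks_visible_in_cohort_correlation(self, small_panel, spec):
        """The empirical correlation matrix of a spiked cohort shows the
        network blocks (nonzero where the tensor is nonzero) while unspiked
        gene pairs stay near the reference correlation."""
        cfg = SimulationConfig(n_subjects=2000, rejection_tol=np.inf, seed=5)
        subjects = simulate_cohort(small_panel, cfg)
        apply_network(subjects, small_panel, spec, seed=6, weight=2.0)
        expr = np.vstack([s.expr_final for s in subjects])
        corr = np.corrcoef(expr, rowvar=False)
        gi = {g: i for i, g in enumerate(spec.genes)}
        assert corr[gi["CDH1"], gi["CDH10"]] > 0.4
        assert corr[gi["CDH19"], gi["PCDH17"]] > 0.3
        # a pair with no tensor edge stays weak
        assert abs(corr[gi["CDH5"], gi["CDH7"]]) < 0.15


class TestTitration:
    def test_bad_weight_lists(self, small_panel):
        cfg = SimulationConfig(n_subjects=10, seed=0)
        with pytest.raises(ValueError):
            titrate_weight(small_panel, cfg, weights=())
        with pytest.raises(ValueError):
            titrate_weight(small_panel, cfg, weights=(1.0, 2.0))
        with pytest.raises(ValueError):
            titrate_weight(small_panel, cfg, weights=(1.0, -0.5))

    def test_weight_zero_detections_near_alpha(self, default_panel):
        """With no spiked signal the causal pairs are detected at ~the false
        positive rate only (the baseline carries no causal-SNP effect)."""
        from eqtlspike.network import detect_causal_pairs

        cfg = SimulationConfig(n_subjects=500, seed=8)
        subjects = simulate_cohort(default_panel, cfg)
        spec8 = build_default_network(default_panel.genes, default_panel.causal_snp)
        apply_network(subjects, default_panel, spec8, seed=9, weight=0.0)
        assert detect_causal_pairs(default_panel, spec8, subjects) <= 3
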