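import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eqtlspike as eq
from eqtlspike.panel import Haplotype, PanelConfig, ReferencePanel, SnpDef

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


SMALL_PANEL_CONFIG = dict(
    snps_per_gene=[12] * 15,
    haplotypes_per_gene=8,
    n_ref_subjects_study1=60,
    n_ref_subjects_study2=50,
    seed=11,
)


@pytest.fixture(scope="session")
def small_panel() -> ReferencePanel:
    """15 genes x 12 SNPs: fast but structurally complete."""
    return eq.generate_reference_panel(PanelConfig(**SMALL_PANEL_CONFIG))


@pytest.fixture(scope="session")
def default_panel() -> ReferencePanel:
    """The contest-scale panel: 7554 SNPs across 15 genes."""
    return eq.generate_reference_panel(PanelConfig(seed=1))


def manual_panel(gene_defs, seed=0, ref_n=50, noise_sd=0.1, dose_shift=0.0) -> ReferencePanel:
    """Build a ReferencePanel by hand from explicit pools and effects.

    gene_defs: list of dicts with keys
      name, alleles ((K, S) 0/1 array), freqs ((K,) summing to 1),
      effects ((K,)), causal_col (int)
    """
    rng = np.random.default_rng(seed)
    genes, snps, pools = [], [], {}
    hap_alleles, pool_freqs = {}, {}
    partial_effects, genotypic_means, causal_snp = {}, {}, {}
    K_max = max(np.asarray(d["alleles"]).shape[0] for d in gene_defs)
    effects_arr = np.zeros((len(gene_defs), K_max))
    expr = np.empty((ref_n, len(gene_defs)))
    counts = {}

    for g, d in enumerate(gene_defs):
        name = d["name"]
        A = np.asarray(d["alleles"], dtype=np.uint8)
        f = np.asarray(d["freqs"], dtype=float)
        e = np.asarray(d["effects"], dtype=float)
        K, S = A.shape
        genes.append(name)
        freq = f @ A
        for j in range(S):
            snps.append(
                SnpDef(
                    snp_id=f"{name}_snp{j}",
                    gene=name,
                    position=1000 + j,
                    alleles=("A", "G"),
                    maf=float(min(freq[j], 1 - freq[j])),
                )
            )
        pools[name] = [Haplotype(name, A[k].copy(), float(f[k])) for k in range(K)]
        hap_alleles[name] = A
        pool_freqs[name] = f
        effects_arr[g, :K] = e
        for k in range(K):
            partial_effects[(name, k)] = float(e[k])
        cj = int(d["causal_col"])
        causal_snp[name] = f"{name}_snp{cj}"
        carrier = A[:, cj].astype(bool)
        m_c = float(f[carrier] @ e[carrier] / f[carrier].sum()) if carrier.any() else 0.0
        m_n = float(f[~carrier] @ e[~carrier] / f[~carrier].sum()) if (~carrier).any() else 0.0
        for dose in range(3):
            genotypic_means[(name, dose)] = dose * m_c + (2 - dose) * m_n + dose_shift * dose

        cdf = np.cumsum(f)
        cdf[-1] = 1.0
        pairs = np.searchsorted(cdf, rng.random((ref_n, 2)), side="right")
        cnt = np.zeros((ref_n, K), dtype=np.int8)
        np.add.at(cnt, (np.repeat(np.arange(ref_n), 2), pairs.ravel()), 1)
        counts[name] = cnt
        expr[:, g] = e[pairs[:, 0]] + e[pairs[:, 1]] + rng.normal(0, noise_sd, ref_n)

    corr = np.atleast_2d(np.corrcoef(expr, rowvar=False))
    np.fill_diagonal(corr, 1.0)
    return ReferencePanel(
        genes=genes,
        snps=snps,
        pools=pools,
        partial_effects=partial_effects,
        genotypic_means=genotypic_means,
        causal_snp=causal_snp,
        ref_expression=expr,
        ref_correlation=corr,
        config=PanelConfig(n_genes=len(genes), snps_per_gene=[hap_alleles[g].shape[1] for g in genes]),
        hap_alleles=hap_alleles,
        pool_freqs=pool_freqs,
        effects_array=effects_arr,
        target_maf=None,
        ref_hap_counts=counts,
    )
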