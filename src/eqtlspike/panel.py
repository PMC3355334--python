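"""Synthetic reference panel: haplotype pools, partial expression effects, genotypic means.

This module builds the stand-in for the pooled real eQTL reference data that seeds the
simulator: 15 cadherin-family gene regions, a SNP panel with a realistic minor-allele
frequency (MAF) spectrum, per-gene haplotype pools with linkage disequilibrium, additive
per-haplotype expression effects, and per-genotype expression means at one designated
causal SNP per gene.  It also implements the cross-study "regularization" (per-study
z-scoring before pooling) and the haplotype partial-effect regression estimator.

The emulation targets are summary statistics of the original pooled panel: 7554 SNPs,
mean MAF 0.17 over all SNPs, 1557 monomorphic SNPs, MAF range 0–0.5.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GENES",
    "SnpDef",
    "Haplotype",
    "PanelConfig",
    "ReferencePanel",
    "MafSummary",
    "PartialEffectEstimate",
    "generate_reference_panel",
    "regularize_expression",
    "estimate_partial_effects",
    "fit_haplotype_effects",
    "summarize_maf",
]

#: Canonical 15-gene cadherin panel used by the contest-style presets.
DEFAULT_GENES = (
    "CDH1", "CDH5", "CDH7", "CDH10", "CDH11",
    "CDH19", "CDH22", "PCDH1", "PCDH7", "PCDH9",
    "PCDH10", "PCDH15", "PCDH17", "PCDH18", "PCDH19",
)

#: Well-known SNP id given to the causal variant of CDH19 (the gene-therapy locus).
CDH19_CAUSAL_SNP = "rs12955865"

_NUCLEOTIDES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SnpDef:
    """One SNP of the panel.  ``maf`` is the realized pool frequency of the alternate
    (minor) allele; alleles are (reference, alternate) nucleotide symbols."""

    snp_id: str
    gene: str
    position: int
    alleles: tuple[str, str]
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError(f"MAF out of [0, 0.5] for {self.snp_id}: {self.maf}")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"alleles must be distinct for {self.snp_id}")


@dataclass(frozen=True)
class Haplotype:
    """One pooled haplotype of a gene: 0/1 alleles over the gene's SNPs (0 = reference)."""

    gene: str
    alleles: np.ndarray
    pool_frequency: float


@dataclass
class PanelConfig:
    """Generator settings for the synthetic reference panel.

    ``maf_beta_params`` parameterizes the non-monomorphic MAF distribution:
    Beta(a, b) truncated to (0, 0.5].  The default (0.8, 1.28) is calibrated so
    that, together with the monomorphic point mass, the mean MAF over *all*
    SNPs is 0.17 (truncated-Beta mean 0.214 × polymorphic fraction 0.794).
    """

    n_genes: int = 15
    snps_per_gene: Sequence[int] | None = None  # default: 7554 split across genes
    flank_bp: int = 10_000
    gene_span_bp: int = 40_000
    maf_monomorphic_fraction: float = 0.206
    maf_beta_params: tuple[float, float] = (0.8, 1.28)
    haplotypes_per_gene: int = 24
    ld_copy_prob: float = 0.8
    effect_scale: float = 0.6
    ref_noise_sd: float = 0.4
    dose_shift: float = 0.4
    causal_maf_target: float = 0.3
    n_ref_subjects_study1: int = 193
    n_ref_subjects_study2: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.haplotypes_per_gene < 1:
            raise ValueError("haplotypes_per_gene must be >= 1")
        if not 0.0 <= self.maf_monomorphic_fraction < 1.0:
            raise ValueError("maf_monomorphic_fraction must be in [0, 1)")
        if self.snps_per_gene is None:
            self.snps_per_gene = _split_counts(7554, self.n_genes)
        self.snps_per_gene = tuple(int(c) for c in self.snps_per_gene)
        if len(self.snps_per_gene) != self.n_genes:
            raise ValueError("snps_per_gene length must equal n_genes")
        if any(c < 1 for c in self.snps_per_gene):
            raise ValueError("snps_per_gene entries must be positive")
        if min(self.n_ref_subjects_study1, self.n_ref_subjects_study2) < 2:
            raise ValueError("reference study sizes must be >= 2")


def _split_counts(total: int, parts: int) -> tuple[int, ...]:
    base, extra = divmod(total, parts)
    return tuple(base + 1 if i < extra else base for i in range(parts))


@dataclass
class MafSummary:
    n_snps: int
    mean_maf: float            # over all SNPs, zeros included
    mean_maf_polymorphic: float
    n_monomorphic: int
    min_maf: float
    max_maf: float


@dataclass
class PartialEffectEstimate:
    """Per-haplotype partial-effect estimates (sum-to-zero centered per gene).

    ``effects`` maps (gene, haplotype index) -> coefficient; haplotypes never
    observed in the reference subjects appear in ``missing`` and carry NaN.
    """

    effects: dict[tuple[str, int], float]
    missing: set[tuple[str, int]]
    rank_deficient: set[str]


@dataclass
class ReferencePanel:
    """The generated reference panel (see module docstring)."""

    genes: list[str]
    snps: list[SnpDef]
    pools: dict[str, list[Haplotype]]
    partial_effects: dict[tuple[str, int], float]
    genotypic_means: dict[tuple[str, int], float]
    causal_snp: dict[str, str]
    ref_expression: np.ndarray          # pooled standardized, [subjects x genes]
    ref_correlation: np.ndarray         # genes x genes, Pearson
    config: PanelConfig

    # dense internals used by the simulator (redundant with the mapping views above)
    hap_alleles: dict[str, np.ndarray] = field(repr=False, default_factory=dict)   # gene -> (K, S_g) uint8
    pool_freqs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)    # gene -> (K,)
    effects_array: np.ndarray = field(repr=False, default=None)                    # (G, K)
    target_maf: np.ndarray = field(repr=False, default=None)                       # drawn targets, all SNPs
    ref_hap_counts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        corr = self.ref_correlation
        if not np.allclose(corr, corr.T, atol=1e-10) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("ref_correlation must be symmetric with unit diagonal")
        gene_of = {s.snp_id: s.gene for s in self.snps}
        for gene, snp_id in self.causal_snp.items():
            if gene_of.get(snp_id) != gene:
                raise ValueError(f"causal SNP {snp_id} is not located in gene {gene}")

    # -- convenience views -------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def gene_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        start = 0
        for gene in self.genes:
            n = self.hap_alleles[gene].shape[1]
            out[gene] = slice(start, start + n)
            start += n
        return out

    def causal_columns(self) -> np.ndarray:
        """Index of each gene's causal SNP within that gene's own SNP block."""
        idx = np.empty(len(self.genes), dtype=np.intp)
        per_gene_ids = {}
        for snp in self.snps:
            per_gene_ids.setdefault(snp.gene, []).append(snp.snp_id)
        for g, gene in enumerate(self.genes):
            idx[g] = per_gene_ids[gene].index(self.causal_snp[gene])
        return idx

    def causal_allele_matrix(self) -> np.ndarray:
        """(genes x haplotypes) alternate-allele indicator at each gene's causal SNP."""
        cols = self.causal_columns()
        G = len(self.genes)
        K = max(self.hap_alleles[g].shape[0] for g in self.genes)
        out = np.zeros((G, K), dtype=np.uint8)
        for g, gene in enumerate(self.genes):
            out[g, : self.hap_alleles[gene].shape[0]] = self.hap_alleles[gene][:, cols[g]]
        return out

    def genotypic_mean_table(self) -> np.ndarray:
        """(genes x 3) expression mean conditional on causal-SNP dose."""
        out = np.empty((len(self.genes), 3))
        for g, gene in enumerate(self.genes):
            for d in range(3):
                out[g, d] = self.genotypic_means[(gene, d)]
        return out


# ---------------------------------------------------------------------------
# generation


def _draw_target_mafs(rng: np.random.Generator, n: int, cfg: PanelConfig) -> np.ndarray:
    """Mixture: point mass at 0, else Beta(a, b) truncated to (0, 0.5]."""
    a, b = cfg.maf_beta_params
    maf = np.zeros(n)
    poly = rng.random(n) >= cfg.maf_monomorphic_fraction
    k = int(poly.sum())
    draws = rng.beta(a, b, size=k)
    bad = draws > 0.5
    while bad.any():  # truncation by redraw
        draws[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = draws > 0.5
    maf[poly] = draws
    return maf


def _carrier_pattern(rng: np.random.Generator, freqs: np.ndarray, target: float) -> np.ndarray:
    """Pick a haplotype subset whose pooled frequency approximates ``target``.

    Greedy over a random permutation (add a haplotype when doing so moves the
    cumulative frequency closer to the target) followed by single-flip local
    improvement, which removes the one-sided overshoot bias of a pure additive
    greedy.  Guaranteed polymorphic (at least one carrier and one
    non-carrier); folded so the pattern is minor.
    """
    K = freqs.shape[0]
    pattern = np.zeros(K, dtype=np.uint8)
    cum = 0.0
    for k in rng.permutation(K):
        w = freqs[k]
        if abs(cum + w - target) < abs(cum - target):
            pattern[k] = 1
            cum += w
    for _ in range(2 * K):  # flip whichever haplotype most improves the match
        signed = np.where(pattern == 1, -freqs, freqs)
        gain = np.abs(cum - target) - np.abs(cum + signed - target)
        k = int(np.argmax(gain))
        if gain[k] <= 1e-15:
            break
        pattern[k] ^= 1
        cum += signed[k]
    if pattern.sum() == 0:
        k = int(np.argmin(np.abs(freqs - target)))
        pattern[k] = 1
        cum = freqs[k]
    elif pattern.sum() == K:
        k = int(np.argmin(np.abs((cum - freqs) - target)))
        pattern[k] = 0
        cum -= freqs[k]
    if cum > 0.5:  # fold: the minor allele is the pattern by convention
        pattern = (1 - pattern).astype(np.uint8)
    return pattern


def _simulate_reference_study(
    rng: np.random.Generator,
    n_subjects: int,
    freqs_by_gene: list[np.ndarray],
    effects: np.ndarray,
    cfg: PanelConfig,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Draw a reference cohort: expression (n x G) on a study-specific scale plus
    per-gene haplotype-count matrices (for the partial-effect regressions)."""
    G = len(freqs_by_gene)
    expr = np.empty((n_subjects, G))
    counts: list[np.ndarray] = []
    # study-specific instrument offset/scale, removed later by regularization
    offset = rng.normal(0.0, 0.3, size=G)
    scale = np.exp(rng.normal(0.0, 0.2, size=G))
    for g in range(G):
        f = freqs_by_gene[g]
        K = f.shape[0]
        cdf = np.cumsum(f)
        cdf[-1] = 1.0
        pairs = np.searchsorted(cdf, rng.random((n_subjects, 2)), side="right")
        cnt = np.zeros((n_subjects, K), dtype=np.int8)
        rows = np.repeat(np.arange(n_subjects), 2)
        np.add.at(cnt, (rows, pairs.ravel()), 1)
        counts.append(cnt)
        raw = effects[g, pairs[:, 0]] + effects[g, pairs[:, 1]]
        raw = raw + rng.normal(0.0, cfg.ref_noise_sd, size=n_subjects)
        expr[:, g] = (raw + offset[g]) * scale[g]
    return expr, counts


def generate_reference_panel(config: PanelConfig | None = None) -> ReferencePanel:
    """Generate the synthetic reference panel.  Deterministic given ``config.seed``."""
    cfg = config if config is not None else PanelConfig()
    rng = np.random.default_rng(cfg.seed)

    genes = list(DEFAULT_GENES[: cfg.n_genes]) if cfg.n_genes <= len(DEFAULT_GENES) else [
        f"GENE{i + 1:02d}" for i in range(cfg.n_genes)
    ]
    G = cfg.n_genes
    K = cfg.haplotypes_per_gene

    snps: list[SnpDef] = []
    pools: dict[str, list[Haplotype]] = {}
    hap_alleles: dict[str, np.ndarray] = {}
    pool_freqs: dict[str, np.ndarray] = {}
    causal_snp: dict[str, str] = {}
    target_maf_all: list[np.ndarray] = []
    effects = np.zeros((G, K))
    causal_carrier: dict[str, np.ndarray] = {}

    gene_start = 1_000_000
    for g, gene in enumerate(genes):
        S = cfg.snps_per_gene[g]
        lo = gene_start - cfg.flank_bp
        hi = gene_start + cfg.gene_span_bp + cfg.flank_bp
        positions = np.sort(rng.choice(hi - lo + 1, size=min(S, hi - lo + 1), replace=False)) + lo
        targets = _draw_target_mafs(rng, S, cfg)
        freqs = rng.dirichlet(np.ones(K))
        alleles = np.zeros((K, S), dtype=np.uint8)

        prev_poly: int | None = None
        realized_target = targets.copy()
        for j in range(S):
            if targets[j] <= 0.0:
                continue  # monomorphic: all-reference column
            if prev_poly is not None and rng.random() < cfg.ld_copy_prob:
                alleles[:, j] = alleles[:, prev_poly]
                realized_target[j] = realized_target[prev_poly]
            else:
                alleles[:, j] = _carrier_pattern(rng, freqs, targets[j])
            prev_poly = j
        realized = freqs @ alleles  # pooled alternate-allele frequency, already <= 0.5

        # alleles: random distinct ref/alt nucleotides per SNP
        ref_idx = rng.integers(0, 4, size=S)
        alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4

        gene_ids = [f"rs{g + 1:02d}{j + 1:04d}" for j in range(S)]

        # causal SNP: polymorphic, inside the gene body, realized MAF closest to target
        body = (positions >= gene_start) & (positions <= gene_start + cfg.gene_span_bp)
        candidates = np.flatnonzero(body & (realized > 0))
        if candidates.size == 0:
            candidates = np.flatnonzero(realized > 0)
        if candidates.size == 0:  # fully monomorphic gene: designate a body SNP anyway
            candidates = np.flatnonzero(body) if body.any() else np.arange(S)
        causal_j = int(candidates[np.argmin(np.abs(realized[candidates] - cfg.causal_maf_target))])
        if gene == "CDH19":
            gene_ids[causal_j] = CDH19_CAUSAL_SNP
            alt_idx[causal_j] = 3  # alternate allele 'T' so the TT edit is dose 2
            if ref_idx[causal_j] == 3:
                ref_idx[causal_j] = 0
        causal_snp[gene] = gene_ids[causal_j]
        carrier = alleles[:, causal_j].astype(bool)
        causal_carrier[gene] = carrier

        # additive per-haplotype expression effects, orthogonalized to the causal
        # carrier status so the causal SNP acts only through the spiked network
        e = rng.normal(0.0, cfg.effect_scale, size=K)
        for group in (carrier, ~carrier):
            if group.any():
                wsum = freqs[group].sum()
                if wsum > 0:
                    e[group] -= float(freqs[group] @ e[group]) / wsum
        effects[g] = e

        for j in range(S):
            snps.append(
                SnpDef(
                    snp_id=gene_ids[j],
                    gene=gene,
                    position=int(positions[j]),
                    alleles=(str(_NUCLEOTIDES[ref_idx[j]]), str(_NUCLEOTIDES[alt_idx[j]])),
                    maf=float(realized[j]),
                )
            )
        pools[gene] = [
            Haplotype(gene=gene, alleles=alleles[k].copy(), pool_frequency=float(freqs[k]))
            for k in range(K)
        ]
        hap_alleles[gene] = alleles
        pool_freqs[gene] = freqs
        target_maf_all.append(realized_target)
        gene_start += 10_000_000  # genes on distinct pseudo-chromosomes; spacing cosmetic

    freqs_by_gene = [pool_freqs[g] for g in genes]
    expr1, counts1 = _simulate_reference_study(rng, cfg.n_ref_subjects_study1, freqs_by_gene, effects, cfg)
    expr2, counts2 = _simulate_reference_study(rng, cfg.n_ref_subjects_study2, freqs_by_gene, effects, cfg)
    df1 = pd.DataFrame(expr1, columns=genes)
    df2 = pd.DataFrame(expr2, columns=genes)
    pooled = regularize_expression(df1, df2)
    ref_expression = pooled.to_numpy()
    ref_correlation = np.corrcoef(ref_expression, rowvar=False)
    np.fill_diagonal(ref_correlation, 1.0)

    partial_effects = {(gene, k): float(effects[g, k]) for g, gene in enumerate(genes) for k in range(K)}

    genotypic_means: dict[tuple[str, int], float] = {}
    for g, gene in enumerate(genes):
        carrier = causal_carrier[gene]
        f = pool_freqs[gene]
        e = effects[g]
        m_c = float(f[carrier] @ e[carrier] / f[carrier].sum()) if carrier.any() else 0.0
        m_n = float(f[~carrier] @ e[~carrier] / f[~carrier].sum()) if (~carrier).any() else 0.0
        for d in range(3):
            genotypic_means[(gene, d)] = d * m_c + (2 - d) * m_n + cfg.dose_shift * d

    return ReferencePanel(
        genes=genes,
        snps=snps,
        pools=pools,
        partial_effects=partial_effects,
        genotypic_means=genotypic_means,
        causal_snp=causal_snp,
        ref_expression=ref_expression,
        ref_correlation=ref_correlation,
        config=cfg,
        hap_alleles=hap_alleles,
        pool_freqs=pool_freqs,
        effects_array=effects,
        target_maf=np.concatenate(target_maf_all),
        ref_hap_counts={gene: np.vstack([counts1[g], counts2[g]]) for g, gene in enumerate(genes)},
    )


# ---------------------------------------------------------------------------
# regularization and estimation


def regularize_expression(study_a: pd.DataFrame, study_b: pd.DataFrame) -> pd.DataFrame:
    """Standardize each study's gene columns to mean 0 / sample SD 1, then pool.

    Cross-platform "regularization": within-study z-scoring (ddof=1) followed by
    row concatenation, so differently assayed expression studies become
    commensurable before any downstream estimation.
    """
    a = pd.DataFrame(study_a).copy()
    b = pd.DataFrame(study_b).copy()
    if list(a.columns) != list(b.columns):
        raise ValueError("studies must share the same gene columns, in the same order")
    out = []
    for name, df in (("study_a", a), ("study_b", b)):
        sd = df.std(ddof=1)
        bad = sd[~(sd > 0)].index.tolist()
        if bad:
            raise ValueError(f"zero-variance expression column(s) {bad} in {name}")
        out.append((df - df.mean()) / sd)
    return pd.concat(out, axis=0, ignore_index=True)


def fit_haplotype_effects(counts: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Least-squares fit of expression on per-haplotype copy counts (0/1/2).

    Returns (centered coefficients with NaN for unobserved haplotypes,
    observed mask, rank_deficient flag).  Coefficients are reported relative to
    the mean effect over observed haplotypes (sum-to-zero convention).
    """
    counts = np.asarray(counts, dtype=float)
    y = np.asarray(y, dtype=float)
    K = counts.shape[1]
    observed = counts.sum(axis=0) > 0
    coef = np.full(K, np.nan)
    if observed.sum() == 0:
        return coef, observed, False
    sol, _, rank, _ = np.linalg.lstsq(counts[:, observed], y, rcond=None)
    rank_deficient = rank < int(observed.sum())
    coef[observed] = sol - sol.mean()
    return coef, observed, rank_deficient


def estimate_partial_effects(panel: ReferencePanel) -> PartialEffectEstimate:
    """Re-estimate per-haplotype partial effects from the panel's reference cohort.

    Emulates the original estimation: per gene, a regression of pooled
    standardized expression on haplotype copy counts.  Haplotypes never drawn
    for a reference subject are flagged missing (NaN), not zero.
    """
    effects: dict[tuple[str, int], float] = {}
    missing: set[tuple[str, int]] = set()
    rank_deficient: set[str] = set()
    for g, gene in enumerate(panel.genes):
        counts = panel.ref_hap_counts[gene]
        y = panel.ref_expression[:, g]
        coef, observed, deficient = fit_haplotype_effects(counts, y)
        if deficient:
            rank_deficient.add(gene)
        for k in range(counts.shape[1]):
            effects[(gene, k)] = float(coef[k])
            if not observed[k]:
                missing.add((gene, k))
    return PartialEffectEstimate(effects=effects, missing=missing, rank_deficient=rank_deficient)


def summarize_maf(panel: ReferencePanel) -> MafSummary:
    """MAF summary recomputed from the realized haplotype pools (not config targets)."""
    mafs = []
    for gene in panel.genes:
        f = panel.pool_freqs[gene] @ panel.hap_alleles[gene]
        mafs.append(np.minimum(f, 1.0 - f))
    maf = np.concatenate(mafs)
    mono = maf <= 0.0
    poly = maf[~mono]
    return MafSummary(
        n_snps=int(maf.size),
        mean_maf=float(maf.mean()),
        mean_maf_polymorphic=float(poly.mean()) if poly.size else 0.0,
        n_monomorphic=int(mono.sum()),
        min_maf=float(maf.min()),
        max_maf=float(maf.max()),
    )
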