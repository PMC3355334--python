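"""Stage 1 — haplotype shuffling with correlation-preserving rejection sampling.

Simulated subjects are built by drawing, independently for each chromosome copy,
one pooled haplotype per gene.  Baseline expression is the sum of the two drawn
haplotypes' partial effects.  A candidate subject is accepted only if appending
its expression vector to the reference expression matrix changes no cell of the
gene-gene Pearson correlation matrix by more than ``rejection_tol`` (default
0.02; a deviation strictly greater than the tolerance rejects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ReferencePanel

__all__ = [
    "SimulationConfig",
    "SimulatedSubject",
    "draw_subject_haplotypes",
    "baseline_expression",
    "accept_candidate",
    "simulate_cohort",
    "dose_matrix",
    "attempt_log",
    "CorrelationGate",
]


@dataclass
class SimulationConfig:
    """Cohort-simulation settings.

    Presets: ``full`` (1000 subjects, the original release size) and
    ``contest_release`` (500 subjects, the size distributed to contestants).
    """

    n_subjects: int = 1000
    rejection_tol: float = 0.02
    max_attempts_per_subject: int = 1000
    spike_weight: float = 0.25
    disease_threshold: float = 2.0
    penetrance_below: float = 0.8
    seed: int = 0

    PRESET_SIZES = {"full": 1000, "contest_release": 500}

    def __post_init__(self) -> None:
        if self.rejection_tol <= 0:
            raise ValueError("rejection_tol must be > 0")
        if not 0.0 <= self.penetrance_below <= 1.0:
            raise ValueError("penetrance_below must be a probability")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimulationConfig":
        if name not in cls.PRESET_SIZES:
            raise ValueError(f"unknown preset {name!r}; expected one of {sorted(cls.PRESET_SIZES)}")
        overrides.setdefault("n_subjects", cls.PRESET_SIZES[name])
        return cls(**overrides)


@dataclass
class SimulatedSubject:
    """One simulated individual.

    ``hap_pair`` holds, per gene (panel order), the indices of the two drawn
    pool haplotypes; ``causal_doses`` the minor-allele count at each gene's
    causal SNP.  Expression vectors follow the pipeline stages: baseline
    (shuffling), network (the genotype-conditional MVN draw), final
    (baseline + weight x network).  ``affected`` stays None until the disease
    model runs.
    """

    family_id: str
    person_id: str
    hap_pair: np.ndarray                  # (genes, 2) int
    causal_doses: np.ndarray              # (genes,) int8
    expr_baseline: np.ndarray | None = None
    expr_network: np.ndarray | None = None
    expr_final: np.ndarray | None = None
    affected: bool | None = None
    attempts: int = 0
    max_deviation: float = float("nan")

    def haplotype_pair(self, panel: ReferencePanel) -> dict[str, tuple[int, int]]:
        return {g: (int(self.hap_pair[i, 0]), int(self.hap_pair[i, 1])) for i, g in enumerate(panel.genes)}

    def doses(self, panel: ReferencePanel) -> dict[str, int]:
        """Minor-allele dose at every SNP (computed on demand from the haplotypes)."""
        out: dict[str, int] = {}
        slices = panel.gene_slices()
        snp_ids = [s.snp_id for s in panel.snps]
        for i, gene in enumerate(panel.genes):
            A = panel.hap_alleles[gene]
            d = A[self.hap_pair[i, 0]] + A[self.hap_pair[i, 1]]
            for j, snp_id in enumerate(snp_ids[slices[gene]]):
                out[snp_id] = int(d[j])
        return out


class CorrelationGate:
    """Fast augmented-correlation deviation via cached reference cross-moments.

    Mathematically identical to appending the candidate row to the reference
    expression matrix and recomputing ``np.corrcoef`` (verified in the tests),
    but O(G^2) per candidate.
    """

    def __init__(self, reference_expr: np.ndarray, reference_corr: np.ndarray | None = None):
        X = np.asarray(reference_expr, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("reference expression matrix must have >= 3 rows")
        self.n = X.shape[0]
        self.s1 = X.sum(axis=0)
        self.sxy = X.T @ X
        self.ref_corr = (
            np.corrcoef(X, rowvar=False) if reference_corr is None else np.asarray(reference_corr, dtype=float)
        )

    def max_deviation(self, candidate: np.ndarray) -> float:
        x = np.asarray(candidate, dtype=float)
        n1 = self.n + 1
        s1 = self.s1 + x
        sxy = self.sxy + np.outer(x, x)
        cov = n1 * sxy - np.outer(s1, s1)
        var = np.diag(cov)
        if np.any(var <= 0):
            return float("inf")
        corr = cov / np.sqrt(np.outer(var, var))
        return float(np.max(np.abs(corr - self.ref_corr)))


def draw_subject_haplotypes(
    panel: ReferencePanel,
    rng: np.random.Generator,
    family_id: str = "0",
    person_id: str = "1",
) -> SimulatedSubject:
    """Draw two independent per-gene haplotypes from the pools (with replacement)."""
    G = len(panel.genes)
    hap_pair = np.empty((G, 2), dtype=np.intp)
    u = rng.random((G, 2))
    for i, gene in enumerate(panel.genes):
        f = panel.pool_freqs[gene]
        cdf = np.cumsum(f)
        cdf[-1] = 1.0
        hap_pair[i] = np.searchsorted(cdf, u[i], side="right")
    causal = panel.causal_allele_matrix()
    rows = np.arange(G)
    doses = (causal[rows, hap_pair[:, 0]] + causal[rows, hap_pair[:, 1]]).astype(np.int8)
    return SimulatedSubject(family_id=family_id, person_id=person_id, hap_pair=hap_pair, causal_doses=doses)


def baseline_expression(subject: SimulatedSubject, panel: ReferencePanel) -> np.ndarray:
    """Per gene: partial effect of haplotype 1 plus partial effect of haplotype 2."""
    G = len(panel.genes)
    out = np.empty(G)
    for i, gene in enumerate(panel.genes):
        h1, h2 = int(subject.hap_pair[i, 0]), int(subject.hap_pair[i, 1])
        e1 = panel.partial_effects.get((gene, h1))
        e2 = panel.partial_effects.get((gene, h2))
        for h, e in ((h1, e1), (h2, e2)):
            if e is None or not np.isfinite(e):
                raise ValueError(f"missing partial effect for gene {gene}, haplotype {h}")
        out[i] = e1 + e2
    return out


def accept_candidate(
    candidate_expr: np.ndarray,
    reference_expr: np.ndarray,
    tol: float,
) -> tuple[bool, float]:
    """Append the candidate to the reference matrix, recompute the correlation
    matrix, and accept iff no cell moved by more than ``tol`` (ties accept)."""
    X = np.asarray(reference_expr, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("reference expression matrix must have >= 3 rows")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("reference expression matrix has a zero-variance column")
    ref_corr = np.corrcoef(X, rowvar=False)
    aug = np.vstack([X, np.asarray(candidate_expr, dtype=float)])
    sd = aug.std(axis=0)
    if np.any(sd == 0):  # degenerate augmented column
        return False, float("inf")
    aug_corr = np.corrcoef(aug, rowvar=False)
    max_dev = float(np.max(np.abs(aug_corr - ref_corr)))
    return max_dev <= tol, max_dev


def simulate_cohort(panel: ReferencePanel, config: SimulationConfig) -> list[SimulatedSubject]:
    """Rejection-sample ``config.n_subjects`` accepted subjects.

    Each subject uses an independent child RNG stream spawned from the root
    seed, so acceptance or rejection of one subject never perturbs another's
    draws.  Raises if any subject exhausts ``max_attempts_per_subject``.
    """
    gate = CorrelationGate(panel.ref_expression, panel.ref_correlation)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    effects = panel.effects_array
    causal = panel.causal_allele_matrix()
    G = len(panel.genes)
    rows = np.arange(G)
    cdfs = []
    for gene in panel.genes:
        cdf = np.cumsum(panel.pool_freqs[gene])
        cdf[-1] = 1.0
        cdfs.append(cdf)

    subjects: list[SimulatedSubject] = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(streams[i])
        for attempt in range(1, config.max_attempts_per_subject + 1):
            u = rng.random((G, 2))
            hap_pair = np.empty((G, 2), dtype=np.intp)
            for g in range(G):
                hap_pair[g] = np.searchsorted(cdfs[g], u[g], side="right")
            expr = effects[rows, hap_pair[:, 0]] + effects[rows, hap_pair[:, 1]]
            dev = gate.max_deviation(expr)
            if dev <= config.rejection_tol:
                doses = (causal[rows, hap_pair[:, 0]] + causal[rows, hap_pair[:, 1]]).astype(np.int8)
                subjects.append(
                    SimulatedSubject(
                        family_id=str(i + 1),
                        person_id="1",
                        hap_pair=hap_pair,
                        causal_doses=doses,
                        expr_baseline=expr,
                        attempts=attempt,
                        max_deviation=dev,
                    )
                )
                break
        else:
            raise RuntimeError(
                f"subject {i} exceeded {config.max_attempts_per_subject} attempts; "
                "consider a larger rejection_tol"
            )
    return subjects


def dose_matrix(panel: ReferencePanel, subjects: list[SimulatedSubject]) -> np.ndarray:
    """(subjects x SNPs) minor-allele dose matrix, SNPs in panel order."""
    n = len(subjects)
    blocks = []
    for i, gene in enumerate(panel.genes):
        A = panel.hap_alleles[gene]
        h1 = np.array([s.hap_pair[i, 0] for s in subjects])
        h2 = np.array([s.hap_pair[i, 1] for s in subjects])
        blocks.append((A[h1] + A[h2]).astype(np.int8))
    return np.hstack(blocks) if blocks else np.empty((n, 0), dtype=np.int8)


def attempt_log(subjects: list[SimulatedSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [s.family_id for s in subjects],
            "person_id": [s.person_id for s in subjects],
            "attempts": [s.attempts for s in subjects],
            "max_deviation": [s.max_deviation for s in subjects],
        }
    )
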