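"""Disease model ("hoomphalitis") and the genotype-edit counterfactual.

Affection status is a threshold/penetrance rule on the sum of final expression
over the 8 network genes: if the sum falls strictly below the threshold
(default 2.0) the subject is affected with probability ``penetrance_below``
(default 0.8); at or above the threshold the subject is unambiguously
unaffected.

The counterfactual models a gene-therapy edit at a causal SNP: remove the
edited gene's contribution from the disease sum, model the edited genotype's
contribution as Normal(effect_mean, effect_sd^2), and integrate the normal
density over the affected region:

    P(affected) = penetrance_below * Phi((threshold - (S0 + effect_mean)) / effect_sd)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import ReferencePanel
from .shuffle import SimulatedSubject

__all__ = [
    "DiseaseModel",
    "CounterfactualQuery",
    "CounterfactualResult",
    "affection_status",
    "assign_affection",
    "remove_gene_effect",
    "counterfactual_affection",
]


@dataclass
class DiseaseModel:
    network_genes: list[str]
    threshold: float = 2.0
    penetrance_below: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance_below <= 1.0:
            raise ValueError("penetrance_below must be a probability")

    def disease_sum(self, expr_final: np.ndarray, genes: list[str]) -> float:
        index = {g: i for i, g in enumerate(genes)}
        try:
            return float(sum(expr_final[index[g]] for g in self.network_genes))
        except KeyError as err:
            raise ValueError(f"missing expression value for network gene {err.args[0]}") from err


def affection_status(
    expr_final: np.ndarray,
    model: DiseaseModel,
    rng: np.random.Generator,
    genes: list[str],
) -> bool:
    """One Bernoulli penetrance draw if the network-gene sum is strictly below
    the threshold; deterministically unaffected otherwise (ties unaffected)."""
    s = model.disease_sum(np.asarray(expr_final, dtype=float), genes)
    if s < model.threshold:
        return bool(rng.random() < model.penetrance_below)
    return False


def assign_affection(
    subjects: list[SimulatedSubject],
    panel: ReferencePanel,
    model: DiseaseModel,
    seed: int | np.random.SeedSequence = 0,
) -> list[SimulatedSubject]:
    """Assign affection to a cohort using a dedicated RNG stream (phenotype
    sampling never perturbs genotype/expression simulation)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    idx = [panel.genes.index(g) for g in model.network_genes]
    draws = rng.random(len(subjects))
    for subj, u in zip(subjects, draws):
        s = float(np.asarray(subj.expr_final)[idx].sum())
        subj.affected = bool(s < model.threshold and u < model.penetrance_below)
    return subjects


def remove_gene_effect(
    subject: SimulatedSubject,
    gene: str,
    panel: ReferencePanel,
    model: DiseaseModel,
    mode: str = "expression",
) -> float:
    """Disease sum with one network gene's contribution removed.

    mode="expression" (default) removes the gene's full realized expression
    value — the arithmetic used in the published worked example.
    mode="network" removes only the spiked network component
    (final - baseline), i.e. the part attributable to the causal SNP's
    genotype-conditional draw.
    """
    if gene not in model.network_genes:
        raise ValueError(f"{gene} is not a network (disease-sum) gene")
    if subject.expr_final is None:
        raise ValueError("subject has no final expression; run the spike-in first")
    g = panel.genes.index(gene)
    base_sum = model.disease_sum(subject.expr_final, panel.genes)
    if mode == "expression":
        contribution = float(subject.expr_final[g])
    elif mode == "network":
        if subject.expr_baseline is None:
            raise ValueError("mode='network' requires baseline expression")
        contribution = float(subject.expr_final[g] - subject.expr_baseline[g])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return base_sum - contribution


@dataclass
class CounterfactualQuery:
    """Edit ``target_snp`` (a causal SNP) of ``subject`` to ``new_genotype``;
    the edited genotype's expression contribution is Normal(mean, sd^2).
    Defaults are the published gene-therapy scenario (TT at the CDH19 locus)."""

    subject: SimulatedSubject
    target_snp: str
    new_genotype: str = "TT"
    effect_mean: float = 0.957
    effect_sd: float = 0.911
    mode: str = "expression"

    def __post_init__(self) -> None:
        if self.effect_sd <= 0:
            raise ValueError("effect_sd must be > 0")


@dataclass
class CounterfactualResult:
    base_sum: float
    sum_without_gene: float
    prob_affected: float
    prob_unaffected: float
    gene: str
    target_snp: str


def counterfactual_affection(
    query: CounterfactualQuery,
    model: DiseaseModel,
    panel: ReferencePanel,
) -> CounterfactualResult:
    """Probability the edited subject remains affected / becomes unaffected."""
    gene = next((g for g, s in panel.causal_snp.items() if s == query.target_snp), None)
    if gene is None:
        raise ValueError(f"{query.target_snp} is not a causal SNP of any gene")
    s0 = remove_gene_effect(query.subject, gene, panel, model, mode=query.mode)
    base_sum = model.disease_sum(query.subject.expr_final, panel.genes)
    z = (model.threshold - (s0 + query.effect_mean)) / query.effect_sd
    p_aff = float(model.penetrance_below * stats.norm.cdf(z))
    return CounterfactualResult(
        base_sum=base_sum,
        sum_without_gene=s0,
        prob_affected=p_aff,
        prob_unaffected=1.0 - p_aff,
        gene=gene,
        target_snp=query.target_snp,
    )
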