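# Methods

This note documents the generative model, the defaults and why they were
chosen, the numerical choices, and what the synthetic reference panel does and
does not emulate.

## Reference panel

The panel stands in for a pooled pair of real eQTL studies of 15
cadherin-family genes.  It is generated, not estimated, so every downstream
quantity has known ground truth.

**SNP panel.** 7554 SNPs split across 15 gene regions (each a 40 kb gene body
± 10 kb flank on its own pseudo-chromosome).  Minor-allele frequencies are
drawn from a mixture: a point mass at 0 with weight 0.206 (monomorphic — SNPs
known to exist but never observed in the pool), otherwise Beta(0.8, 1.28)
truncated to (0, 0.5].  The truncated Beta has mean 0.214, so the expected
mean MAF over *all* SNPs is 0.794 × 0.214 ≈ 0.170 with ≈ 1557 monomorphic
sites — the summary statistics of the emulated pooled panel.  The Beta shape
(0.8) puts substantial mass near zero, echoing the rare-variant excess of real
site-frequency spectra.

**Haplotype pools.** Each gene carries 24 pooled haplotypes with Dirichlet(1)
frequencies.  Allele columns are built SNP-by-SNP: with probability 0.8 a SNP
copies the previous polymorphic SNP's carrier pattern (first-order linkage
disequilibrium, producing the per-locus LD "flares" real panels show),
otherwise a fresh carrier subset is chosen whose pooled frequency best
approximates the drawn MAF (greedy assembly plus single-flip local
improvement; the local improvement removes the one-sided rounding bias a pure
additive greedy has).  Realized frequencies are folded at 0.5 so the stored
alternate allele is always the minor allele.

**Partial effects.** Each haplotype has an additive expression effect drawn
N(0, 0.6²).  Effects are then centered (pool-frequency weighted) *within* the
carrier and non-carrier groups of the gene's causal SNP, so baseline
expression is exactly orthogonal to causal-SNP dose: the causal SNP acts only
through the spiked network.  Without this orthogonalization, chance alignment
between random haplotype effects and carrier status (≈ σ/√K) is easily
"detected" at n = 500 and would contaminate the weight-titration ground truth.

**Causal SNPs.** One per gene: the polymorphic gene-body SNP with realized MAF
closest to 0.3 — common enough that association scans at the release sizes
have meaningful power.  CDH19's causal SNP is named rs12955865 with alternate
allele T, matching the gene-therapy counterfactual convention.

**Genotypic means.** The mean of the network draw for gene *g* at dose *d* is
the carrier/non-carrier decomposition of the realized partial effects (zero
after orthogonalization) plus a shift of 0.4·d — a moderate cis-eQTL effect of
0.4 expression SD per minor-allele copy.  0.4 was chosen a priori so that the
2-fold weight ladder (below) spans "all 8 signals detected" to "a few
detected" at n = 500.

**Reference cohort and regularization.** Two reference studies (193 and 150
subjects, echoing the two source studies) are simulated with per-study
instrument offset/scale distortions and expression noise SD 0.4.
`regularize_expression` z-scores each study per gene (sample SD, ddof = 1) and
concatenates — the cross-platform "regularization" step — and the pooled
matrix defines the reference correlation used by the rejection rule.
`estimate_partial_effects` re-implements the estimation route (per-gene least
squares of pooled expression on haplotype copy counts, sum-to-zero centered,
unobserved haplotypes flagged missing rather than zero); the simulator itself
uses the generating effects, keeping ground truth exact.

## Shuffling and the rejection rule

Subjects are assembled gene-by-gene from the pools (two independent draws per
gene, i.e., Hardy–Weinberg at pool frequencies with free recombination between
genes).  The acceptance test appends the candidate's 15-vector to the
*reference* matrix only — not to previously accepted subjects — so acceptance
decisions are independent and parallelizable; the alternative (accumulating
accepted subjects into the comparison pool) is not implemented.  Comparison
uses Pearson correlation; a candidate is rejected only when some cell moves
strictly more than the tolerance (ties accept).  A `max_attempts_per_subject`
guard (1000) turns pathological configurations into a clear error instead of
a hang.  Each subject consumes an independent child RNG stream spawned from
the root seed, so rejections never perturb later subjects' draws.

With the default panel (reference n = 343) a single appended row moves
correlation cells by O(1/n), so the 0.02 rule rejects rarely; it binds hard
for small reference panels and heavy-tailed candidates, and the acceptance
audit (recomputing the augmented correlation from scratch for every accepted
subject) holds regardless.

## Spiked network

The tensor is stored at full 15 × 15 × 3 × 3 resolution (dose at the row gene
× dose at the column gene).  The shipped default has:

- a 2-gene block CDH1–CDH10 at r = 0.8 (all dose combinations);
- a 4-gene block CDH19–PCDH1–PCDH10–PCDH17 at r = 0.6;
- PCDH19 edges to CDH11 and CDH19 at r = 0.75 active only when **both** genes
  carry at least one minor allele — the genotype-conditional sub-network.

Eight genes carry structure, and those eight drive the disease sum.  The
conditional value 0.75 is deliberately strong enough that active slices are
indefinite (the {CDH19, PCDH19, CDH11} principal submatrix has a negative
eigenvalue), so the nearest-PSD repair is exercised on real inputs, exactly as
an edge-by-edge specified "correlation matrix" requires.

**Nearest-PSD repair** projects to the Frobenius-nearest positive
semi-definite matrix by eigenvalue clipping with symmetry restoration,
iterated to < 1e-7 movement.  Clipping a symmetric matrix *is* the nearest PSD
matrix, so the iteration converges immediately and exists to guard round-off;
no unit-diagonal constraint is imposed (the object is a covariance, not a
correlation, and the diagonal is restored implicitly by the per-gene variances
being PSD-compatible).  Repairs are memoized per distinct dose configuration
of the genes that actually carry dose-varying edges (≤ 3⁸ keys rather than
3¹⁵).

**Sampling** is mean + U√S·z from the SVD of the repaired covariance, one
child RNG stream per subject.  The final convolution is weighted addition,
`final = baseline + weight × draw` — the only operator consistent with
"up-weight to make the network easy to find", and the weight-0 anchor
(final ≡ baseline, bit-identical) is tested.

**Weight ladder.** Releases use the 2-fold descending ladder
(4, 2, 1, 0.5, 0.25).  Titration at n = 500 detects (mean over replicates)
8, 8, 8, ≈ 6–7, ≈ 2–3 of the 8 spiked causal-SNP → gene signals at p < 0.05;
the shipped contest weight 0.25 is the smallest ladder weight detecting at
least one but fewer than all eight.  `titrate_weight` re-derives this curve
and asserts weak monotonicity.

## Disease model and counterfactual

Affection: S = Σ final expression over the 8 network genes; if S < 2.0 the
subject is affected with probability 0.8 (one Bernoulli draw from a dedicated
phenotype RNG stream), otherwise unaffected.  The threshold is strict: S
exactly 2.0 is unaffected — the only total rule consistent with "below the
threshold ⇒ 80% affected" and "exceeding ⇒ unambiguously unaffected".

The genotype-edit counterfactual removes the edited gene's contribution from
the disease sum and treats the edited genotype's contribution as
Normal(μ, σ²) (defaults μ = 0.957, σ = 0.911, the published gene-therapy
scenario), giving

    P(affected) = 0.8 · Φ((2 − (S₀ + μ)) / σ).

`remove_gene_effect` supports two readings of "remove the gene": the full
realized expression value (default — this is the arithmetic that takes a
disease sum of 1.97 to 2.8 when the gene contributes −0.83) or only the spiked
network component (final − baseline).  For the worked scenario
(S₀ = 2.8, μ = 0.957, σ = 0.911) the formula yields P(affected) = 0.0215.  The
historically quoted answer for that scenario (29.69%) cannot be reproduced
from these printed inputs under any arithmetic we are prepared to assert; the
formula above is shipped as the model-consistent answer and the discrepancy is
documented rather than curve-fit.

## Association scans

Single-locus: OLS of expression on minor-allele dose (additive coding, no
dominance term), two-sided t-test, R²; monomorphic SNPs yield flagged records
with NaN statistics rather than silent omission.  Two-locus:
`y ~ a + b + a·b` with the t-test on the interaction coefficient only.  Both
are closed-form vectorized; the two-locus sweep assembles per-pair 4×4 normal
equations from shared cross-moment matrices and is processed in chunks so the
contest-scale shortlist (thousands of SNPs, ~10⁸ pair×gene fits) runs in
bounded memory, with the p < 0.05 report filter applied on the fly.  Aliased
pairs (normalized Gram determinant < 1e-10) are flagged and skipped.  Raw
p-values are reported — no multiple-testing correction by default (a
Bonferroni helper exists but is off), matching how the benchmark data were
distributed.  The report filter is strict: p = 0.05 exactly is excluded.

The default pair shortlist is "SNPs with single-locus p < 0.01 for any gene".
On spiked releases, LD around the causal SNPs plus the network correlations
make this shortlist large (≈ half the panel), so the sweep is quadratic-heavy
by construction; the streaming path keeps it tractable, and `two_locus_full`
gates the complete 7554² sweep.

## What the generator does not emulate

- Cross-gene *baseline* correlation: reference genes are generated
  independently, so the reference correlation matrix is near-identity plus
  sampling noise.  Real pooled data have biological co-expression; here all
  cross-gene structure comes from the spiked network.  A green rejection-rule
  test therefore establishes the rule's soundness, not realism of the
  reference correlation.
- Within-gene dose LD is first-order (pattern copying), not a coalescent;
  fine-scale LD decay and recombination hotspots are out of scope (msprime
  would be the tool if population-genetic realism mattered).
- Genotype imputation, microarray normalization/QC of the source studies, and
  family structure (all subjects unrelated; family IDs are labels).

## Numerical and reproducibility notes

- All randomness flows from integer seeds through `numpy` SeedSequence
  spawning; per-subject child streams make cohorts insensitive to each
  other's rejection histories.  Identical config + seed gives byte-identical
  release files (fixed float formatting, SHA-256 manifest).
- Degenerate inputs: zero-variance expression columns raise with the gene and
  study named; missing partial effects raise with gene/haplotype named;
  rejection exhaustion advises a larger tolerance.
- The 20,000-subject calibration run completes in a few seconds; the full
  acceptance script (including the ~10⁸-fit interaction sweep) in ~4 minutes
  on one CPU.
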