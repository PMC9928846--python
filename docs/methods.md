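# Methods

## Scope and model

`gremlkit` estimates SNP-based (genomic) heritability and genetic
correlations for quantitative traits in related populations — the
setting of livestock herds genotyped on a SNP array, where pedigree
relationships are replaced by a genomic relationship matrix (GRM)
estimated from the markers themselves.

The single-trait model is the animal model

    y = X b + g + e,     g ~ N(0, G σg²),  e ~ N(0, I σe²)

so that V(y) = G σg² + I σe², with G the GRM. SNP heritability is
h² = σg² / (σg² + σe²). The two-trait model stacks both phenotypes (one
record per animal, so the random-effect incidence matrix is the
identity) with

    V = Σg ⊗ G + Σe ⊗ I,

Σg and Σe the 2×2 genetic and residual trait covariance matrices. The
genetic correlation is rG = σg12 / √(σg1² σg2²) and the phenotypic
correlation rP = (σg12 + σe12) / √(Vp1 Vp2).

## GRM estimator

Per-SNP standardized dosages with sample-estimated allele frequencies
(the estimator used by the mainstream GCTA tooling): off-diagonal
entries average (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1 − p_i)) over SNPs
non-missing in both individuals; the diagonal uses the distinct form
1 + mean[x² − (1 + 2p)x + 2p²] / (2p(1 − p)), which captures genomic
inbreeding rather than the squared standardized dosage. Monomorphic
SNPs are excluded entirely; per-pair SNP counts are recorded.

Because allele frequencies are estimated from the sample, each SNP's
standardized dosages sum to ~0 across the sample, so off-diagonals sum
against the diagonal: the mean off-diagonal of an unrelated panel is
−1/(n−1), not 0. Tests assert this sharper expectation.

## Restricted likelihood and optimizer

The restricted log-likelihood is

    logL = −½ [ log|V| + log|X'V⁻¹X| + y'Py ],
    P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹,

with the (n−p)/2·log 2π constant dropped. This convention is fixed so
external grid searches over the same function are comparable.

Fitting is average-information (AI) REML with one EM warm-up iteration
(more are configurable):

* EM update (univariate): σ² ← σ² + (σ⁴/n)(y'P A P y − tr(P A)) for
  A ∈ {G, I}; the matrix generalization
  Σ ← Σ + (1/n)·Σ(Q − T)Σ is used in the bivariate fitter, where Q and
  T collect the per-trait-block quadratic forms and traces. EM steps
  never decrease the likelihood (asserted in tests).
* AI updates θ ← θ + AI⁻¹·score with step-halving (up to 30 halvings)
  whenever a proposed step would decrease the likelihood.
* Variance components are floored at `variance_floor_fraction` × V(p)
  (default 1e-6); under a true h² of zero, estimates pile up at this
  floor rather than going negative.
* In the bivariate fitter Σg and Σe are bent after every update:
  eigenvalues floored at the same fraction of the mean phenotypic
  variance, diagonals floored per trait. This keeps V positive definite
  while letting |rG| approach 1; fits with |rG| ≥ 1 − 1e-3 are flagged
  `boundary`.
* Convergence is |ΔlogL| < `loglik_tolerance` (default 1e-4); hitting
  `max_iterations` (default 100) yields `converged=False`, not an
  exception.

Starting values are half the OLS residual variance for each variance
component (and half the residual covariance for the cross terms) —
bounded, scale-free, and inside the parameter space after bending.

Both fitters rotate the data by the eigenvectors of G once, making V
diagonal (univariate) or block-diagonal in 2×2 blocks λ_i Σg + Σe
(bivariate). Every iteration is then O(n); the rotation is the only
O(n³) step. The rotated likelihood is the dense formula exactly (tests
verify agreement to ~1e-5, the dense inverse's own float error at
n = 200). Eigenvalues of G are clipped at zero — realized GRMs of
related samples are near-singular and tiny negative eigenvalues are
noise.

When G is numerically proportional to the identity, σg² and σe² enter
only through their sum and the AI matrix is singular; the fitters raise
`NonIdentifiableError` rather than return an arbitrary split.

### Standard errors

The sampling covariance of the variance parameters is the inverse AI
matrix at the optimum. SEs of derived ratios use the first-order delta
method: gradient (σe², −σg²)/Vp² for h²; for rG the gradient is
(−rG/2σg1², 1/√(σg1²σg2²), −rG/2σg2², 0, 0, 0) in the parameter order
(σg1², σg12, σg2², σe1², σe12, σe2²), and analogously for rP with the
phenotypic sums. Calibration (empirical SD across simulation replicates
vs mean reported SE, within 30%) is part of the acceptance suite.

### Determinism choice: canonical trait order

Swapping the two traits must permute the estimates exactly. After ~20
AI iterations, floating-point summation order would not guarantee
agreement at 1e-8, so the bivariate fitter internally orders the pair
canonically (lexicographic on the phenotype bytes), fits once, and maps
the results back. Swap symmetry is therefore exact by construction.

## Quality control

Filter cascade (PLINK-conventional order, since the upstream tools do
not document theirs): individual missingness > 10% first; then, with
per-SNP statistics recomputed on survivors, SNP call rate < 90%, folded
MAF < 5%, exact HWE test p < 1e-3. All removal comparisons are strict,
each removed item gets exactly one reason tag, and the cascade is
idempotent.

The HWE test is the standard exact test (not mid-p, not chi-square):
conditional on the observed allele counts, it sums the probabilities of
all heterozygote counts whose probability does not exceed the observed
one. Up to n = 500 the weights are exact integers (multinomial
coefficient × 2^h) and the tail sum is a `Fraction`, so the ≤
comparison involves no rounding; beyond that a log-gamma evaluation
with a 1e-12 relative tie tolerance takes over. Monomorphic SNPs and
singleton alleles return p = 1 (a single configuration exists).

## Relatedness-ceiling pruning

Greedy max-degree elimination: repeatedly remove the individual in the
largest number of above-ceiling pairs, ties broken by removing the
later individual in input order, until no pair exceeds the ceiling.
The rule is deterministic and, on random relatedness structures, within
one individual of the exhaustive optimum (asserted over a 50-case
suite of 12-individual GRMs).

Known limitation: retained count is *not* guaranteed monotone in the
ceiling. On an idealized half-sib herd, a ceiling that admits half-sib
pairs (> 0.25) but not parent–offspring pairs (0.5) makes the greedy
rule remove each sire first (highest degree) and then still break every
dam–offspring pair — one wasted removal per family — whereas a lower
ceiling removes the offspring directly. Monotonicity holds empirically
on unstructured relatedness and in the random-GRM acceptance suite, and
is treated as an empirical property, not an invariant.

## Synthetic data

The generator emulates a two-generation herd: founders drawn binomial(2,
p_i) with p_i ~ U(0.05, 0.5) by default, offspring by gene dropping
(one Mendelian allele per parent per SNP, independent across SNPs).
Full-sib, half-sib, and mixed family designs are supported; expected
GRM entries are 0.5 (full sibs, parent–offspring) and 0.25 (half sibs).
Traits are sampled with exactly the fitted model's covariance —
Σg ⊗ G (realized GRM, 1e-8 diagonal jitter before factorization) plus
Σe ⊗ I — and true breeding values are returned for oracle checks.

What this does *not* emulate: linkage disequilibrium between SNPs
(deliberately absent so expected relatedness stays analytic),
selection, assortative mating, deeper pedigrees, genotyping error, and
the specific 65-herd/487-sire structure of real progeny-testing data.
A green recovery test therefore establishes correctness of the
estimation machinery under the model's own assumptions, not robustness
to LD-induced biases in real array data.

Defaults are one stated world: a half-sib herd of 1,000 animals (45
sires × 10 offspring + 550 founders) at 2,000 SNPs with h² = 0.5 —
the scale at which the recovery properties are quantified. The
`wagyu_default` preset transcribes a published six-carcass-trait
analysis (CW, REA, RT, SFT, YI, BMS) on its reporting scale: Vp and h²
per trait, the reported pairwise rG matrix, and residual correlations
back-computed from the reported phenotypic correlations via
cov_e = rP·√(Vp1 Vp2) − rG·√(Vg1 Vg2). Because those pairwise values
come from separate bivariate fits, the implied 6×6 residual correlation
matrix is very slightly indefinite (min eigenvalue −0.0017); the preset
bends it (eigenvalue floor 1e-4, rescaled to unit diagonal), which
perturbs individual correlations by < 0.02.

## Sweep pipeline

For each ceiling: prune, subset phenotypes by ID intersection (records
missing a phenotype are dropped per fit with a logged count), fit
univariate GREML per trait and bivariate GREML per pair. A `None`
ceiling runs the full data. Rows retaining fewer than `min_n`
individuals (default 50) are flagged skipped; individual fit failures
are recorded in their cell and never abort the sweep. Each row is
exactly reproducible from its (ceiling → prune → fit) provenance.

## Numerical conventions summary

| Quantity | Choice | Default |
|---|---|---|
| logL constant | drop (n−p)/2·log 2π | — |
| convergence | abs. change in logL | 1e-4 |
| EM warm-up iterations | before AI updates | 1 |
| variance floor | fraction of V(p) | 1e-6 |
| bending floor (bivariate) | fraction of mean V(p) | 1e-6 |
| GRM jitter (simulation) | added to diag before Cholesky | 1e-8 |
| G eigenvalues | clipped at 0 | — |
| boundary rG flag | abs(rG) ≥ 1 − 1e-3 | — |
| HWE exact-integer path | total genotype count ≤ | 500 |
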