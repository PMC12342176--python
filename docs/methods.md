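# Methods

This note documents the models behind `popgs`, what the synthetic-data
generator does and does not emulate, the numerical choices, and the
problem sizes the test suite runs at.

## The breeding setting

The package targets clonally propagated tree-breeding programs organised
as multi-generation full-sib families: a small pool of elite parents is
crossed, progeny are genotyped genome-wide and phenotyped for growth
(H in m, DBH in cm) and wood properties (BD in g/cm³, MA in °, FL and FW
in μm), a phenotyped *reference* subset trains prediction models, and the
remaining *breeding* candidates are ranked on genomic estimated breeding
values (GEBVs). Default trait presets are the reference population's
printed moments and narrow-sense heritabilities: H 14.37 ± 1.38 (h² 0.42),
DBH 22.24 ± 4.21 (0.87), BD 0.41 ± 0.03 (0.80), MA 14.21 ± 0.91 (0.13),
FL 1147.45 ± 78.07 (0.14), FW 24.60 ± 2.28 (0.24).

## Synthetic populations

**Founder haplotypes.** Each chromosome is a copy-or-refresh binary
Markov chain: the allele at marker j copies marker j−1 with probability ρ
and is otherwise redrawn as Bernoulli(p_j), with p_j ~ Uniform(0.05, 0.95)
so the MAF ≥ 0.05 QC filter is close to neutral on synthetic panels.
Allele correlation between markers k steps apart is exactly ρᵏ, so
r²(d) = ρ^(2d/s) at marker spacing s and the half-decay distance has the
closed form −log 2 · s / log ρ² — the oracle the LD tests check against.
`rho_for_decay(spacing, target)` inverts it; the study-style preset tunes
ρ so founder LD halves near 16 kb, the reference population's decay
scale. Marginal frequencies are geometrically smoothed versions of the
per-marker draws (tightly linked markers share similar frequencies, as in
real data). Marker positions are evenly spaced, which keeps the decay
closed form exact.

**Gene dropping.** Gametes recombine parental haplotypes with crossover
counts Poisson(genetic length), Haldane map, no interference; crossover
points are uniform in physical coordinates (constant cM/Mb within a
chromosome). Families are spread over generations; later crosses may
recruit earlier progeny as parents. Per-family progeny counts were never
published for the emulated program, so the default is uniform
(24/family × 32 families ≈ the program's 765 trees); both are
configurable.

**Traits.** Sparse additive architectures: n_qtn markers (default 20) get
Gaussian effects (gamma magnitudes with random signs for L-shaped
architectures), scaled so Var(TBV) = h²·σ² and Gaussian noise makes up
the rest, giving phenotypes with approximately the preset mean, SD and
heritability; per-QTN PVE% = 100·2p(1−p)β²/Var(y). The generator does
**not** model dominance or epistasis, genotyping error, shared
environment/block effects, or coalescent ancestry — so passing tests show
the estimators are correct under an additive, environment-free model, not
that real heritabilities or predictive abilities would be reproduced.

All randomness flows from one seed through per-stage spawned streams;
identical configurations are bit-reproducible.

## Quality control

Filters run in a fixed order per marker: missing fraction > 0.02 (the
"detection rate" convention read as per-SNP call rate), MAF < 0.05, then
Hardy–Weinberg P < 1e−6 (SNP-HWE-style exact test below 1000 samples, χ²
above). HWE filtering on a full-sib population removes genuinely
family-distorted markers; the α default keeps only extreme distortions.
Mean imputation fills the real number 2p (float matrices downstream);
mode imputation keeps integer dosages.

## Population structure

The GRM is VanRaden method 1, G = WW′/c with c = 2Σp(1−p); if the
smallest eigenvalue falls below 1e−8·trace/n, εI with ε = 1e−6 is added
(logged) so solvers see a positive-definite kernel. PCA is the
eigendecomposition of G with coordinates scaled by √eigenvalue. NJ trees
use Saitou–Nei agglomeration (scikit-bio) on 1 − allele-sharing
distances; bootstrap support resamples markers and counts bipartitions.
LD is the squared Pearson correlation of dosage vectors (composite,
unphased — PLINK's convention); the decay distance is the first 1-kb bin
midpoint whose mean r² falls to half the maximum bin mean (an absolute
r² < 0.1 alternative is provided, since the half-maximum rule is a
definition choice). Pruning is greedy within 50-SNP windows stepping by
50: each offending pair loses its lower-MAF member (ties: the later
marker), with passes repeated until no surviving within-window pair
exceeds r² = 0.2; the audit in the tests verifies the post-condition
exhaustively. Note that in a closed full-sib population the measured
decay distance exceeds the founder target (family structure adds
long-range background LD); the pipeline reports what it measures.

## Two-stage multi-locus GWAS

Stage 1 fits the null mixed model y = μ + g + e, g ~ N(0, Gσ²g) once by
REML and reuses the variance components for every marker (P3D); each
marker is tested by a GLS Wald χ²(1) after projecting out the intercept
(and optional covariates) in the whitened space. Markers with P < 0.01
are retained. Covariate-collinear and monomorphic markers are excluded
with a diagnostic count. PCA covariates default to none — the emulated
population shows no strong stratification beyond family structure, which
the GRM captures — but the hook accepts any design matrix.

Stage 2 first LD-clumps the retained set (a marker with r² > 0.2 to a
smaller-P retained marker is dropped) so each association signal has one
representative rather than splitting its LOD across neighbours. The
clumped set enters a joint model y = μ + Σx_jβ_j + e with independent
Gaussian effects. Per-marker variances follow the empirical-Bayes sweep
variance_j ∝ β̂_j² + posterior-variance_j, renormalized each sweep until
the relative change drops below 1e−6 (at most 300 sweeps; non-convergence
returns the last iterate with a warning). The *scale* of the variance
vector and σ²e are re-estimated every sweep by maximum likelihood on the
marginal model y ~ N(0, X·diag(v)·X′ + σ²e·I) — evaluated in O(k) per
step through the low-rank spectrum — so null markers collapse toward zero
while real signals keep their variance share; anchoring the total at a
fixed constant instead either over- or under-shrinks depending on how
inflated the winner's-curse stage-1 effects are. The convergence metric
floors collapsed variances at 1e−6 of the total so numerical jitter at
zero cannot keep the sweep alive.

Each marker's LOD is log₁₀ of the ratio of the joint marginal likelihood
with and without that marker (all via the same low-rank form; the tests
check it against scipy's dense multivariate-normal logpdf). Classes:
**significant** = stage-1 P < 0.05/m (Bonferroni) *and* LOD > 3;
**suggested** = LOD > 3 only. PVE uses the pre-model sample variance of
y. Candidate-gene windows take every gene whose span intersects the
closed interval [pos − 16 kb, pos + 16 kb] (the population LD decay
distance), strand-agnostic; a gene ending exactly on the boundary is
included.

## Prediction models

**REML** profiles the restricted likelihood to δ = σ²e/σ²g via the
spectral decomposition of G (coarse log-grid, then bounded refinement to
1e−8 in log δ); flat likelihoods that run into the large-δ boundary
return σ²g = 0 with a flag. **GBLUP** solves the mixed-model equations on
the training block and extends GEBVs to everyone by conditional
expectation ĝ = G[:, t](G_tt + δI)⁻¹(y − μ̂) with a GLS intercept.
**RR-BLUP** uses the dual ridge form â = W′(WW′ + λI)⁻¹(y − μ̂) with
λ = c·δ from REML on the matched GRM; because both use the same kernel,
intercept and shrinkage, their GEBVs agree to numerical precision — the
module's master identity, asserted at 1e−6 relative in every run.

The **Bayesian alphabet** samplers share one single-site Gibbs sweep:
BRR (common marker variance), BayesA (per-marker scaled-inv-χ²(ν=4, S)
variances), BayesB (per-marker variances plus a point mass at zero with
prior weight π = 0.95), BayesC (common variance plus the point mass).
Chains default to 10 000 iterations, 2 000 burn-in, thinning 5; the prior
scale S follows a BGLR-style heuristic assigning half the phenotypic
variance to markers a priori. Fixing the variances turns BRR into exact
Bayesian ridge regression whose posterior mean *is* the ridge solution —
the sampler-correctness oracle. Chains are seed-reproducible; posterior
means, SDs and inclusion frequencies come from thinned post-burn-in
draws.

**ML regressors** run with fixed, documented hyperparameters (RF 500
trees; GBDT depth 3 / 500 rounds / rate 0.1; KRR with RBF kernel at the
median-heuristic bandwidth; ridge and elastic net with the REML-derived
penalty) — no nested tuning, so cross-validation measures the models, not
a tuner. Targets are centered before fitting since kernel ridge has no
intercept.

## Cross-validation and marker selection

Predictive ability is the Pearson correlation between validation-set
phenotypes and GEBVs, computed per fold and averaged over all
repetition × fold cells (identical to fold-then-repetition averaging for
equal fold sizes). Plans are seeded permutations; k = n degenerates to
LOOCV with one repetition. Subsets: random densities (1, 0.5, 0.2, 0.1,
0.05, 0.01), LD pruning (50, 50, 0.2), and GWAS-P thresholds (1 … 1e−4)
where the stage-1 scan runs on the training individuals of each fold
only — the engine's leakage test plants a marker that predicts only
validation phenotypes and asserts the fold-local subset excludes it. An
empty (or single-marker, which cannot form a kernel) subset falls back to
the top-10 smallest-P markers, flagged. Failed cells record their error
and the run continues. Optimal choices are two-phase — best model across
random densities, then best strategy for that model — with ties broken
toward smaller subsets, then faster fits; the relative improvement
(PA_best − PA_full)/PA_full is reported per trait. Whether preselection
beats the full panel depends on the regime: with strong family structure
and moderate marker counts the full-panel GRM already carries the
kinship signal, while in marker-diluted, weakly related panels (m ≫
n_train) fold-internal P ≤ 0.01 preselection raises PA severalfold — the
acceptance script reports both regimes.

## Breeding deployment

Panels are harmonized on shared (chrom, pos) markers; fewer than 50% of
the reference panel shared is a hard error. GWAS-significant QTNs enter
GBLUP as fixed covariates (other models pre-adjust y by OLS on the QTN
dosages and add the fitted component back). Selection takes the top
⌈0.2·n⌉ GEBVs (configurable direction, e.g. minimizing BD for pulp
objectives; ties break by id). Genetic gain is reported on the
predicted-value scale μ̂ + GEBV — percentages of raw GEBVs (mean ≈ 0) are
ill-defined — as 100·(mean_selected − mean_all)/|mean_all|. GCBV is
Σ w_t·z(GEBV_t) with per-trait z-standardization (equal weights on cm and
m scales would otherwise be scale-dependent; a flag disables it) and
default weights H:0.5, DBH:0.5. Kinship networks are bipartite
parent ↔ selected-progeny graphs; each selected progeny adds one count to
its dam and sire, so weights sum to exactly twice the selected count, and
the top-weight dams/sires are reported as core parents.

## Problem sizes and limitations

The suite runs simulations at desk scale — populations of 200–768
individuals and panels of 400–5 000 markers, 5–20 replicates per
stochastic check — chosen so every stage is exercised at the study's
design (32 families, ~765 progeny, six traits) while the whole pipeline
re-runs in minutes. Known limitations: additive-only genetics; a Markov
founder model rather than coalescent ancestry (no allele-frequency
spectrum realism); no phased imputation (mean/mode only, behind an
interface a phased imputer can plug into); single-trait mixed models
(GCBV combines GEBVs post hoc); and the empirical-Bayes refit tests each
clumped representative, so tightly linked causal variants inside one
clump are reported as a single QTN.
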