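# Methods

## The simulator: stepping-stone colonization with polygenic selection

The generator models population allele frequencies, not individuals. A chain
of K demes is colonized left to right: deme 1 holds the ancestral population
(size `Ne_anc`, default 100 000); every `expansion_interval` generations
(default 10) a fraction `founder_fraction` (default 0.01) of the rightmost
occupied deme founds the next deme, which grows to `Ne_cap` (default 10 000)
within one generation. Founding is modeled as a binomial draw of
`2·round(founder_fraction·N_source)` allele copies per locus rather than
individual emigration — adequate because everything downstream consumes
frequencies. With K = 25 demes the last deme is founded at generation 240
and the run ends at generation 260. There is no back-migration between
established demes and no demographic stochasticity beyond the founding step.

Ancestral polymorphism starts from the neutral equilibrium density
f(q) ∝ 1/(q(1−q)), truncated to [1/(2Ne), 1−1/(2Ne)] and sampled by inverse
CDF (the density is flat on the logit scale). New neutral loci arrive as a
Poisson stream (`neutral_mut_rate_per_gen`, default 5) and adaptive loci at
a fixed count per generation (`adaptive_mut_per_gen`, default 3); each new
locus starts at frequency 0.01 in one uniformly chosen occupied deme —
mutations that already survived their earliest, most loss-prone phase.

Selection is genic: `q' = q(1+s_eff)/(1 + q·s_eff)`, applied to adaptive
loci only, with the coefficient interpolated between the two environmental
endpoints: `s_eff(E) = E·s + (1−E)·(1/(1+s) − 1)`. At E = 1 the derived
allele gains s; at E = 0 it pays the reciprocal-fitness cost 1/(1+s) − 1
(≈ −s), the usual trade-off of stress adaptation. Drift is binomial with the
deme's current size. Two environment types are built in: a local patch
(E1 = 1 on demes 5–10 at K = 25) and a geographic cline (E2 rising linearly
over demes 15–25); other K get the same proportional layout.

Traits are polygenic sums of monogenic latent traits (default 15 traits per
environment type × 10 latents each). A latent trait contributes
`2·γ_G·q(causal locus)` per causal locus, with γ_G = −1: the derived,
environmentally favoured allele lowers the trait, so trait and environment
end up negatively correlated. All surviving causal loci of a latent
contribute to the trait even when only one is chosen for observation.

Observation mimics SNP discovery: 10 000 initial-neutral and 500 new-neutral
loci drawn among pooled-polymorphic loci, plus one causal locus per latent
trait (the survivor with the highest across-deme variance; random
tie-break). Fifty diploids per deme are then sampled with dosages
Binomial(2, q) per locus — Hardy–Weinberg and linkage equilibrium within
demes. Individual trait values add Gaussian noise with σ_e = 0.5 × the SD of
genotypic values unless set explicitly. The initial pool default (16 000) is
sized so that ~10 000 initial-neutral loci remain polymorphic at
observation time under the default history.

What the generator does **not** emulate: linkage and LD structure, two-
dimensional geography, back-migration, pleiotropy, dominance, genotyping
error, and ascertainment toward common SNPs. Tests passing on this generator
therefore demonstrate internal consistency of the method chain under clean
drift + selection dynamics, not robustness to those real-data features.

### Scaled scenario

Simulation-based checks run on a desk-scale version (`scaled_scenario`):
K = 10 demes, Ne 2000/1000, 2000 initial neutral loci, 110 generations,
selection s = 0.05 on E1 = demes 3–5, the E2 cline over demes 6–10, five
traits per environment type with four latents each, and 8 adaptive
mutations per generation so most latents acquire a surviving causal locus at
the reduced scale. These sizes keep a full pipeline replicate under ~2 s
while preserving the qualitative structure (founder-driven diversity
gradient, detectable selection, two separable trait blocks).

## Population-specific FST

`psFST_i = Σ_l (M̃_W,l,i − M̃_B,l) / Σ_l (1 − M̃_B,l)` — a ratio of sums
(not a mean of per-locus ratios), with M̃_W the unbiased within-population
matching probability of two distinct alleles and M̃_B the between-pair
matching averaged over **all** population pairs. Matching probabilities are
label-symmetric, so psFST is invariant to allele-orientation flips. Loci
contribute only where both terms are defined (n ≥ 2 alleles); missing data
shrink per-locus denominators rather than being imputed. Standard errors
come from a bootstrap over loci (default 200 resamples) — a resampling
substitute for an asymptotic formula, flagged as such in the output
metadata. The locus-wise global FST used for per-gene top-SNP selection is
the matching-based analogue `(mean_i M̃_W,l,i − M̃_B,l)/(1 − M̃_B,l)`.

## Correspondence analysis

The composite table column-binds minor-allele SNP frequencies (as-is),
min–max scaled trait means, and min–max scaled environments together with
their sign-reversed copies (1 − scaled value), so positive and negative
associations both appear as proximity. Min–max scaling to [0, 1] was chosen
because CA requires nonnegative mass and it puts heterogeneous variables on
the same footing as frequencies; SNP columns are deliberately not reweighted
against the much smaller trait/environment blocks — the ordination is meant
to be dominated by genetic structure (a flag can change this upstream by
subsetting). Missing cells are mean-imputed within column; constant columns
are dropped. The decomposition is the standard SVD of
`D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}`; total inertia equals Pearson χ²/n. Axis
signs follow a fixed convention (largest-|coordinate| column element
positive) so runs are reproducible. Population age colors rescale psFST to
[0, 1] (0 = smallest psFST = oldest); a constant psFST vector degenerates to
0.5 everywhere.

## Association scans

GWAS is ordinary least squares of the individual trait on allele dosage with
population-membership indicators, which absorb the mean structure that the
colonization history creates. After projecting out the population means,
each locus is a simple regression with a two-sided t test on n − K − 1
degrees of freedom. Kinship/mixed-model correction is out of scope; within
the simulator's exchangeable-within-deme individuals the indicator model is
the correct fixed-effects adjustment. Multiple testing uses
Benjamini–Hochberg at α = 0.05 throughout; gene–environment correlations
apply BH within each environment variable.

## Graph fitting

Drift covariance: `W_ij = mean_l (q_il − q̄_l)(q_jl − q̄_l)/(q̄_l(1−q̄_l))`
with the unweighted across-population mean q̄; loci fixed overall are
skipped. The tree is neighbor joining on `d_ij = W_ii + W_jj − 2W_ij`,
branch lengths refit by nonnegative least squares of path distances, rooted
at the attachment node of a user-chosen root population (no automatic
rooting; the root is a modelling decision). Optional admixture edges are
added greedily: each round picks the (source, target, least-squares weight)
triple that most reduces the residual between the observed and graph-implied
covariance, both double-centered because the observed covariance is computed
around the across-population mean. This greedy fit is a deliberate,
deterministic simplification of likelihood-based migration-graph search; an
externally fitted graph can be substituted via the TreeMix readers.

## Per-edge selection parameters

Leaf polygenic scores `Z_i = 2 Σ_j β_j q_ij` over a trait's significant
loci; additive variance `V_A = 4 Σ_j β_j² q̄_j(1−q̄_j)`. Internal node
scores minimize `Σ_e (z_child − z_parent)²/(V_A c_e)` (generalized least
squares under Brownian drift on the graph; admixture targets are constrained
to the weighted mix of their two parents). Per edge we report:

- `raw = (ẑ_child − ẑ_parent)/√(V_A c_e)` — the model-scaled contrast; it
  telescopes exactly along root-to-leaf paths.
- `alpha` — the contrast divided by its **null standard deviation under
  drift**. The naive model SD √(V_A c_e) is miscalibrated twice over: the
  GLS reconstruction absorbs degrees of freedom (deflating contrasts), and
  the dispersion of standardized frequency change depends strongly on allele
  frequency, which a q̄(1−q̄) factor cannot capture. We therefore estimate
  each edge's null variance empirically: panel loci (all genotyped SNPs) are
  binned by pooled frequency (deciles), the mean squared edge contrast is
  computed per bin, and each trait locus contributes β² times its bin's
  value. Scores built from effect sizes assigned to random genotyped loci
  then calibrate to mean ≈ 0, SD ≈ 1 on neutral simulations. Without a
  panel, a Brownian-model quadratic form in the tree covariance is used as
  fallback. Edges with c_e = 0 get α = 0.

Known limitation: trait-associated loci that arose as **new mutations**
during the expansion are geographically concentrated in ways that
frequency-matched standing variation is not, so their α values are
overdispersed (SD ≈ 1.3 in the simulator's neutral runs) even without
selection. The exploratory analysis reads this as candidate selection;
single-edge α values for such architectures should be interpreted by
ranking, not by Gaussian tail probabilities.

## SET matrix and its PCA

Per-trait α vectors on a shared graph are column-bound; traits with no
significant GWAS loci are omitted and reported. Columns are centered and, by
default, scaled to unit variance before the SVD — the per-trait α scales
under the simplified estimator are not guaranteed comparable; a flag
disables scaling. Trait-loading columns are orthonormal, variance
proportions sum to one over all components, and the largest-|loading|
element of each component is made positive for determinism. Component edge
scores are the projections of the (centered, scaled) α rows; an all-zero α
row therefore scores at minus the mean projection, not zero. Environmental
loadings are `Σ_t load(t, k)·r(t, E)` with missing correlations counted as
zero; the loading of a sign-reversed environment is analytically the
negation, so only the raw orientation is materialized.

## Numerical choices and degenerate inputs

- Minor-allele orientation flips a locus iff the pooled n-weighted mean
  frequency exceeds 0.5; an exact tie keeps the reference orientation.
- Genepop: the counted allele is the numerically largest code per locus;
  populations are named by the last token of each block's first individual
  id when unique, else `pop1..popK`; multiallelic loci error unless
  explicitly dropped; missing genotypes are never imputed at the I/O layer.
- psFST with every locus monomorphic everywhere is undefined and raises;
  locus-wise global FST is undefined where the between-matching is 1.
- Tree fitting requires finite distances (raises otherwise); near-zero
  branch lengths are floored only inside the GLS weights (ε = 10⁻⁶ of total
  tree length).
- Ties in top-SNP-per-gene selection break by locus id order; ties in
  causal-locus observation break uniformly at random under the run's seed.
- All randomness flows from a single seeded `numpy` Generator per run;
  CLI commands log their seed.
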