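# Methods

## Model and objective

Genotypes are held samples-as-rows: X is N×M with entries in {0, ½, 1}
(average alternate alleles per haplotype of a diploid call), imputed
entries in [0, 1]. Archetypal Analysis approximates X ≈ αZ with
Z = βᵀX, α (N×K) row-stochastic and β (N×K) column-stochastic, by
minimizing RSS = ‖X − αZ‖²_F. The two stochasticity constraints give
the model 2NK − N − K free parameters (N(K−1) from α, K(N−1) from β),
exposed on the fit object; by contrast an explicit-frequency admixture
model spends KM parameters on its centroids, which is why AA can work
in a rotated, M-independent space and an explicit-frequency model
cannot.

## Projection

`fit_projection` centers the columns of X and computes the thin SVD
X_c = UΣVᵀ, keeping at most N−1 components (centering removes one
dimension) and dropping components with σ ≤ 1e−12·σ_max as numerical
nulls. AA is fitted on the scores X′ = UΣ. Because V is orthonormal,
any quantity built from inner products of rows — pairwise distances,
the RSS of any (α, β) — is identical in score space and centered SNP
space; the test suite asserts this to relative 1e−8 and the fitted-RSS
version to 1e−6. Singular-vector signs are fixed by making the
largest-magnitude entry of each V column non-negative, so repeated runs
and platforms agree bit-for-bit. `truncate` keeps the top-d triplets
for deliberately lossy reduction; a truncated fit evaluated in the full
score space can only do worse than the full-rank fit, never better,
since the solver never saw the discarded variance. `back_project`
returns z·Vᵀ + μ; re-adding the centering mean μ is an interpretation
choice that makes SNP-space archetypes dosage-like and directly
comparable to genotype rows.

## Solver

Sub-problems are non-negative least squares with a soft sum-to-one
constraint: the system is augmented with a row of ones weighted by 1/C
(target 1/C as well) and solved by `scipy.optimize.nnls`, after which
weights are renormalized to the exact simplex. The augmentation
direction matters: with the constraint row at weight 1/C, a *smaller* C
enforces the simplex *harder* (at C = 0.001 the raw solutions sum to
one within ~1e−6); the opposite reading — dividing the data by C — would
invert that behavior and is not used. Defaults C = 0.001, tolerance
T = 0.001 on the relative RSS change |RSS_c − RSS_p|/RSS_p, and 50
iterations maximum. The tolerance is applied to the relative absolute
change rather than its square, since a squared scalar would make T's
scale meaningless.

One alternation step solves every α row against the current archetypes,
then updates β by the classical two-stage center update: the
unconstrained least-squares optimum Z* given α, followed by a
per-archetype simplex-NNLS projection of Z* onto the convex hull of the
data rows, then re-solves α. The projection stage is not provably
monotone in RSS, so a candidate step that would raise the RSS is
rejected and the alternation stops; the recorded RSS trace is therefore
non-increasing by construction, which the tests assert across
randomized configurations. The initial archetypes are themselves
expressed through β before the first iteration so the invariant
Z = Xᵀβ holds at every recorded point. An archetype whose total α mass
collapses to zero is re-seeded to the sample with the largest current
reconstruction residual (standard dead-unit rescue; rarely triggered).

Initialization: FurthestSum by default — first index uniform from the
seed, each later index maximizing the summed Euclidean distance to the
picks so far, ties to the lower index. The original heuristic's
discard-and-reselect of the arbitrary first pick is available as
`reselect_first` (off by default). `random_uniform` draws archetype
coordinates inside the per-dimension data range; `random_sample` picks
K distinct rows. All randomness flows from one integer seed through
`numpy.random.Generator`; `restarts > 1` spawns independent sub-seeds
and keeps the lowest-RSS fit. Explicit `init_indices` allow two runs on
rotated copies of the same data to start identically, which is how the
projection-equivalence checks are phrased.

## Diagnostics

`explained_variance` is 1 − Var(Y − Ŷ)/Var(Y) with population variances
pooled over all entries; it is undefined (raises) for constant Y. RSS
and EV are reported in fit space; by the rotation argument the
full-rank values equal their SNP-space counterparts.

## Genotype I/O

VCF reading uses cyvcf2 and accepts only biallelic SNPs with diploid GT
fields (phased and unphased alike); multi-allelic records, indels and
monomorphic-ALT records are skipped and counted, haploid or
mixed-ploidy calls are an error. Missing genotypes are flagged and
mean-imputed per variant before centering, which keeps each centered
column mean at zero; the missing mask is preserved for provenance.
MAF is min(p, 1−p) of the non-missing column mean (the dosage encoding
makes the column mean the alternate-allele frequency directly), and the
rare-variant filter removes strictly below the threshold — a site at
exactly 0.1 survives the default filter. α matrices are written as
ADMIXTURE-compatible whitespace .Q tables at six decimals with sample
IDs in a sibling file.

## Synthetic panels

`simulate_panel` draws per-population allele frequencies independently
per SNP, uniform in [0.5 − s, 0.5 + s] with spread s = 0.4 by default so
frequencies span [0.1, 0.9] — the common-variant regime left after the
usual MAF ≥ 0.1 cut; ancestry rows come from a symmetric Dirichlet with
concentration 0.3 (realistic mixtures including near-pure individuals);
allele counts are Binomial(2, QF) and dosages counts/2. The generator
deliberately omits linkage disequilibrium, shared drift between
populations (every population's frequencies are independent), mutation
spectra and missingness patterns of real assays. Consequently, passing
recovery tests show the estimator is correct *under the generative
model it targets*; they do not certify behavior under LD pruning
choices or strong drift hierarchies. `add_vertex_individuals` appends
pure-ancestry samples (one-hot Q rows), which matters because AA's
archetypes cannot leave the convex hull of the data: when no pure
individuals exist the archetypes sit at the most extreme admixed
samples and α is compressed accordingly. `write_fixture_vcf` emits
minimal VCF 4.2 for hard calls only; fractional (imputed) dosages have
no GT representation and raise.

## Baselines

`kmeans_binary_alpha` is plain Lloyd iteration (one-hot α,
unconstrained centers). `kmedoids_binary` restricts centers to data
rows: greedy BUILD initialization on the first restart, random
initialization on the rest (10 restarts by default), alternating
Voronoi descent with squared-Euclidean cost and lower-index tie-breaks,
then a best-improvement medoid↔point swap refinement run to
convergence. The swap pass is what lets the method reliably reach the
exhaustive-search optimum on small instances — alternating descent
alone stalls in exchange-reachable local optima; it is skipped above
N = 512 where its quadratic scan would dominate the runtime.
`match_columns` aligns two soft assignment matrices by Hungarian
assignment on the per-column Pearson correlation matrix
(zero-variance columns score 0).

## Problem sizes and numerical choices

The validation suite and the acceptance script run on simulated panels
of roughly N = 20–306 and M = 50–500 — large enough that ancestry
recovery is non-trivial (binomial noise at M = 400 is comparable to the
between-population signal) while the full suite completes in seconds.
Simplex sums are verified to 1e−4 (the post-solve renormalization makes
them exact to machine precision in practice), reconstruction and
rotation identities to 1e−8, and fitted-RSS equivalences to relative
1e−6, reflecting that the last involves tens of NNLS solves whose
active sets may differ between rotated copies at the margin.

## Known limitations

K is an input, not inferred; no cross-validation is provided. The
alternation finds local optima — restarts mitigate but do not remove
this. No LD modeling or pruning, no phasing, no PLINK binary input
(export to VCF or a delimited dosage matrix instead). The explained
variance of AA is bounded by its convex-hull constraint and is expected
to sit below that of unconstrained-centroid methods at the same K; that
is the price of archetypes that correspond to realizable populations.
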