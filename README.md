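# archepop — Archetypal Analysis for population structure

`archepop` estimates genetic cluster structure from diploid SNP genotypes
using Archetypal Analysis (AA): an unsupervised, convex matrix
factorization that plays the same role as ADMIXTURE's **Q**/**F**
decomposition but runs on a dimensionally-reduced representation of the
data, making it orders of magnitude cheaper on biobank-scale panels. It
is aimed at population geneticists who want ADMIXTURE-style ancestry
fractions — and cluster centroids guaranteed to be realizable
populations — without the cost of likelihood maximization over every
SNP.

## The model

Each individual *i* is a genotype vector **x**ᵢ ∈ {0, ½, 1}ᴹ of average
alternate-allele dosages at M biallelic SNPs. For a chosen number of
clusters K, AA finds an N×K matrix **α** of ancestry fractions and an
N×K matrix **β** of archetype weights minimizing the residual sum of
squares

&nbsp;&nbsp;&nbsp;&nbsp;RSS = ‖X − αZ‖²_F,&nbsp;&nbsp; Z = βᵀX,

subject to simplex constraints: every **α** row and every **β** column
is non-negative and sums to one. The rows of Z — the *archetypes* — are
therefore convex combinations of observed individuals (they lie inside
the convex hull of the sample, unlike ADMIXTURE's frequency vectors),
and each individual is in turn a convex combination of archetypes, its
**α** row being directly comparable to an ADMIXTURE **Q** row.

Since N centered genotype vectors span at most N−1 dimensions, the
pipeline first centers X, takes the thin SVD X_c = UΣVᵀ, and fits AA on
the scores X′ = UΣ (N×(N−1)) instead of X (N×M). This is a pure
rotation, so the RSS — and hence the fit — is unchanged while the
working dimension drops from M (often 10⁵–10⁶) to N−1.

The solver alternates constrained non-negative least squares for **α**
and **β**; the simplex constraint is enforced by augmenting each NNLS
system with a sum-to-one row weighted by 1/C (C = 0.001 by default:
smaller C, harder constraint). Iteration stops when the relative RSS
change falls below T = 0.001 or after 50 iterations. Initialization is
FurthestSum by default (greedy max-aggregate-distance selection of seed
individuals), with uniform-random and random-sample alternatives.

Restricting **α** to one-hot rows recovers Lloyd's K-Means; restricting
both **α** and **β** recovers K-Medoids — both are included as
reference reductions (`kmeans_binary_alpha`, `kmedoids_binary`), along
with a binomial admixture simulator (`simulate_panel`) that generates
panels with known **Q**/**F** truth for validation.

## Worked example

Simulate a 3-way admixed panel, write it as VCF, and run the pipeline
(see `examples/` for library-level walkthroughs of every capability):

```bash
python - <<'EOF'
from archepop.simulate import simulate_panel, write_fixture_vcf
panel, truth = simulate_panel(120, 400, 3, seed=5)
write_fixture_vcf(panel, "demo.vcf", seed=6)
EOF
archepop --input demo.vcf --k 3 --seed 7 --out demo -v -v
```

which logs

```
INFO archepop.genotype_io: read_vcf: 120 samples x 400 biallelic SNPs
INFO archepop: 400 variants after MAF >= 0.1 filter
INFO archepop: SVD: 119 scores retained (0.01s)
INFO archepop: AA: K=3, 4 iterations, converged=True, RSS=4927.54, EV=0.1732 (0.02s)
INFO archepop: wrote demo.{alpha.Q,beta.txt,archetypes.txt,report.json}
```

`demo.alpha.Q` holds one row per individual, e.g.

```
0.000000 0.646622 0.353378
0.095826 0.580413 0.323761
0.943380 0.000000 0.056620
```

Row 1 is an individual estimated as a 65/35 mixture of archetypes 2 and
3; row 3 is nearly pure archetype 1. RSS is the residual sum of squares
of the score-space reconstruction and EV the pooled explained variance
1 − Var(X′ − αZ)/Var(X′); with only 400 simulated SNPs most variance is
binomial sampling noise, so an EV of 0.17 at K=3 is expected.
`demo.archetypes.txt` gives each archetype as an M-vector of
frequency-like dosages, every entry inside the observed range.
`--plots` adds a compositional (polygon) plot and an ADMIXTURE-style
stacked bar plot.

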