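# Methods

## The TWAS statistic

For a gene with harmonized cis-eQTL weights `w` over m SNPs, GWAS z-scores
`z` over the same SNPs, and LD correlation `V` estimated from a reference
panel, the imputed-expression association is `Z = w'z / sqrt(w'Vw)`. Under
the null hypothesis that the trait is independent of the gene's predicted
expression, `z ~ MVN(0, V)` and `Z ~ N(0, 1)`; the reported p-value is the
two-sided normal tail. The statistic is invariant to SNP ordering and to
allele relabeling (simultaneous sign flips of w, z and the corresponding
rows/columns of V), which the test suite asserts as properties.

Harmonization aligns weights and GWAS records to the panel's allele
orientation: swapped a1/a2 flips the sign of the corresponding w or z entry,
strand-ambiguous SNPs (A/T, C/G) are dropped by default (flag to retain —
without strand information their orientation is unresolvable), and SNPs
missing from the GWAS or panel are dropped with the statistic recomputed on
the remaining set rather than imputed. A gene with no surviving SNP is a
logged skip, never an abort; the scan reports an attrition table
(MHC-excluded / no usable SNPs / monomorphic / degenerate predictor) so the
difference between weights on disk and genes tested is auditable.

Genes overlapping the extended MHC (chr6:28,477,797–33,448,354, hg19,
1-based inclusive; configurable) are excluded because its long-range LD
invalidates the local-LD assumptions of the statistic. The Bonferroni
threshold uses the number of genes actually tested, not the number of weight
sets supplied. All internal coordinates are 1-based inclusive; BED input is
converted at the parse boundary.

Numerical guards: `w'Vw <= 1e-8` raises a degenerate-predictor error; LD
matrices are PSD-repaired by eigenvalue clipping at 1e-8 only when the
smallest eigenvalue is below −1e-8 (sample correlation matrices are PSD up
to rounding), and the clipped mass is recorded; two-sided p-values are
floored at the smallest positive float so probit and log transforms stay
finite out to |Z| ≈ 40.

## Loci, conditional analysis, GWAS conditioning

Significant genes whose boundaries lie within 500 kb are merged into loci,
chained transitively (A–B and B–C within the window places all three in one
locus). Boundary-to-boundary distance is used rather than midpoints — the
more inclusive reading, which errs toward analysing correlated genes jointly.

Within a locus the TWAS z-vector is treated as multivariate normal with
covariance Omega, the correlation of predicted expression across panel
individuals (identical to `w~'Vw~` on standardized dosages). The conditional
z of gene i given a retained set R is

```
z_i|R = (z_i − Ω_iR Ω_RR⁻¹ z_R) / sqrt(1 − Ω_iR Ω_RR⁻¹ Ω_Ri)
```

applied in a backward-elimination loop: while any retained gene's
conditional p exceeds the locus-wide threshold `0.05/(2·N)` (pairwise-testing
correction), the gene with the largest conditional p is dropped (ties broken
by smaller |marginal z|, then lexicographic id — the selection order is a
declared choice; forward selection would differ only at loci with 3+
mutually correlated signals). Survivors are conditionally independent;
eliminated genes carry the conditional statistics they had when dropped. A
ridge of 1e-6 stabilizes Ω inversion and is logged when material; genes
fully collinear with the retained set get conditional z = 0.

GWAS conditioning treats each SNP s and the gene predictors as jointly
normal: the SNP–predictor correlation is `ρ_sg = (Vw_g)_s / sqrt(w_g'Vw_g)`,
and the conditioned SNP score follows the same MVN formula with Omega as the
predictor covariance. The sentinel is the max-|z| SNP of the locus; the
locus is *explained* when the sentinel's conditional two-sided p rises to at
least 5×10⁻⁸ (configurable). SNPs numerically collinear with the predictor
space (`ρ'Ω⁻¹ρ ≥ 1 − 1e-8`) are flagged fully-explained rather than given an
undefined quotient.

TWAS loci are labelled *known* when within 500 kb of any supplied GWAS risk
interval, else *novel*.

## Competitive gene-set enrichment

Gene scores are `y_g = Φ⁻¹(1 − p_g)` on the two-sided TWAS p — the
MAGMA-style probit score, oriented so stronger association gives larger y
and enrichment coefficients are positive. The per-set model is

```
y = β₀ + β_set·m + β_len·log(length) + β_snp·log(n_snps) + u + ε
u ~ N(0, σ²_K K),  ε ~ N(0, σ²_e I)
```

Nearby genes share eQTL SNPs and LD, so their TWAS scores are correlated
even under the null; K — the gene×gene correlation of predicted expression
imputed into the reference panel — absorbs this as a random effect. K is
sparsified (entries zeroed across chromosomes, for boundary gaps over 5 Mb,
or when r² < 1e-4) and, because zeroing can break positive semi-definiteness,
repaired by clipping negative eigenvalues at zero and re-normalizing the
diagonal to 1; the clipped eigenvalue mass is recorded on the object.

With a single random effect, REML reduces to one eigendecomposition of K:
rotating by the eigenvectors diagonalizes the covariance to
`σ²_e(γΛ + I)` with variance ratio `γ = σ²_K/σ²_e`, leaving a 1-D bounded
optimization of the restricted likelihood over log γ (with an explicit γ = 0
comparison and a log-scale grid fallback on non-convergence). β_set and its
standard error come from GLS at the optimum. The eigendecomposition is done
once per K; testing another set only rotates its membership column, so
thousands of sets or simulation replicates are cheap. When the fitted ratio
is zero the estimates equal OLS exactly (asserted in tests). Covariate
columns linearly dependent on earlier ones (e.g. a constant gene length) are
dropped with a log entry; a membership column collinear with the covariates
is an error.

The enrichment p is one-sided (β_set > 0), the competitive-test convention;
the two-sided p is also emitted. The Wald reference is normal rather than t —
with thousands of genes the difference is negligible. Sets with fewer than
10 scored (cis-heritable, TWAS-tested) genes are excluded before testing,
and BH-FDR is computed over the tested sets only. Whether covariates should
be log-scaled and whether the r² filter applies to predicted-expression
correlation (the reading implemented here) or to some SNP-level LD summary
were genuinely open choices; both defaults are flagged and overridable.

## Summary statistics

The direction-of-effect test is an exact two-sided binomial test against 0.5
(minimum-likelihood two-sidedness). The paired-score comparison uses Pearson
product-moment correlation (a Spearman option exists) with a Fisher-z 95% CI
and a t-reference p on n−2 d.f. The two-proportion comparison is a 1-d.f.
Pearson χ² on the 2×2 table, continuity correction off by default (the
intended use is large-sample).

## The synthetic-data generator

The generator encodes the minimal model under which the TWAS statistic is
calibrated; it defines the study conditions for every simulation-based test.

- **Panel.** Two latent standard-normal AR(1) chains per individual
  (adjacent-SNP correlation ρ, default 0.8) thresholded at Φ⁻¹(MAF) give
  haplotype allele indicators; dosages are their sums. This yields
  Hardy–Weinberg genotypes whose LD decays monotonically with SNP lag at the
  exactly computable threshold-attenuated value (asserted against the
  bivariate-normal closed form). MAFs are uniform on (0.05, 0.5). Default
  panel size 500 individuals, matching the scale of a 1000 Genomes
  subpopulation reference.
- **Layout.** One synthetic chromosome, genes at 1 Mb spacing with 20-kb
  bodies and SNPs within ±250 kb, so both the 500-kb locus merge and the
  5-Mb K-sparsification rules are exercised with non-trivial outcomes.
- **Weights.** Per gene, n_causal (default 3) SNPs receive normal weights
  scaled so the predicted-expression variance in the panel equals cis-h²
  (default 0.2); expression realisations add N(0, 1−cis-h²) noise. Marginal
  SNP–expression z-scores are recorded to populate top-eQTL columns.
- **GWAS z.** `z = Σ_g λ_g V w~_g + ε`, `ε ~ MVN(0, V)` via Cholesky of
  `V + 1e-6·I` (the ridge guards the rank deficiency of an n-individuals <
  m-SNPs sample correlation). By construction gene g's TWAS statistic has
  expectation λ_g and unit variance, so λ is a per-gene non-centrality dial:
  0 for null genes, with the planted-set enrichment added as `λ += shift`.
- **Gene sets.** Uniform random sets within a size range; the first set is
  the designated planted set.

All four generators take explicit seeds and are bit-reproducible; a study is
seeded from one `SeedSequence` spawn.

What the generator does **not** emulate: real human haplotype structure
(block boundaries, recombination hotspots), population stratification,
trans-eQTLs, allele-frequency–dependent effect sizes, multiple weight
training models, or imperfect summary-statistic imputation. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated model, not that any particular biological result would
replicate.

## Simulation sizes used in tests and the acceptance script

Chosen so the whole suite runs on one CPU in a few minutes while keeping
each assertion's sampling error well inside its band:

- Null scan calibration: 200-gene all-null studies, KS vs N(0,1) at α=0.01
  over 10 fixed seeds (tests) / 20 derived seeds (acceptance script).
- Oracle agreement: 100 random instances per statistic (≤5 SNPs / 2–3 genes
  / ≤50 p-values), tolerances 1e-12 (TWAS) and 1e-10 (conditional, BH).
- Enrichment calibration: K from a 1000-gene synthetic study;
  1000 null-membership fits (100-gene sets) for type-I at α=0.05, 200 fits
  with planted β_set = 0.6 for recovery, variance split σ²_K=0.3/σ²_e=0.7.
- Planted-set detection: full pipeline at 1000 genes, 15 sets of 100–150
  genes, λ shift 1.0 — a competitive test's power scales with set size, so
  set sizes are chosen for ~4.5σ expected enrichment while keeping sets a
  small fraction of the genome (large relative sets leak signal into
  overlapping null sets and genuinely reduce discrimination).
- Mediation conditioning: a 3-gene locus with λ = (8, 0, 0), 100 GWAS
  replicates; the TWAS-nominated gene is conditioned out and the sentinel's
  conditional p compared with 5×10⁻⁸.

## Known limitations

- The conditional analysis treats Omega as known; reference-panel noise in
  Omega is ignored (as is standard for summary-statistic conditioning).
- PSD repair of K slightly perturbs the zeroed entries; the pre-repair
  matrix is available (`psd_repair=False`) and the perturbation is bounded
  by the clipped eigenvalue mass.
- The scan drops missing-in-GWAS SNPs rather than imputing weights to the
  remaining LD structure; with sparse GWAS coverage this loses power
  relative to summary-statistic imputation.
- Weight training from expression data, cross-tissue scans, fine-mapping of
  TWAS loci and colocalization are out of scope.
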