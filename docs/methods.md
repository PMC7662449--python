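# Methods

This note documents the statistical models implemented in `gbckit`, the
defaults and numerical choices, what the synthetic generator does and does
not emulate, and known limitations.

## Data model

Genotypes are biallelic SNP dosages counting a designated allele A:
0, 1 or 2 copies, with an explicit missing mask. The regression coding
(AA = 1, AB = ½, BB = 0) — the within-individual allele-A frequency — is
`dosage / 2`, produced at the point of use. A single internal canon serves
both the regression/path estimators (which want the 0–1 scale) and the
admixture likelihood (which wants counts out of 2).

Reference breeds enter as a SNPs × breeds table of allele-A frequencies
`x_ij ∈ [0, 1]` with per-cell allele counts. `allele_frequencies` computes
them from labeled genotypes as Σ dosage / (2 × non-missing animals);
`align_panels` intersects a genotype panel with a frequency table, keeping
the frequency table's SNP order so outputs are bit-reproducible.

## Adjusted linear regression

Per animal, ordinary least squares with intercept of the 0–1 coded genotype
vector on the K reference frequency columns, over loci complete in the
target and in every breed. The coefficient vector is mapped to the simplex
by clamping negatives to zero and rescaling to unit sum. The clamp-then-
rescale rule is the simplest policy consistent with bounded, unit-sum
proportions; it is deliberately a *post hoc* adjustment (no non-negative
least squares by default) so the raw fit remains an ordinary OLS whose
coefficients, residual variance and design condition number (ratio of
extreme singular values of the centered design) are reported for
diagnostics. The intercept is always fitted but never enters the simplex.

## Supervised admixture likelihood

Dosages are Binomial(2, f_i) under HWE with mixture frequency
f_i = Σ_j x_ij w_j. The optimized objective is
L(W) = Σ_i [y_i ln f_i + (2 − y_i) ln(1 − f_i)]; the binomial constant
Σ ln C(2, y_i) is independent of W and omitted, also from the reported
log-likelihood. Reference frequencies are estimated a priori and treated as
known (supervised mode only; joint estimation of frequencies is out of
scope).

Constraint handling: raw weights are kept non-negative by box constraints
and the objective is evaluated at w / Σw (sum-scaling), with the returned
vector renormalized — a bound-constrained quasi-Newton (L-BFGS-B) with the
analytic gradient, chain-ruled through the rescaling. Pure sum-scaling
without the non-negativity box is available (`nonneg=False`) since the
rescaling alone does not preclude negative weights. Defaults: uniform
initialization 1/K, relative objective tolerance 1e-10, gradient norm 1e-8,
at most 500 iterations; non-convergence is flagged and the best iterate
returned, never silently. An ascent guard returns the initial point if the
optimizer somehow ends below it.

Mixture frequencies are clipped to [ε, 1−ε] with ε = 1e-6 so monomorphic
reference SNPs cannot produce ln 0; panels cleaned of monomorphic SNPs are
unaffected by the clip.

## Path analysis

Standardizing the regression equation (mean 0, sample SD 1, n−1
denominator throughout) turns the coefficients into path coefficients
p_yx_j = b_j σ_xj / σ_y. Equivalently the path coefficients solve the
correlation system R_xx p_yx = r_yx, where r_yx stacks the correlations of
the target with each breed column and R_xx is the breed correlation matrix.
Both routes are implemented (`solve_path_coefficients`,
`path_from_regression`) and agree to solver precision; the correlation route
solves the linear system directly rather than inverting R_xx, and refuses
matrices whose condition number exceeds a configurable cap (default 1e8),
naming the most correlated breed pair.

Determination decomposition:

- direct determination: p²_j;
- combined determination: d_j = p_j (R_xx p)_j = p²_j + Σ_{j′≠j} p_j r_jj′ p_j′;
- residual: R = 1 − Σ_j d_j, the squared residual path coefficient
  (coefficient of alienation p_ye = √max(0, R)).

The decomposition identity Σ d_j + R = 1 holds exactly because
Σ d_j = p′ R_xx p and r_yx = R_xx p reproduce the target's unit variance.
Strong positive cross terms can push Σ d_j above 1, i.e. R < 0; p_ye is then
clamped to 0 with a warning while the raw signed R is retained. The
composition ratios remain well defined because they never use R.

Compositions: D-GBC_j = p²_j / Σ p² and C-GBC_j = d_j / Σ d. Negative
combined components (possible with negative correlations or coefficients)
are clamped to zero and the remainder renormalized, flagged on the
estimate; the raw signed values stay in `PathSolution` for diagnostics.
The reliability of a combined composition is reported as 1 − R. The
residual-vs-reliability semantics are intentionally reported as the pair
(R, 1 − R): R is the unexplained variance share, 1 − R the explained share;
consumers choose which to threshold. Correlations are Pearson by default
(frequency relationships between breeds are close to linear); Spearman with
average ranks for ties is available for monotone-but-nonlinear settings.
Correlations use pairwise-complete observations; regression and likelihood
fits drop loci missing in the target animal — per-animal estimators should
not discard a locus merely because some other column is missing elsewhere.

The target of `estimate_path_gbc` can be one animal's dosage vector
("genotype data" mode, rescaled by ½ internally) or a composite population's
frequency vector ("correlation data" mode, e.g. the pooled mean dosage / 2);
correlations, unlike the likelihood, are indifferent to which of the two
scales carries the signal.

Interpretation note: on an idealized HWE mixture with weights w and
exchangeable, uncorrelated breeds, the path coefficients are proportional
to w, so D-GBC estimates w²_j / Σ w² rather than w itself. The path
measures quantify relative *variance determination* — the causal question —
not the admixture weights; the regression and likelihood estimators target
the weights. The test suite checks exactly these semantics.

## Path diagrams

`PathDiagram` holds causal edges (a DAG, validated by topological sort)
carrying path coefficients, plus correlation arcs restricted to exogenous
nodes. Tracing follows the rules sufficient for two-layer breed pedigrees:
a traced path is a directed chain, or exactly one correlation arc leaving
the source followed by a directed chain; no node repeats. The compound-path
coefficient is the product of its segment coefficients. The determination
of a sink by a source is the sum of squared directed-path coefficients plus
cross terms between each directed path and each arc-initiated path — on a
single-layer diagram this reproduces `combined_determination` exactly, and
on the packaged Ultrablack diagram it reproduces the pedigree shares
0.8125 / 0.1875. Deeper tracing classes (arcs mid-path, bidirectional
passes) are out of scope and documented as such.

## Reference QC and SNP panels

Purity score: −2 × mean per-locus log10 HWE genotype probability of the
animal's dosages under its claimed breed's frequencies (clipped at 1e-6).
A raw likelihood is ≤ 1 everywhere, so a cutoff of 2 is only meaningful on
a normalized negative-log scale; per-locus averaging makes the score — and
the default cutoff 2, i.e. mean genotype probability 10⁻¹ — independent of
panel size. Base and normalization are configurable. Frequencies include
the scored animal by default; leave-one-out recomputation is available and
markedly sharpens separation in small panels (the scored animal cannot
vouch for itself).

Uniform panels: chromosomes receive counts proportional to their bp span
(largest-remainder rounding, capped by availability), an even grid is laid
over each span (midpoint when a chromosome gets one pick), and the nearest
unused SNP to each grid point is taken. Deterministic, duplicate-free,
sorted by (chrom, pos). This is a grid-nearest design; MAF- or LD-aware
panel selection is out of scope.

## Synthetic data

Reference breeds follow the Balding–Nichols construction: per SNP an
ancestral frequency p0 ~ Uniform(0.1, 0.9), then each breed's frequency
~ Beta(p0 (1−F)/F, (1−p0) (1−F)/F). The single parameter F acts as an Fst:
the between-breed correlation induced by the shared ancestor is
Var(p0) / (Var(p0) + F·E[p0(1−p0)]), so small F means near-identical breeds.
Because that correlation cannot fall below ≈ 0.35 for any F < 1 at this
ancestral spread, *unrelated* breeds are built from independent ancestral
draws (correlation ≈ 0), and *related* pairs from a shared intermediate
ancestor: the Beefmaster-like scenario draws the correlated pair with
F_intermediate = 0.02 and F_pair = 0.45, fixed once from the moment formula
to target r ≈ 0.4 and verified empirically (observed ≈ 0.38).

Crossbreds: HWE mode draws dosages Binomial(2, Σ w_j x_ij) independently
per locus — exactly the admixture model's assumption. Block mode draws two
gamete mosaics whose breed-of-origin is constant within fixed-length bp
blocks (default 5 Mb) sampled from W, then alleles Bernoulli(x_breed); it
adds within-gamete ancestry correlation while preserving per-SNP expected
frequencies. One integer seed feeds named substreams per operation, so each
fixture is independently reproducible.

Named scenarios (defaults M = 5000 SNPs, n = 100 animals):

- `brangus_like`: two distant breeds (independent ancestors, F = 0.25 each),
  W = (0.625, 0.375) — the regime where all estimators agree;
- `beefmaster_like`: three breeds, W = (0.5, 0.25, 0.25), breeds 2–3
  correlated at r ≈ 0.4 — the regime where combined and direct measures
  separate;
- `ultrablack_like`: one gamete from the stabilized 0.625/0.375 composite
  and one from breed 1, expected ancestry (0.8125, 0.1875).

What the generator does *not* emulate: linkage disequilibrium within
breeds (HWE mode is locus-independent; block mode adds only blockwise
ancestry correlation, not background LD), allele-frequency change in the
reference breeds since breed formation, genotyping error, ascertainment
bias of commercial arrays, and selection within composites. Passing tests
on these fixtures therefore validate the estimators under their own model
assumptions, not their field accuracy on array data, where those unmodeled
features dominate the error budget.

## Problem sizes and tolerances

The test suite runs the estimators at M = 5000 loci and 100 animals for
recovery checks (mean admixture error ≤ 0.01 at W = (0.5, 0.25, 0.25)),
50 seeded instances for the dual-route (≤ 1e-8) and decomposition (≤ 1e-10)
identities, and a 1001-point exhaustive grid as the two-breed likelihood
oracle (agreement ≤ 0.001) — sizes chosen so the whole suite completes in a
few seconds while the Monte-Carlo bounds retain comfortable margins.
Simplex outputs are exact to 1e-12 after renormalization. Degenerate
inputs are errors, not silent results: empty SNP intersections,
zero-variance vectors for standardization, all-non-positive coefficient
vectors, ill-conditioned correlation matrices, breeds with no genotyped
animals, and fewer than three complete loci for a correlation.

## Known limitations

- Path-analysis reliability (1 − R) is attached per estimate but has no
  sampling-distribution interpretation here; no standard errors or
  confidence intervals are provided for any estimator.
- D-GBC/C-GBC are ratios of determinations; they coincide with pedigree
  fractions only under the diagram parameterization, not when estimated
  from raw mixture data (see the interpretation note above).
- The supervised admixture model ignores LD between loci; with dense panels
  the log-likelihood curvature (hence apparent precision) is overstated.
- `filter_reference` scores each animal against a point estimate of its
  breed frequencies; with very few animals per breed the score is noisy and
  leave-one-out mode is advisable.
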