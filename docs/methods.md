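# Methods

## Experimental design being modeled

The package targets a fully crossed two-factor design: soil microbiome
status (natural field soil vs gamma-sterilized) × *Striga hermonthica*
treatment (infected vs uninfected control), measured at two infection
timepoints (2 and 3 weeks post-infection) in up to four microbiome
sub-categories (bulk soil, rhizosphere, soil-plug-associated roots,
sand-associated roots). Host responses are the number of *Striga*
attachments per gram of root, aerenchyma proportion, endodermal suberin
intensity, and the root-exudate abundances of two haustorium-inducing
factors (syringic and vanillic acid). Suberin is only scored at 3 wpi;
the HIFs only at 2 wpi.

## Synthetic data generator

The generator draws taxa and traits jointly on a latent Gaussian scale,
`Z = XB + E` with `E ~ MN(0, I, Σ)`, where Σ is a correlation matrix
carrying the *planted* taxon–trait residual correlations. Taxon latents map
to sequencing counts through a logistic-normal multinomial: softmax of
(latent + per-taxon log-abundance offset, offsets ~ N(0, 1.5²) for a
realistic rank-abundance spread), then a multinomial draw at a fixed library
size (default 20,000 reads). This choice — rather than, say, a
Dirichlet-multinomial — keeps the planted correlations on the same latent
scale the joint model estimates, which makes parameter recovery well-posed.

Sterilization is modeled as taxon dropout plus per-taxon soil mean shifts: a
seeded fraction (default 0.3) of non-planted taxa is absent from every
sterilized sample, which reproduces the reduced bacterial alpha diversity of
irradiated soil. Trait observations are the Gaussian latents plus fixed
intercepts; keeping traits linear in the latents means planted correlations
survive unchanged into the observed tables (an exponential
measurement scale would attenuate them).

Default effect sizes encode the qualitative findings the design is built to
detect: fewer attachments and lower HIF levels in natural soil, more
aerenchyma and suberin, a strong *Striga* main effect on attachments, no
planted interactions. Replication defaults to 6 per cell (the phenotyping
replication; per-cell sequencing sample sizes are not published, so this is
a design choice exposed in `SimConfig`). Default planted associations are
three suppressive taxa at |ρ| = 0.5 — one per mechanism, with compensating
trait–trait correlations, since three taxa each at ρ = 0.6 with the same
trait would make Σ non-positive-definite. The generator verifies positive
definiteness by Cholesky factorization and rejects configs that fail.

All randomness flows from one integer seed through a fixed
`SeedSequence` spawning order (taxon parameters, dropout, one stream per
sub-category × timepoint, features), so identical configs give
byte-identical tables.

What the generator does **not** emulate: amplicon error profiles, chimeras,
compositional zero-inflation beyond dropout, retention-time drift, batch
effects, or phylogenetic correlation among taxa. Passing tests therefore
demonstrate statistical correctness of the pipeline under its own model
assumptions, not robustness to every artifact of real sequencing data.

## Trait screen

`trait ~ soil + striga + soil:striga`, sequential (type I) sums of squares on
balanced data and hierarchical (type II) when replicates are missing; the two
coincide on balanced designs, and type II is the better-behaved choice when
they do not. A trait is forwarded to the joint model when its soil term is
significant and the interaction is not (`soil_only`), i.e. the microbiome
changed it regardless of infection. α defaults to 0.05 and is config-exposed.
An empty design cell triggers a main-effects-only fallback with a warning;
zero residual variance is an error. Shannon diversity uses natural log.
The enrichment test is the one-sided hypergeometric upper tail (equivalent
to one-sided Fisher). The odds ratio for fully-suberized plants uses the
Haldane–Anscombe 0.5 correction only when a cell is zero.

## Joint model

Counts enter as CLR-transformed relative abundances (pseudocount 0.5) and
are modeled as Gaussian alongside the traits. This departs from generalized
joint attribute models that treat counts through censored composition
machinery; the Gaussian-CLR route preserves full conjugacy (exact Gibbs, no
tuning) at desk-scale runtime while targeting the same residual-correlation
estimand. A prevalence filter (default ≥ 20% of samples) plus a
mean-relative-abundance cap (default 100 taxa, ties broken by taxon id)
controls dimensionality; neither is prescribed by the source experiment, so
both are exposed for sensitivity analysis.

Priors: ridge precision τ = 10⁻³ on B; Σ ~ inverse-Wishart(ν₀ = q + 2,
identity scale). MCMC defaults: 10,000 iterations, 2,000 burn-in, thinning 5
(1,600 retained draws). Inverse-Wishart draws use the Bartlett
decomposition. Convergence is monitored with Geweke z-scores on log|Σ| and
ten Σ entries; |z| > 2 warns but does not abort (with 11 monitored series,
one excursion beyond 2 is expected by chance in roughly half of healthy
chains). Residual correlations are computed per draw and then averaged,
which keeps the unit diagonal exact. Fits run independently per
sub-category × timepoint; traits per timepoint follow the screen's
`soil_only` classification, with attachments always included as the ranking
anchor.

Numerical notes: the B full conditional uses the Cholesky factor of
(XᵀX + τI) throughout (no explicit inverse); a non-finite Σ draw aborts with
a diagnostic; `n ≤ p` raises an error suggesting stronger taxa filtering;
every retained Σ draw is symmetric positive definite by construction.

## Ranking and candidate selection

Sign filtering uses strict inequalities (a correlation of exactly zero
supports neither direction). Ranks are desirability ranks: value m for the
most desirable correlation, ties averaged; the combined rank is the rank of
the sum of the attachment rank and the focal-trait rank, computed within a
sub-category × timepoint and reported side-by-side across bundles rather
than merged. Top-k summaries include every taxon tied at the k-th value, so
k may be exceeded. Genus-level candidate selection uses an
any-member-OTU rule against the ±0.2 cutoffs (how OTUs aggregate to genera
is not prescribed by the source analysis; the any-member rule matches
selecting isolates by genus). Mechanisms are unioned across OTUs and
bundles. With ~50 taxa and n = 24 per bundle the ±0.2 cutoff admits some
null taxa by chance; the null-calibration evaluation quantifies exactly this
false-exceedance rate (about 4–5% of entries at n = 100).

## HIF degradation screen

Feature masses are assumed adduct-corrected to neutral monoisotopic masses
upstream; an optional [M+H]⁺/[M−H]⁻ mode shifts by a proton mass before
comparison. The 25 ppm window is inclusive, with a 10⁻⁹ ppm guard (10⁻¹⁵
relative mass — far below instrument precision) so a feature sitting exactly
on the boundary cannot be flipped by floating-point round-trip. Matching is
many-to-many and mass-only; retention time is carried but unused. The
fold-change epsilon is half the smallest positive peak area in the table.
BH adjustment runs across matched features only, mirroring a screen where
the matched set is the hypothesis universe. Welch's test is the default
(robust to unequal variances); `student` mode is available where the
classical equal-variance test is wanted.

The built-in product list covers plausible microbial conversions of the five
HIFs (demethylations, decarboxylations, reductions) with hand-computed
monoisotopic masses; it is a synthetic stand-in for an external
structure-prediction tool's output, which the pipeline treats as an input.

## Evaluation problem sizes

The packaged evaluation (`strigasoil.evaluation`, run by
`scripts/acceptance.py`) uses: recovery at n = 48 (2 × 2 × 12) with 25 taxa
and 5 traits over 10 seeds; null calibration at n = 100, q = 30 over 20
seeds with responses drawn directly from the Gaussian model (Σ = I) — the
count path is deliberately bypassed there because CLR closure adds a
−1/(K−1) correlation offset among taxa that is a property of
compositionality, not of sampler calibration; ranking-oracle agreement on
100 random correlation matrices of up to 50 taxa; and 10 end-to-end runs
with 50 taxa and three planted suppressive taxa. These sizes keep the full
evaluation around two minutes on one CPU while leaving each check
well-powered.

## Known limitations

- Gaussian-CLR count handling ignores zero-inflation structure beyond the
  pseudocount; heavy dropout regimes bias residual correlations of affected
  taxa toward zero.
- Residual-correlation recovery at the study's per-bundle sample sizes
  (n = 24–48) has sampling noise of ±0.1–0.2 per entry; single-bundle
  candidate lists should be read accordingly, and cross-bundle agreement is
  the more reliable signal.
- The H1/H2 contrasts are linear in the latent scale; effects on counts are
  interpretable as log-fold changes of relative abundance only through the
  CLR approximation.
- Genus aggregation by any-member-OTU can flag a genus on a single OTU;
  the evidence table in the candidate JSON lists the supporting OTUs so
  this is auditable.
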