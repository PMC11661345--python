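# Methods

This note documents the statistical models behind `popsloci`, the choices
made where the methods literature leaves room, and what the synthetic
study design does and does not establish about real data.

## Summary-statistics model and the synthetic study

All downstream stages consume only variant-level summary statistics
(effect allele, frequency, β, SE, p, N_eff) plus reference genotypes, so
the generator draws summary statistics directly from the standard
multivariate-normal model rather than simulating phenotypes: per LD block,

    z ~ N( R · (√N_eff · b),  R )

with `R` the empirical reference-panel correlation and `b` the
standardized joint effects (non-zero only at planted causal variants).
This makes the null exact by construction and the non-centrality of a
causal variant exactly `√N_eff · β · √(2f(1−f))`. Reported SE is
`1/√(N_eff · 2f(1−f))`, β = z·SE, p the two-sided normal tail.

Reference panels are haplotype Markov copying chains: within a block of
`ld_block_size` adjacent variants, each haplotype allele copies its left
neighbor with probability `ld_decay`, otherwise it is redrawn from the
block allele frequency. With a constant frequency per block this yields
`corr(i,j) = ld_decay^|i−j|` exactly in expectation for the binary
genotypes — a thresholded-Gaussian construction would attenuate the
correlation (tetrachoric effect) and miss that target. Allele frequencies
diverge across ancestries by a Balding–Nichols beta perturbation of a
shared ancestral frequency (fixation index F = 0.05, clipped to
[0.02, 0.98]).

Default study design (also the acceptance-script configuration): 50,000
variants at 1 kb spacing on 20 chromosomes, LD blocks of 50 (decay 0.9),
1,000 genes tiling the chromosomes (gene body = central 60% of its slot),
500 features of which ~10 are signature columns shifted by 2.0 in causal
genes, 25 causal loci separated by ≥1.5 Mb (so padded clump regions never
merge two planted signals), standardized causal effects ~N(0, 0.04), 30%
of causal variants flagged non-synonymous plus a 2% background of in-gene
non-synonymous annotations. The two ancestries mirror an East-Asian /
European design: effective sample sizes 15,886 and 127,626 with reference
panels of 538 and 2,000 samples (the EUR panel size is a simulation-scale
choice; the mixed panel is assembled by proportional subsampling so its
composition matches the ~11%/89% effective-sample-size shares).

What the generator deliberately does **not** model: genotype imputation
error and imputation-quality filtering, strand ambiguity under the
default settings (palindromic alleles are exercised in dedicated QC
fixtures instead, so the ambiguity rule never silently removes a planted
causal), proxy-case dilution (absorbed into N_eff), cross-block LD,
allele-frequency-dependent effect-size architecture, and realistic
gene-length / feature-correlation structure. Passing tests therefore
demonstrate the correctness and calibration of the *methods* under a
faithful generative model, not the empirical performance of the pipeline
on real cohorts.

## QC and meta-analysis

Harmonization matches variants to the panel by chromosome, position and
unordered allele pair; swapped-allele records are flipped (β negated,
frequency complemented). Strand-ambiguous (A/T, C/G) variants with
effect-allele frequency in [0.4, 0.6] are dropped — the standard guard
against undetectable strand errors. Frequency QC applies two sequential
rules against the panel frequency: |Δf| > 0.1, then a two-sided
fold-change > 12; counts are reported per rule. Meta-analysis is
inverse-variance fixed-effects on β/SE (the effect-based scheme; a
sample-size-weighted alternative was considered and rejected because
betas and SEs are what downstream stages consume). Variants present in
one study are carried through unchanged; N_eff sums and frequencies
average with N_eff weights.

## Signal isolation

Clumping is the greedy algorithm: repeatedly take the most significant
unassigned genome-wide-significant variant as an index and absorb all
unassigned significant variants within 3 Mb with r² ≥ 0.1 (LD from the
mixed-ancestry panel); ties in p break by position for determinism.
Clump spans grow by ±500 kb and overlapping spans merge, pooling index
variants.

Conditional/joint analysis works in z-score space with reference LD.
Joint estimates for a selected set S:

    β̂_S = R_S⁻¹ (z_S / √n_S)   (standardized scale)
    se_j = √((R_S⁻¹)_jj / n_j)

and the conditional z of a candidate v given S is the normalized
multivariate-normal conditional

    z_{v|S} = (z_v − r_vS R_S⁻¹ z_S) / √(1 − r_vS R_S⁻¹ r_Sv).

Stepwise forward selection starts at the region's top variant and adds
the smallest-conditional-p candidate while it stays below 5×10⁻⁸;
candidates are excluded as collinear when either any pairwise r² with
the selected set or their multiple-regression R² on the whole set
reaches 0.9 (the latter matches the conditional-analysis literature and
prevents cascades of phantom hits when a very strong signal meets small
panel/GWAS LD mismatch). After selection, hits with joint p > 5×10⁻⁸ are
dropped worst-first with re-estimation. Leave-one-hit-out conditioning
reuses the conditional formula with the other hits as the conditioning
set; the conditioning variants themselves are fixed at z = 0, p = 1, and
the conditional β on the allele scale is reported as z_cond × SE with
the marginal SE retained — an approximation that slightly overstates the
conditional SE but is immaterial for Bayes-factor fine-mapping, which
depends on z and the SE scale.

Per-variant effective sample sizes enter the joint SEs directly; LD for
meta-analyzed statistics always comes from the mixed panel (a config
switch allows ancestry-specific panels instead).

## Fine-mapping

Wakefield's approximate Bayes factor with effect-size prior SD 0.2 on
the log-odds scale (the usual case-control default; configurable). PIPs
are the log-space softmax of lABFs over all region variants — stable for
lABF well beyond 700. The 95% credible set is the minimal prefix of
variants sorted by PIP (position-ascending within ties) whose cumulative
PIP reaches 0.95, with boundary ties included (coverage may then exceed
0.95). The weighted center averages member positions with PIPs
renormalized within the set. Locus windows are the member span ±300 kb,
floored at position 1, with closed-interval gene-body overlap in 1-based
coordinates. Measured calibration: with a single causal variant at
non-centrality 8 in AR(0.9) blocks of 50, the causal variant falls in
the 95% set in ~99% of 500 replicates (the set over-covers because it is
the smallest set *reaching* 0.95, and the fixed-effect regime is
well-powered).

## Gene-level association

The SNP-wise mean statistic is the mean squared variant z over the
common (MAF > 1%) variants inside a gene body (inclusive bounds, no
flank; overlapping genes share variants; genes with fewer than three
mapped variants are not scored). Under the null the statistic is
distributed as `(1/m) Σ λ_k χ²₁` with λ_k the eigenvalues of the
variants' LD correlation matrix (floored at 1e-8). The tail probability
uses Imhof's characteristic-function inversion for p ≥ 0.01 — the
oscillatory integral on [0, ∞) carries absolute error of order 1e-5, so
it cannot be trusted deeper — and the Kuonen saddlepoint approximation
(Barndorff-Nielsen form) beyond, whose relative error stays within a few
percent arbitrarily far into the tail; eigenvalues below 1e-7 of the
trace are dropped first because they slow the integrand's decay without
affecting the distribution. p-values are floored at 1e-300 with a
warning and mapped to gene z-scores by the upper-tail probit. Each
ancestry is tested against its own panel and frequencies; gene z-scores
are meta-analyzed as `Σ wᵢzᵢ / √(Σ wᵢ²)` with wᵢ = √N_eff.

## Polygenic priority scoring

Features are screened marginally against the per-ancestry gene z-scores
(slope t-test, keep p < 0.05; constant features skipped). Scores come
from ridge regression of z on the selected features, fit once per
chromosome on all *other* chromosomes' genes — features standardized
with training-fold statistics only, penalty chosen per fold by efficient
leave-one-out cross-validation over a log-spaced grid (1e-2…1e6) — and
used to predict the held-out chromosome. Holding the feature set fixed,
chromosome-c scores are therefore a function of non-c gene z-scores
only; the marginal screen itself sees all chromosomes, as in the
original formulation. With no selected features every gene scores the
training-fold mean. Per-ancestry scores are combined by the
√N_eff-weighted *mean* (scores are predictions, not test statistics, so
a convex combination rather than a z-style `/√Σw²` combination is used;
the alternative is available behind a switch). Percentiles are
average-rank based, scaled so the genome-wide minimum maps to 0 and the
maximum to 1; an all-tied vector sits at 0.5. No gene–gene LD
decorrelation is applied in the marginal screen — a simplification
relative to the full method, flagged in output metadata.

## Prioritization

Per locus: the nearest gene is the one minimizing distance to the
credible set's PIP-weighted center (0 inside the gene body; equidistant
ties break toward the higher meta PoPS score, then lexicographic id);
the top-PoPS gene is the unique maximizer of the meta score among locus
genes (unscored genes can never hold the flag; ties break
lexicographically). Criterion A fires when the same gene holds both
flags. Criterion B fires for a gene whose non-synonymous credible-set
variants carry summed raw PIP above 0.5 (the sum reading; a
single-variant reading is a config option). When both criteria fire —
same or different genes — the criterion-B gene is the sole call, with
basis `nonsynonymous`; only-A gives `pops_nearest`; otherwise no call.
Overlapping loci from different independent signals are called
independently per signal. External per-locus causal probabilities are
compared after capping each locus's total at 100% (rescaling only loci
whose probabilities over-sum; idempotent).

## Numerical and engineering choices

* Determinism: every random draw descends from integer seed sequences
  `[seed, tag, index]`; identical configs reproduce identical outputs
  byte-for-byte, and the run manifest records a SHA-256 of the canonical
  config JSON.
* LD matrices are empirical correlations of hard-call genotypes;
  monomorphic columns standardize to zero (r = 0). Cholesky jitter 1e-6
  regularizes the simulation draws; conditional residual variances are
  floored at 1e-12.
* Coordinates are 1-based inclusive everywhere in memory; BED output is
  0-based half-open, converted only in the I/O layer.
* Problem sizes in the test suite (blocks of 40–50 variants, panels of
  2,000–5,000, 500 fine-mapping replicates, 10⁶-draw Monte-Carlo oracle)
  were chosen to keep the full suite in the minutes range while leaving
  comfortable statistical margins on every calibration check.

## Known limitations

* Single-causal fine-mapping only: leave-one-out conditioning isolates
  signals, but each credible set assumes one causal variant; no
  multi-causal (SuSiE-style) sets.
* The conditional SE approximation above; joint SEs ignore the residual
  phenotypic-variance reduction term.
* PoPS feature screening ignores gene–gene correlation of z-scores
  induced by LD between neighboring genes.
* The generator's LD is strictly block-diagonal and its gene models are
  uniform tiles; real LD leaks across blocks and real gene architecture
  is far more heterogeneous.
* Chromosome X is out of scope throughout (autosomal genes only).
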