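# Methods

This note documents the statistical conventions, numerical choices and
known limitations of `genediv`. Everything stated here is computed by
the package itself; the test suite and `scripts/acceptance.py` exercise
each claim.

## Data model and gap handling

The unit of analysis is a gapped multiple sequence alignment of one
locus across n inbred lines, treated as haploid haplotypes (inbred lines
are homozygous; heterozygous calls are out of scope). Coordinates are
1-based inclusive alignment columns. An optional reference row (the
B73-style allele that anchors the annotation) is held out of every
statistic; it only breaks ties when a major allele must be chosen.

Gap handling follows the complete-deletion convention of classic
locus-survey software: an **indel event** is a maximal contiguous block
of gap-containing columns (possibly multi-allelic, e.g. no-deletion /
−3 / −6 over the same six columns); "number of indels" counts events and
"number of indel sites" counts the columns they span; and every
diversity or neutrality statistic is computed over the gap-free columns
only, so the net length of a region is its gross length minus its indel
sites. This convention was adopted because it makes Watterson's
estimator depend only on (S, n, L_net), which is how published
per-region values are stated. `N` bases are missing data: they never
create a variant, are excluded from allele counts, and π handles them
pairwise (each sequence pair is compared over the columns where both
have called bases). Whether legacy software excluded missing data
pairwise or listwise is not documentable from outputs alone; pairwise
was chosen as the less wasteful convention, and the two coincide when no
`N` is present (the default generator emits none).

## Estimators and neutrality tests

- π is computed from the sequences (mean over pairs of per-site
  mismatch fractions), not reconstructed from the variant table; the
  allele-count reconstruction Σ 2pq·n/(n−1)/L is kept as a cross-check
  oracle in the tests and must agree to 1e-12 when no data are missing.
- θ_w = S/(a₁·L_net) per site, with S counting segregating **SNP**
  sites only. Singletons (η_s) likewise count SNPs whose minor allele
  occurs in exactly one line; indel events never enter S, η_s, or any
  test statistic. These scoping rules are what reproduce published
  per-region values from published counts.
- Tajima's D uses the 1989 variance constants b₁, b₂, c₁, c₂, e₁, e₂; D
  is undefined (reported NAN) when S = 0. Its significance flags come
  from the beta-distribution approximation of the statistic's original
  construction: D is rescaled onto its attainable range
  [D_min, D_max] (computed from n) and compared with the beta law fixed
  by zero mean and unit variance.
- Fu & Li's starred statistics use the no-outgroup forms:
  D\* = ((n/(n−1))S − a₁η_s)/√(u_D\*S + v_D\*S²) with the
  corrected d_n-based coefficients, and
  F\* = (πL − ((n−1)/n)η_s)/√(u_F\*S + v_F\*S²) with the originally
  published u_F\*/v_F\* coefficients. This particular pairing is the one
  that agrees with the output of the standard desktop software for these
  tests, and both members are verified against an independent
  transcription of the closed forms in the test suite.
- D\*/F\* significance flags use two-sided critical values frozen from a
  20,000-replicate neutral-coalescent simulation (fixed S, no
  recombination), linearly interpolated in n. These are sharper than the
  classical tabulated critical values, which are conservative because
  they cover a range of mutation rates — so a value near the boundary
  may be flagged here and not by legacy software, or vice versa. The
  flags are descriptive output only; no numerical result depends on
  them.

## Haplotypes and proteins

Sequences identical over the chosen column set (gaps significant) form a
haplotype; numbering is by descending count with ties to the
first-occurring line. A sequence whose only differences are `N`
positions joins the complete haplotype it matches at every called site
(ties to the larger haplotype) — the behaviour users of the classic
tools expect. Hd = (n/(n−1))(1 − Σpᵢ²).

CDS haplotypes are translated after removing gaps (reverse-complemented
first on minus-strand genes). Differences from the longest protein
allele are enumerated by a column-synchronised scan over reference
codons, which assumes in-frame indels occupy whole codons of the
reference allele; partial-codon overlaps are reported as `complex`
rather than guessed. Residue coordinates are given on the longest
(no-deletion) protein. A haplotype whose ungapped CDS length is not a
multiple of 3 is translated to its first stop and flagged. Domain
intervals are closed 1-based residue ranges supplied by configuration
(e.g. the three mitochondrial-carrier domains of a BT1-family protein);
they are inputs, never computed.

## Linkage disequilibrium and recombination

r² is computed from haplotype frequencies of biallelic SNPs over each
pair's complete-data subset; multi-allelic indels are excluded (LD is a
SNP-level analysis here, as in the motivating study). Significance is a
two-sided Fisher exact test on the 2×2 haplotype count table — chosen
for small-count robustness since the upstream tool's test is not
documented — at α = 0.05 without multiplicity correction by default
(`--bonferroni` available).

Decay regression fits r² against inter-site distance d under five
families: a + bd; a + b·ln d; a·e^{bd}; a·d^b; and the Hill–Weir
expectation E[r²](C) with C = c·d,

E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))],

with the per-bp recombination scale c as the single free parameter,
grid-seeded (log-spaced c ∈ [1e−5, 1e−1]) before nonlinear least
squares. R² of every family is evaluated on the original r² scale so
the families are comparable, and the family with maximal R² is
selected. The distance at which a fit reaches r² = 0.1 is the smallest
positive root, found by sign-scan plus Brent's method; a curve that
never reaches the target reports none.

Rm is the Hudson–Kaplan bound: collect every four-gamete-incompatible
SNP pair as an open interval between its positions, discard intervals
that contain another incompatible interval, then scan left-to-right
keeping intervals disjoint from the last kept (intervals sharing an
endpoint are disjoint, since the crossover lies strictly between the
sites). The greedy count equals the exhaustive minimum; the test suite
verifies this against a brute-force interval-piercing oracle on all
random panels it draws (m ≤ 8 SNPs).

## Association

Variants pass a MAF filter (default 0.05, computed over called samples;
an allele at exactly the threshold is kept). Alleles below threshold
are removed from the contrast and their carriers masked for that
variant; variants left with fewer than two alleles are dropped, and the
two most frequent surviving alleles form the 0/1 major/minor contrast.

The model is ordinary least squares on per-line trait means:
`y = μ + Qγ + xβ + ε`, with K−1 admixture columns (the last column is
dropped when rows sum to one, avoiding collinearity with the
intercept). The marker is tested by the partial F-test of the full
against the Q-only model, and marker R² = (SSE_Q − SSE_full)/SS_total —
the after-Q definition; a marginal (Q-ignoring) R² is available by
flag. Rank-deficient designs (variant collinear with Q) are flagged
with NA rather than fitted. Raw p-values are reported with a Bonferroni
column alongside; the study scale (≈30 variants × 11 traits) does not
justify anything more elaborate by default. Allele classes are compared
with Welch's t-test (pooled-variance optional): the trait is measured
with error and class variances need not match. Replicates, when
present, feed the across-line one-way ANOVA only; association always
runs on line means, matching the bulk-harvest design of such panels.

## The synthetic panel generator

The generator's default configuration is the package's model of the
study conditions: 80 lines over a 2,436-column amplicon in seven regions
(520 promoter / 624 exon1 / 131 intron1 / 162 exon2 / 128 intron2 / 534
exon3 / 337 3′-UTR; the CDS is the 1,320-column exon concatenation). The
region lengths are taken from the annotation; where a source states a
round total that disagrees with its own region list, the annotation is
authoritative and no total is hard-coded. Planted structure:

- 22 SNPs distributed 7/5/0/0/0/4/6 across the regions; exactly one
  singleton, located in the promoter (the region-by-region neutrality
  statistics imply that location); one nonsynonymous site (a
  third-position ATA→ATG), the rest third-position changes of
  four-fold-degenerate codons.
- 8 indel events spanning 37 columns (1/3·{6,6,7}/0/7/6/1 by region),
  two singletons, and one tri-allelic in-frame coding event: no
  deletion (50 lines), −3 removing one glutamate (27), −6 removing a
  glutamate–aspartate pair (3). The −6 allele sits below the MAF
  threshold by construction, so association tests the −3 contrast on 77
  lines.
- 11 full-length haplotypes with exact counts 29/16/18/9/2/1×6,
  collapsing to 6 CDS haplotypes (32/18/16/9/3/2) that encode 6 distinct
  proteins; exact-count assignment is the default so haplotype-diversity
  values are deterministic (multinomial sampling by flag).
- one recombinant background: two lines carry one clade's alleles left
  of a crossover in intron 1 and a private background to its right.
  Carrier sets were arranged so exactly one reduced four-gamete interval
  survives (and none without the crossover), and so that no other
  variant is a near-perfect LD proxy of the causal deletion (max
  r² ≈ 0.17) — the study condition under which the causal variant is
  the only significant association.
- three subpopulations; each line's admixture row is Dirichlet with
  concentration boosted toward its haplotype's home group. Home groups
  cut across the causal carriers so the deletion is not a proxy for Q;
  one pasting trait (PV) carries subpopulation mean shifts so that
  omitting Q demonstrably inflates null associations.
- 11 traits with means and dispersions at the scale of published maize
  starch phenotypes; within-line replicate noise is back-solved from
  each trait's published across-line ANOVA F (rep_sd =
  sd·√(r/(F−1))). The causal effect on gelatinization enthalpy targets
  a marker R² of 9.26%: β is solved against the Q-residualized carrier
  variance on the contrast subset and the line-mean noise scale, because
  that is the quantity the partial F-test estimates. The measured mean
  R̂² over replicates runs ≈1–2 points above target — the incremental-R²
  estimator is biased upward by roughly (1−R²)/df — which is inherent to
  the estimator, not the plant.

A separate "neutral" mode samples exact Kingman coalescent genealogies
(successive pairwise coalescence with Exp(k(k−1)/2) waiting times) and
places a fixed number of infinite-sites mutations on branches
proportionally to length. It has no recombination or demography and is
used for sanity bands (mean Tajima's D and D\* near zero), not for
calibrated inference.

What the generator does **not** emulate: the real panel's allele
frequency spectrum (π-dependent statistics on synthetic data differ from
published values even though every count-dependent statistic matches),
sequencing or alignment error, recurrent mutation, gene conversion, and
linkage to anything outside the amplicon. Passing tests therefore
demonstrate correctness of the estimators and the pipeline's behaviour
under a faithful structural model — not re-measurement of the original
panel's frequency-dependent quantities.

## Numerical conventions

- Ties for major alleles break toward the reference allele, else
  lexicographically; haplotype numbering ties break to the
  first-occurring line. All outputs are deterministic given inputs.
- S = 0 regions report π = θ_w = 0 and NAN for every test statistic.
- Monomorphic-in-subset LD pairs are skipped and logged; Fisher p is 1
  when a site is (nearly) fixed in the shared subset.
- Every pipeline stage logs its input dimensions and the counts that
  appear in the region-summary table, so a run's provenance is
  auditable from the log alone.
- Problem sizes in the test suite (200 association replicates, 1,000
  null GLM replicates, 500 neutral panels, exhaustive four-gamete
  verification at ≤8 SNPs) were chosen as the smallest sizes at which
  the asserted bands are stable, keeping the whole suite under a minute
  on one core.

## Known limitations

- Diploid heterozygous genotypes and unaligned input are out of scope;
  the alignment is trusted as given.
- Coding-consequence annotation evaluates one variant at a time against
  the majority-allele CDS; compound effects of co-occurring variants
  within a codon are not composed.
- The D\*/F\* critical values are simulation-derived approximations (see
  above); use dedicated software if exact legacy flag behaviour
  matters.
- The Q matrix is consumed, never estimated; structure estimation and
  the choice of K belong upstream.
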