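# Methods

## Scope and model overview

The package analyses replicated enzyme-activity measurements on panels of
maize inbred lines (and their testcross F1 hybrids), maps activity
variation to candidate-gene polymorphisms with a mixed linear model, and
screens loci for domestication-related loss of diversity against the wild
ancestor (teosinte). All stages operate on plain-text tabular, FASTA and
JSON formats and are driven either through the Python API or the
`enzyqtn` CLI.

## Plate standardization

One microplate carries 40 experimental wells, 4 wells of a common
reference line and 4 blanks; each well yields a maximal-rate reading
V_max and a same-plate blank reading V_blank. Net activity is
`V_max − V_blank`. Negative net activities are retained and flagged:
clamping them would bias plate means upward. Two standardization schemes
divide each experimental well by a plate-level divisor — the mean net
activity of the plate's experimental wells, or of its reference wells.
Blanks never enter a divisor. The default is `reference_mean` (the
reference line is constant across plates, so its mean is a direct
plate-effect estimate); the two schemes are interchangeable in practice
and agree exactly (after per-enzyme z-scoring) when plate effects vanish.
Missing wells are excluded pairwise; nothing is imputed.

## Heritability and co-regulation

For line-replicated data the one-way taxa ANOVA gives MS_G (between
lines) and MS_E (within). On a balanced design with r replicates,
expected mean squares give `σ²G = (MS_G − MS_E)/r` (truncated at 0) and
`σ²E = MS_E`; broad-sense heritability is `H² = σ²G/(σ²G + σ²E)`.
Unbalanced replication is handled with the harmonic-mean r and a warning;
REML for this simple design is deliberately out of scope. Negative-σ²G
truncation makes Ĥ² slightly conservative-to-upward-biased at low H² and
few lines; the Monte-Carlo recovery test (8 lines × 5 reps, 200
simulations) bounds the bias below 0.05 for H² in {0.2, 0.5, 0.7}.

Enzyme activities in this system are positively correlated across
enzymes, so the package computes the per-sample mean of z-scored
activities ("Mean-STD activity") as a co-regulation trait, and
enzyme-specific residuals as each value minus its sample's mean across
enzymes. The z-score uses the sample standard deviation (n−1). The
heritability of the residuals ("normalized heritability") quantifies
enzyme-specific genetic control, the relevant signal for candidate-gene
mapping. One published table footnote counts "10 enzymes" where nine are
listed; the implementation always averages over the enzymes actually
present in the matrix.

Two-way fixed-effects ANOVA (line × temperature; SNP × genetic
background) reports both sequential (type 1) and each-term-last sums of
squares; the latter uses the marginality-respecting type 2 convention,
since the originating software convention is unknowable and type 2 equals
term-fitted-last for the no-interaction and balanced cases used here.
Designs with empty cells drop the interaction with a warning.

## Mixed-model association

The phenotype model is `y = Xβ + u + e` with `u ~ N(0, σ²g K)`,
`e ~ N(0, σ²e I)`. K is identity-by-state kinship from background
markers: mean allele sharing `1 − |d_i − d_j|/2` per pair, in [0,1], unit
diagonal for inbreds. Structure covariates Q are admixture proportions
with the last column dropped (they sum to 1), or could equally be leading
eigenvectors of the background-marker covariance.

REML estimation exploits the spectral decomposition `K = U Λ U'`:
rotating y and X by U' diagonalizes `V ∝ Λ + δI` for every
`δ = σ²e/σ²g`, so the restricted likelihood is a cheap one-dimensional
function of δ. It is evaluated on a fixed grid of 61 points log-spaced in
[1e−5, 1e5] and refined by golden-section search on log δ within the
bracketing cells (tolerance 1e−4) — no general-purpose optimizer, hence
bit-reproducible across runs. Boundary solutions are meaningful: δ at the
upper edge is the σ²g → 0 branch, where marker tests provably reduce to
ordinary fixed-effects regression (tested to 1e−8 with K = I).

Per-marker testing follows the P3D convention: variance components are
estimated once on the covariates-only null model and reused for every
marker, which costs little power and removes per-marker optimizer noise.
Each test is a GLS F test (1 df) of the marker term under
`V = σ²g K + σ²e I`, computed by Cholesky whitening on the samples
non-missing for that marker. The reported allele effect is the fitted
homozygote-class difference (2 × the per-dosage slope). `R²_marker` is
the incremental explained fraction of whitened total SS around the
whitened intercept fit — with K = I this is exactly the classical
incremental R². Markers collinear with the null design are flagged and
given no P. MAF filtering is strictly `> threshold` (default 0.1), with
one allele observation per inbred and dosage/2 per hybrid.

The empirical null scans a panel of random unlinked markers with the same
model and reports the sorted null P distribution, a KS uniformity check,
and the candidate's quantile `(1 + #{null ≤ candidate})/(m + 1)`. This
places candidate-gene P values in perspective independently of how well K
and Q control stratification. The stepwise extension tests each further
marker by a partial F test on top of the base marker (plus Q, K);
markers in perfect LD with the base are flagged collinear and never
selected. Significance thresholds are left to the caller: the package
reports raw P plus the empirical-null quantile.

Simulation results computed in the test suite: under admixture
(100 lines, 3 subpopulations, divergence 0.2, 553 background SNPs, a
subpopulation-mean phenotype gradient of one residual SD per component),
the mixed model holds the 0.05-level type-I error within [0.03, 0.07]
while structure-naive regression exceeds 0.10 — the motivating property
of the model. With n = 30 unstructured samples the MLM P matches a
100,000-permutation P within Monte-Carlo error.

## LD

r² is computed from two-locus haplotype frequencies,
`r² = D²/(p_A p_a p_B p_b)`; inbred dosages are read directly as
haplotypes, so this equals the squared Pearson correlation of dosages (an
identity the tests verify on 1000 random pairs). Heterozygous or missing
calls are excluded pairwise; monomorphic pairs are skipped and counted.
INDELs are treated as biallelic presence/absence markers. Distances come
from 1-based within-gene positions; decay bins are half-open
`[kw, (k+1)w)` and empty bins are absent rather than zero.

## Additive/dominance decomposition

From class means, `a = (m_hom1 − m_hom2)/2` and
`d = m_het − (m_hom1 + m_hom2)/2`. The default orientation takes the
higher-mean homozygote as hom1 (so a ≥ 0 in reports); an explicit
`allele_order` fixes the orientation instead, under which swapping
alleles flips the sign of a and of d/a but not of d or |d/a|. Contrast
tests use the pooled residual variance of a fixed-effects model
(optionally with a genetic-background factor) — class sizes are small, so
homoscedasticity is assumed. Letter groups come from pairwise t tests at
the chosen α with non-significant pairs merged transitively. Inbred and
hybrid panels are pooled after z-scoring within each background group, so
tester effects cannot masquerade as marker effects.

## Two-factor activity model

Total activity is modelled as SNP genotype (categorical, all observed
dosage classes — 3-level by default) plus protein quantity as a
single-df continuous covariate (ANCOVA), fitted by OLS with sequential
(SNP first) and each-term-last SS. Sequential SS plus residual add to
total SS exactly, balanced or not. Specific activity is
activity/protein, undefined (flagged NaN) for non-positive protein.
Protein–activity correlation is computed on per-line means.

## Diversity screen

π is the mean over all unordered sequence pairs of differences per
compared site, with pairwise deletion: a site enters a pair only when
both sequences carry an unambiguous A/C/G/T (amplicon alignments have
ragged ends; complete deletion is available as an option). Each inbred
line or teosinte accession contributes one sequence. Multi-amplicon loci
combine per-amplicon π as a sites-weighted average. On gap-free data π
equals the site-frequency form `Σ_s (1 − Σ_a p_a²)·n/(n−1) / L`, an
identity the tests verify. The locus ratio π_panel1/π_panel2 (undefined
when the denominator is 0) is placed in a user-supplied reference
distribution of random-gene ratios as
`100·#{reference ≤ ratio}/#reference` (monotone in the ratio). The
allele-frequency-shift test is a Pearson χ² (df 1, no continuity
correction) on the 2×2 panel-by-allele table; Fisher's exact P is always
reported and recommended when any expected count is below 5. Allele
counting (per accession vs per chromosome) materially changes such tests;
the package counts whatever table the caller provides and makes no
attempt to target any particular printed value.

## Synthetic-data generator

The generator is the package's test bed and defines the simulated study
conditions; its defaults mirror the study design it emulates.

- **Population.** Fully homozygous inbreds (dosage ∈ {0,2}).
  Subpopulation allele frequencies follow a Balding–Nichols draw
  Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency
  p ~ U(0.1, 0.9), so Var(p_k) = F·p(1−p) with F the single structure
  dial (`divergence`, default 0.2). Admixture rows are
  Dirichlet(0.2,…): mostly-pure lines with occasional admixture, as in
  diversity panels. Defaults 100 lines, 553 background SNPs, 3
  subpopulations.
- **Candidate gene.** Three major founder haplotypes (default
  frequencies drawn Dirichlet(5)) over 85 sites in a 4.8 kb gene; every
  site is polymorphic among founders; a 3% per-line chance of a
  single-crossover recombinant supplies the "several rare" haplotypes;
  realised MAF ≤ 0.1 sites are dropped (the causal site is retained).
  This yields within-block r² ≥ 0.4, the regime in which a scan
  localises a haplotype.
- **Activity.** activity = μ + g + λc + βx + plate + ε with line effect
  g ~ N(0, σ²G), a single shared standard-normal co-regulation factor c
  per line with per-enzyme loadings λ (the minimal model producing a
  positive correlation matrix), causal dosage effect βx, additive plate
  effects (sd 0.1 by default, ~10% of the baseline μ = 1) and residual
  ε ~ N(0, σ²E). Blank wells carry only the plate effect (plus a small
  V_blank baseline of 0.2 with sd 0.02, typical of absorbance blanks);
  reference wells re-measure one fixed line. V_max = activity + V_blank
  per well, so net activity is exact when noise is switched off.
- **Alignments.** Per site, polymorphism occurs with probability
  min(1, 2θ) and each sequence then carries the alternative base with
  probability 1/2, giving E[π] = θ without coalescent machinery. This
  deliberately has no frequency spectrum or LD structure — adequate for
  validating the π estimator and ratio/tail logic, not for
  genealogy-sensitive statistics (which are out of scope).
- **Hybrids.** F1 dosage is the parental mean; tester allele states are
  whatever the supplied tester rows carry (they are not published, so
  they are parameters).
- **Protein.** Protein z-scores are r·z_activity + √(1−r²)·noise,
  rescaled to a positive arbitrary-unit scale (mean 1, CV 0.3).
- **Determinism.** One master integer seed; every generator derives an
  independent, fixed sub-stream via `SeedSequence(seed, spawn_key=(k,))`,
  so identical seeds give byte-identical outputs.

What passing tests on synthetic data do **not** show: real assay data
have temperature-dependent kinetics, multiplicative batch effects,
genotyping error, linked background markers and ascertainment in the
reference distribution — none of which the generator emulates.

## Numerical choices and degenerate inputs

- z-scores use ddof = 1; constant columns are an error, not silently 0.
- σ²G estimates are truncated at 0; MS_E = 0 designs are flagged
  degenerate rather than producing infinities silently.
- Kinship matrices are symmetrized and negative eigenvalues clipped at 0
  with a warning before REML.
- The δ grid bounds [1e−5, 1e5] act as explicit σ²g→∞ / σ²g→0 branches.
- Collinearity is detected by whitened residual norm ≤ 1e−8 of the
  regressed column.
- A single-haplotype candidate gene is returned monomorphic-flagged
  (with a warning) rather than rejected, so degenerate scans fail loudly
  downstream where r²/association are undefined.
- Problem sizes in the test suite (e.g. 5 phenotype replicates × 553
  markers for calibration; 200 simulations for H² recovery; 100,000
  permutations for the exactness oracle) were chosen to bound Monte-Carlo
  error well below each asserted tolerance.

## Known limitations

- Broad-sense heritability only; no narrow-sense decomposition from the
  replicated design.
- P3D reuses null variance components per marker; exact per-marker REML
  would differ in the fourth decimal of P for strong markers.
- The pooled-variance letter display is anticonservative under strong
  heteroscedasticity across genotype classes.
- The diversity screen consumes a reference ratio distribution as given;
  the selection inference is purely rank-based placement within it.
- The published replicated activity panel itself is distributed only as
  a supplementary document upstream and is not redistributed here; the
  entry point `reproduce_published_heritability` accepts a transcription
  (TSV: line, enzyme, rep, activity) and the corresponding check runs
  only when such a transcription is supplied at
  `data/published_activity_panel.tsv`.
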