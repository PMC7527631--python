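# Methods

`scafqtl` implements an association-mapping workflow for panels genotyped as
**pooled allele frequencies** on a **fragmented draft assembly**.  The two
constraints shape everything: genotypes are continuous major-allele
proportions rather than 0/1/2 dosages, and there are no chromosome
coordinates, so QTLs cannot be delimited by position — they are defined
statistically, as groups of collinear significant markers.

## Marker scoring and selection

Input is a per-accession nucleotide frequency table (%A, %C, %G, %T per
site).  Four rules are applied in order, each marker recording the first
rule it violates:

1. **call rate** — every accession must have a call (a panel this size
   cannot afford imputation on pooled frequencies);
2. **frequency bounds** — the panel-wide major allele frequency must be at
   most `major_max` (0.98) and the second allele must reach `maf_min`
   (0.02);
3. **biallelic** — the two most frequent alleles must jointly reach
   `biallelic_min` (0.95) of the panel frequency mass;
4. **variation** — the sample standard deviation (ddof = 1) of the
   per-accession major-allele frequency must be at least `sd_min` (0.1).

The major allele is defined panel-wide; exact ties are broken
lexicographically (A < C < G < T) so scoring is deterministic.  A survivor's
score for an accession is that accession's frequency of the panel major
allele — a value on the grid {0, 1/16, ..., 1} for pools of 8 diploids.
Whether the 2%/98% bounds should apply before or after restriction to the
top two alleles is ambiguous for multi-allelic sites; they are applied to
the raw panel frequencies here.

## Kinship, PCoA, dendrogram, FST

The genomic relationship matrix follows the VanRaden construction adapted to
frequency-scale genotypes: K = ZZ'/s with Z the column-centered score
matrix and s = Σ_j p̄_j(1 − p̄_j), p̄_j the panel mean score.  The usual
dosage-scale denominator 2Σp(1−p) assumes 0/1/2 genotypes; on proportions
in [0, 1] the variance of a binomial frequency is p(1−p) per unit, so the
sum of column variances under Hardy–Weinberg-like behaviour is the natural
scale.  Structure is visualized by eigendecomposition of the double-centered
K (PCoA; percent variance relative to the sum of positive eigenvalues) and
by average-linkage hierarchical clustering on d(i,j) = max(K_offdiag) −
K(i,j) (the shift by the largest off-diagonal similarity puts the most
similar pair at distance zero; linkage and similarity-to-distance conversion
are configurable since nothing in the problem fixes them).

Cluster differentiation uses Wright's fixation index per marker,

    FST = ( p̄(1−p̄) − Σ_i c_i p_i(1−p_i) ) / ( p̄(1−p̄) ),

with p_i the mean accession score in cluster i and c_i the relative cluster
size; the multi-marker summary is the **ratio of sums** of numerators and
denominators (Weir-style), which is stable when single markers carry little
information.  Per-marker ratios remain available.  Monomorphic markers
(p̄ ∈ {0, 1}) are skipped.

## LD and the collinearity threshold

All within-scaffold marker pairs give (distance, r²) profiles, with r² the
squared Pearson correlation of the score columns.  The long-distance
baseline — the median r² among the most distal quarter of pairs per
scaffold, averaged over scaffolds — calibrates the collinearity threshold:
`max(baseline, 0.1)` on the r² scale.  Collinearity throughout the package
is `|r| >= 0.3` (r² >= 0.09): score columns are polarized by the panel
major allele, so negative correlations are physically meaningful linkage
and magnitude is the right criterion.

## Mixed-model association scan

Per trait and location the phenotype is the accession mean.  The null model
y = μ + g + e with g ~ N(0, σ²_g K), e ~ N(0, σ²_e I) is fit by REML,
profiling the ratio δ = σ²_e/σ²_g on the spectrum of K (dense 256-point
grid on log δ ∈ [−12, 12] plus bounded local refinement; δ pinned at the
upper bound is reported as a boundary fit with σ²_g = 0).  Marker tests are
P3D/EMMAX-style: the ratio δ is frozen from the null fit, each marker is
tested by weighted regression in the rotated space, and the overall variance
scale is re-estimated per marker from the weighted residuals (df = n − 2).
This makes the Wald statistic (α̂/se)² identical to the squared t of an
exact GLS fit, and reduces exactly to ordinary regression when K = I.
p-values use the asymptotic χ²(1) reference.  An exact per-marker REML refit
is not performed; at these panel sizes P3D is the standard trade-off and the
equivalence tests bound what it can miss.

The genome-wide threshold is Bonferroni on the Li–Ji effective number of
independent tests, computed per scaffold (the natural linkage block of a
fragmented assembly — a panel-wide eigendecomposition would be impossible at
the scale this method targets) and summed.  Eigenvalues are rounded to 8
decimals before the integer-part split because the Li–Ji count is
discontinuous at integers.  The scan-calibration diagnostic samples 3,000
markers (or all) and compares observed p-value quantiles of the kinship
model and of uncorrected regression against uniform expectations, plus a
λ_GC-style inflation statistic (median observed χ² over the χ²(1) median).

Per-marker explained variance is the squared correlation between marker
scores and phenotype, on the same accession-mean phenotype the scan uses —
deliberately without kinship re-correction, since it feeds the
explained-variance accounting of the MultiQTL model, which approximates
heritability.

## MultiQTL forward selection

A QTL is a group of significant markers mutually collinear with a
representative; the model is the ordered set of non-collinear
representatives.  Selection repeats: (1) among remaining significant
candidates, pick the one with the largest explained variance conditional on
the representatives already chosen (ties: smaller marginal p, then
lexicographic id); (2) absorb every remaining candidate with |r| >=
r_collinear **to the representative** into its group; (3) in the default
conditional mode, stop when the best candidate's conditional test no longer
clears the genome-wide threshold.  The conditional stop rule is the
conservative choice where the selection literature offers several; a
marginal mode (no stop, ordering only) exists and drives the
threshold-sensitivity scan, whose degenerate ends (r = 1: every significant
marker its own QTL; r = 0: one QTL) only make sense without the stop rule.
Model explained variance is the squared correlation between fitted values of
the plain least-squares fit on the representatives and the observed
phenotype, reported unadjusted (comparable across models) and with a
small-sample adjustment.

## Cross-location QTL regions

For one trait, representative markers from the per-location models form a
graph with edges between markers of different locations at |r| >=
r_collinear; connected components touching at least two locations are QTL
regions.  Components are the least arbitrary reading of "correlated
representatives" but are single-linkage, so a region whose members include a
cross-location pair *not* directly above threshold is flagged as chained.
Within-location representatives are non-collinear by construction, so only
cross-location edges exist at the default threshold.  Regions are numbered
deterministically (location count, then smallest member id).  A region may
list several markers for one location when distinct per-location QTLs join
one component; the tabular report keeps them side by side rather than
forcing one per cell.

## The synthetic panel

The generator produces the statistical structure the analysis assumes, at a
scale where every experiment runs in minutes:

* **Reference panel**: 150 accessions in 5 subpopulations, 200 scaffolds of
  130–600 kbp carrying 25 markers each (5,000 markers), 3 locations.
* **Drift**: each subpopulation is a finite pool of K founder haplotypes,
  K = round(1/F) with F = 2t/(1+t) calibrated so the pairwise ratio-of-sums
  FST between equal subpopulations equals the target t (defaults
  t = 0.02–0.06, mirroring the low differentiation of a cultivated panel).
  Pool haplotypes are generated by a latent copying chain along each
  scaffold (copy probability exp(−decay_rate·d), decay_rate 8·10⁻⁶/bp), so
  *linked markers drift together* — without this, drift noise is independent
  per marker and dilutes panel-level LD below anything a real population
  shows.
* **Marker layout**: markers come in restriction-site loci (3 SNPs within
  ~300 bp), the clustered pattern of reduced-representation libraries.
* **Accessions**: a pooled accession is 8 diploids whose 16 alleles trace
  back to 6 founder haplotypes (narrow seed lots; within-accession
  heterogeneity is a parameter, not a constant of nature).  Founder chains
  are cut at the subpopulation frequencies, so scores are exact counts on
  the 1/16 grid and marginal frequencies — hence FST — are undistorted.
* **LD floor**: a calibrated fraction π of accession founder chains are
  scaffold-conserved (one latent for the whole scaffold).  Far-apart markers
  on a scaffold then stay correlated at π·ρ(p,p′)·v/(v+F̄), with ρ the
  shared-latent copula correlation and v the founder-multiplicity variance
  factor; π is solved by quadrature so the median far-pair r² equals the
  configured floor (0.1).  Because conservation is idiosyncratic to each
  accession, the floor is largely invisible to the accession-level kinship:
  long-range linkage does not masquerade as population structure, which is
  what lets a kinship-corrected scan retain power on such a panel.
* **Cross-scaffold LD**: a 2% minority of markers are noisy founder-level
  copies of markers on other scaffolds (per-founder resample probability
  0.25), reproducing occasional large correlations between distant markers.
* **Phenotypes**: y = Σ_k β_k x_k + g + e per location.  Effect sizes are
  set from the realized score variances so each planted QTL's marginal
  explained variance matches its configured fraction; g is drawn with
  covariance proportional to the realized kinship when a polygenic fraction
  is configured; e is scaled per location so the realized broad-sense
  heritability hits its target.  Cross-location effects share a correlation
  parameter (1 = identical effects everywhere; the limit used for
  cross-location recovery experiments).  The reference trait plants five
  QTLs of 12% variance each at H² = 0.6 — heritability fully attributed to
  the planted QTLs; purely polygenic traits (H² = 0.9, matching the upper
  range of real fiber-trait heritabilities) are used for the calibration
  experiments instead.  Causal markers are drawn from QC-eligible markers on
  distinct scaffolds with pairwise |r| < 0.1, i.e. planted QTLs are
  near-orthogonal.

What the generator does **not** emulate: sequencing and SNP-calling error,
unequal pool contributions, admixed accessions between subpopulations,
missing calls (QC's call-rate rule is exercised by constructed tables, not
by the generator), and selection/adaptive differentiation.  Passing tests
therefore say nothing about robustness to genotyping error or to admixture;
they do establish calibration and power under the assumed covariance
structure.

## Reference experiments

* **Null calibration**: 50 structured panels (120 accessions, 1,200 markers,
  5 subpopulations at FST 0.05, purely polygenic trait).  Median inflation
  of the kinship-corrected scan ≈ 1.0 (band [0.9, 1.1]); uncorrected
  regression inflates severely (≈ 2–4); essentially no marker passes the
  Li–Ji Bonferroni threshold.
* **Recovery**: 20 reference panels.  Mean forward-selection power ≈ 0.83,
  false-discovery proportion < 0.02.  Cross-location region matching loses
  essentially nothing: among planted QTLs detected by the models in ≥ 2
  locations, ≈ 98% are joined into regions.  Recovery of *all* planted QTLs
  as regions is ≈ 0.5 — per-location detection power at these effect sizes
  is ≈ 0.5 (its theoretical envelope given the non-centrality and the
  genome-wide threshold), so requiring two of three locations cannot do
  better; the two numbers are reported separately for that reason.
* **Threshold sensitivity**: pooled over 6 panels × 3 locations, QTL counts
  and explained variances change by ≈ 10% across r ∈ {0.1, 0.2, 0.3} and
  the count rises by ≈ 50–70% from r = 0.3 to r = 0.9.  The
  explained-variance surge seen at full scale does not reproduce here: with
  ~10 significant markers per scan each extra representative adds ~0.01
  absolute R², whereas models absorbing hundreds of significant markers
  overfit dramatically.  This is a scale limitation, not a property of the
  method.

Problem sizes above were chosen so the full suite and the reproduction
script each run in a couple of minutes on one core.

## Numerical choices

* Sample SD (ddof = 1) in the QC variation rule; the rule's originator did
  not specify a denominator.
* REML: spectrum clipped at 0; δ searched on log scale; boundary fits
  flagged rather than erroring.
* Li–Ji eigenvalues rounded to 8 decimals before the integer split.
* Forward-selection residualization is sequential Gram–Schmidt on the
  candidate block; conditional p-values use χ²(1) on the partial-t squared,
  matching the scan's reference.
* Degenerate inputs: empty QC survivor sets return an empty panel with a
  warning-level report; scans skip constant columns (impossible post-QC);
  an empty significant set yields an empty model with explained variance 0;
  fewer than two locations is an error for region matching.
* Tables are TSV with 6-significant-digit floats; pool-grid scores
  round-trip exactly at that precision.
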