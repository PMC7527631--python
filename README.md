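# scafqtl

Assembly-free GWAS and MultiQTL modeling for pooled allele-frequency panels.

`scafqtl` is for association mapping in crops (and other organisms) where
two common shortcuts are unavailable: accessions are genotyped as **pools**
— so a "genotype" is the frequency of the major allele among the pooled
chromosomes, not a 0/1/2 dosage — and the reference genome is a **draft
assembly in scaffolds**, so QTLs cannot be delimited by chromosome
position.  The workflow was developed for fiber-quality traits in hemp
(*Cannabis sativa*), where each accession is a pool of 8 plants (16
alleles) scored at hundreds of thousands of RAD-seq SNPs on tens of
thousands of scaffolds, phenotyped across multiple field locations.

The pipeline:

1. **Marker QC** — four-rule informative-marker selection on per-accession
   nucleotide frequencies (100% call rate; major-allele frequency within
   [0.02, 0.98]; top-two alleles ≥ 0.95 of frequency mass; SD of the
   major-allele frequency ≥ 0.1) and scoring as major-allele proportions.
2. **Structure** — VanRaden-style genomic relationship matrix adapted to
   frequency-scale genotypes (K = ZZ′/Σp̄(1−p̄)), PCoA, dendrogram, and
   pairwise Wright FST between clusters,
   FST = (p̄(1−p̄) − Σ cᵢpᵢ(1−pᵢ)) / p̄(1−p̄), as a ratio of sums over
   markers.
3. **LD** — within-scaffold r² against physical distance; the long-range
   baseline (≈ 0.1 in this kind of panel) calibrates the collinearity
   threshold |r| ≥ 0.3 (r² ≥ 0.09 ≈ 0.1).
4. **GWAS** — kinship-corrected linear mixed model y = Xα + Kβ + e fit by
   REML (EMMAX/P3D-style: variance ratio from the null model, per-marker
   GLS with Wald tests against χ²₁), Bonferroni threshold on the Li–Ji
   effective number of independent tests per scaffold, and a cumulative
   p-value diagnostic contrasting corrected and uncorrected scans.
5. **MultiQTL** — forward selection over significant markers: a QTL is a
   group of collinear significant markers represented by the member
   explaining the most variance; model explained variance is the squared
   correlation of fitted and observed phenotypes.  A threshold-sensitivity
   scan over r ∈ {0.1, ..., 0.9} and a PCA of significant-marker profiles
   round out the model diagnostics.
6. **Cross-location regions** — representative markers from per-location
   models are linked across locations at |r| ≥ 0.3; connected components
   spanning ≥ 2 locations are QTL regions, with transitive chaining
   flagged.

A synthetic-panel generator (`scafqtl.simulate`) reproduces the statistical
structure this analysis assumes — pooled scores on the 1/16 grid,
subpopulations at pairwise FST 0.02–0.06 via finite founder pools,
within-scaffold LD decaying to a distance-independent r² floor, clustered
restriction-site markers, and multi-location traits with planted QTLs,
polygenic background and configurable G×E — together with the ground truth
needed to score QTL recovery.  See `docs/methods.md` for the model and its
assumptions.

## Worked example

```python
from scafqtl import simulate, structure, gwas, multiqtl, crossloc, io

cfg = simulate.SimulationConfig(seed=1)          # 150 accessions, 5,000 markers
_, freqs = simulate.simulate_subpop_frequencies(cfg)
panel, scaffolds, subpops = simulate.simulate_pooled_genotypes(freqs, cfg)
phenotypes, truth = simulate.simulate_phenotypes(panel, cfg)

kinship = structure.vanraden_kinship(panel)
m_eff = gwas.effective_tests(panel)
print(f"markers: {panel.n_markers}, effective tests: {m_eff:.0f}, "
      f"threshold: -log10 p >= {gwas.significance_threshold(0.05, m_eff):.2f}")

models = []
for location in cfg.locations:
    y = io.phenotype_vector(phenotypes, "T1", location)
    null = gwas.fit_null_lmm(y, kinship)
    scan = gwas.scan_markers(panel, y, null, m_eff=m_eff, trait="T1", location=location)
    model = multiqtl.forward_select(scan, panel, y)
    models.append(model)
    print(f"{location}: h2_hat={null.heritability:.2f}, "
          f"{int(scan.table.pass_threshold.sum())} significant markers, "
          f"{model.n_qtls} QTLs, explained variance {model.explained_variance:.2f}")

regions = crossloc.match_regions(models, panel)
for region in regions:
    print(region.region_id, region.markers_by_location)
print("recovery vs truth:", simulate.score_recovery(models, truth, panel))
```

prints

```
markers: 5000, effective tests: 2434, threshold: -log10 p >= 4.69
L1: h2_hat=0.83, 5 significant markers, 2 QTLs, explained variance 0.36
L2: h2_hat=0.84, 3 significant markers, 2 QTLs, explained variance 0.35
L3: h2_hat=0.91, 5 significant markers, 2 QTLs, explained variance 0.33
QTL_T11 {'L1': ['scaffold99_41305'], 'L2': ['scaffold99_41305'], 'L3': ['scaffold99_41305']}
QTL_T12 {'L2': ['scaffold167_145583'], 'L3': ['scaffold167_208285']}
recovery vs truth: {'n_causal': 5, 'n_detected': 6, 'n_true': 6, 'n_false': 0, 'power': 0.6, 'fdp': 0.0}
```

Reading the output: the 5,000 correlated markers amount to ~2,400
independent tests, setting the genome-wide threshold at −log₁₀p ≈ 4.7.  In
each location the scan finds a handful of significant markers which forward
selection condenses into 2 non-collinear QTLs explaining about a third of
the phenotypic variance.  One QTL is anchored by the same marker
(`scaffold99_41305`) in all three locations and becomes the three-location
region `QTL_T11`; another links two markers of scaffold167 across two
locations.  Scoring against the simulation truth: every detected QTL tags a
planted causal marker (no false discoveries), and 3 of the 5 planted QTLs
were detected in at least one location in this single replicate.

## Command line

Each stage is a subcommand reading the previous stage's outputs:

```
scafqtl run      --config cfg.yaml            # everything end to end
scafqtl simulate --config cfg.yaml --seed 1
scafqtl qc       --config cfg.yaml
scafqtl structure --config cfg.yaml
scafqtl ld       --config cfg.yaml
scafqtl gwas     --config cfg.yaml
scafqtl multiqtl --config cfg.yaml
scafqtl crossloc --config cfg.yaml
```

The YAML config sets thresholds (`alpha`, `r_collinear`, QC bounds), the
output directory, the seed, input paths (frequency table or pre-scored
matrix, phenotypes, scaffold index) and, for simulated runs, the panel
parameters.  Outputs are TSV tables (scores, kinship, PCoA, FST, LD pairs,
scans), newick (dendrogram) and JSON (MultiQTL models, QTL regions,
truth), all reproducible byte-for-byte given config and seed.

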