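# Methods

## The problem setting

Genome skimming of a group of closely related plant taxa yields, per
individual, aligned sequences for many genetic regions from three genome
compartments: plastid protein-coding genes and intergenic spacers,
mitochondrial protein-coding genes, and the nuclear ribosomal cistron
(18S–ITS1–5.8S–ITS2–26S). The package evaluates how useful different
concatenations of these regions are as multilocus barcodes: how variable
each data set is, whether it exhibits per-taxon barcoding gaps, whether
taxa come out monophyletic with support, how an automatic partitioning
method groups the individuals, and how haplotypes and populations relate.

Seven data-set codes are built by default: A (all plastid genes), B (all
mitochondrial genes), C (all plastid spacers), D (the full nrDNA cistron),
E (ITS = ITS1–5.8S–ITS2), F (*matK*+*rbcL*), and G (divergence hotspot
regions). Membership is configuration (YAML), not hard-coded; G defaults
to rps1, rps2, rps14, ycf3-psaA and trnE-clpP.

## Distances

All sequence distances are Kimura 2-parameter,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the transition/transversion difference proportions over
pairwise-complete sites. Missing data (gaps, N, IUPAC codes) are handled
by **pairwise deletion** by default — the common default of desktop
phylogenetics software — with complete deletion available by flag. When
the logarithm's argument is non-positive the pair is *saturated*: it is
masked in matrices (never clamped), and every downstream criterion that
would need a masked pair fails loudly rather than silently degrading.
Population-level divergence is the mean K2P over cross-population sample
pairs; its standard error comes from bootstrap resampling of alignment
columns (B = 1000 by default), implemented as multinomial column weights,
which is the same resampling distribution but vectorizes.

## Site classification and hotspot detection

Columns are classified from unambiguous bases only (A/C/G/T; everything
else is missing, MEGA-style): *constant* (≤ 1 state), *singleton variable*
(≥ 2 states, only one shared by ≥ 2 sequences), *parsimony informative*
(≥ 2 states each in ≥ 2 sequences), *indeterminate* (< 2 usable
characters). Report percentages are `100·count/length` rounded **half-up
to 3 decimals** (2 decimals for discrimination rates) using exact decimal
arithmetic, so printed tables are bit-reproducible. Data sets rank by
percent variable sites, descending, ties broken alphabetically.

A region is a **divergence hotspot** when its percent variable sites
strictly exceeds `mean + 2·SD` across regions, with the sample standard
deviation (n−1). Strict inequality means a zero-variance profile flags
nothing; the scan runs jointly over all regions by default (the
mean/SD basis is a config choice). The threshold is undefined for fewer
than two regions, and the pipeline skips the scan in that case.

## Delimitation criteria

* **Tree-based.** Trees are neighbor joining (scikit-bio's Saitou–Nei
  implementation) over K2P distances; negative branch lengths are clamped
  to zero with the excess moved to the sibling branch. Edge support is the
  percentage of column-bootstrap replicates whose rebuilt tree contains
  the same unrooted bipartition; replicates that produce a saturated pair
  are dropped and logged, and more than 10 % drops is an error. A taxon
  succeeds when some internal edge splits off exactly its samples with
  support **strictly above 50**. Working with unrooted bipartitions avoids
  any rooting convention; externally computed trees (e.g. maximum
  likelihood) are accepted through the newick reader, with supports as
  internal node labels or as bracketed comments. The built-in NJ/bootstrap
  path is a deliberate, documented substitute for a full ML analysis: the
  criterion itself is tree-agnostic.
* **Distance-based (barcoding gap).** Per taxon, pairwise extremes:
  success iff the minimum inter-taxon distance strictly exceeds the
  maximum intra-taxon distance. Single-sample taxa are *not assessable*
  (monophyly and intra-taxon distance are undefined) and count as failures
  in rate tables so every cell shares the taxon-count denominator.
* **ASAP-style partitioning.** Single-linkage clustering of the distance
  matrix at every midpoint between consecutive distinct pairwise distances
  yields a nested ladder of candidate partitions from all-singletons to
  one group. Every non-trivial candidate (2 ≤ groups ≤ n−1) is scored by
  two ranked components, and the score is the mean of the two ranks
  (lower = better): gap width `w = min_between − max_within` ranked
  descending, and a panmixia probability ranked ascending. The panmixia
  probability is a seeded permutation test: the share of random sample
  relabellings (group sizes preserved) achieving a gap width *strictly
  wider* than observed. Strictness matters: a few-group candidate is
  occasionally recreated verbatim by a random relabelling, and counting
  those equal-gap events would systematically penalize exactly the
  well-separated partitions the score should favour. This scorer is a
  self-contained surrogate for the published ASAP web service — same
  skeleton (hierarchical candidates, two ranked components, averaged-rank
  score), but the original's coalescent-based probability is replaced by
  the permutation test; reproducing the web server's exact partitions or
  scores is a non-goal. A taxon succeeds when the best-scoring partition
  contains a group equal to exactly its sample set.

## Haplotype networks

Samples collapse to one haplotype when identical at all columns where both
are unambiguous (missing-tolerant matching, closed transitively with a
union-find; a partially ambiguous sequence can therefore bridge two
distinct sequences). The median-joining network is built Bandelt-style:
Hamming distances over mutually unambiguous columns; the minimum-spanning
network (union of all MSTs — an edge is kept iff its weight is within
epsilon of the minimax path weight between its endpoints, with
epsilon = 0 by default); then median vectors are added iteratively for
*connected triplets* (three nodes sharing ≥ 2 network edges) as the
per-site-majority consensus — sites where all three states differ
contribute no median, a documented restriction of the full quasi-median —
whenever the consensus is novel and strictly reduces the triplet's
connection cost; finally median vectors of degree ≤ 2 are pruned and the
network rebuilt. With unique connection weights and epsilon = 0 the result
is exactly the MST.

## Ordination

Classical PCoA: Gower double-centering `B = -1/2 J D² J`, symmetric
eigendecomposition, coordinates scaled by the square root of positive
eigenvalues. Negative eigenvalues (non-Euclidean distance sets) are
reported and their axes dropped; no Lingoes/Cailliez correction is applied
so the user can judge the distortion from the reported magnitudes. Axis
signs are fixed by making each axis's largest-magnitude loading positive,
giving platform-independent output.

## The synthetic data generator

The generator exists so every stage can be tested against planted truth.
Sequences evolve along a binary newick species tree (branch lengths in
expected substitutions/site) under K2P: per site, Poisson(branch ×
rate_multiplier) substitution events; each event is a transition with
probability kappa/(kappa+2) (kappa = ts/tv rate ratio, default 2.0),
otherwise a uniform transversion. Every event is recorded per site in an
event log, making substitution-type statistics directly testable. Below
the species tree two layers model population structure without coalescent
machinery: each population receives founder mutations at half the
between-population divergence, each sample private mutations at half the
within-population diversity θ (so expected within-population pairwise
diversity ≈ θ); both scale with the region's rate multiplier. A hybrid
taxon is a fixed mosaic — each compartment's ancestral sequence is copied
wholesale from a designated parent leaf (no per-site recombination) —
after which its populations vary like any other taxon's. Organellar
compartments carry exactly one haplotype per sample, and nrDNA is treated
as a single concerted-evolution sequence; no heterozygosity is
represented. Gaps/Ns are absent unless a missingness fraction is set.

### Default study design and why

* 32 samples, 6 taxa: four closely related complex members (two of them
  sister taxa), one distant congener on a long branch, and one hybrid
  whose plastid and nrDNA derive from the congener and whose mitogenome
  derives from a complex member; 16 populations (1–4 per taxon), 2 samples
  each.
* 95 regions mirroring a real genome-skimming inventory at ~1/10 length:
  57 plastid genes (including matK 152 bp, rbcL 143 bp; others 80 bp), 18
  spacers (39 bp; the two hotspot spacers 80 bp, as spacer lengths vary
  widely), 15 mitochondrial genes (56 bp), and the 5 nrDNA parts at 1/10
  of 1812/2482/158/241/3155 bp.
* Species-tree branch lengths of a few 10⁻³ substitutions/site, θ = 0.001,
  between-population divergence 0.002 — the order of magnitude seen
  between closely related conifer lineages. Because region lengths are
  scaled down tenfold, per-site rates sit higher than real data's
  variability percentages; keeping expected per-region variable-site
  counts informative at short lengths is the deliberate trade-off, and it
  keeps all distances far from K2P saturation.
* Compartment rate multipliers 1 (plastid genes), 2 (spacers), 6
  (mitochondrial), 0.7 (nrDNA), and 18 for the five planted hotspot
  regions — an ~18-fold contrast, matching the roughly twenty-fold
  variability gap such hotspot screens are designed to expose. A Poisson
  calculation at these settings puts each planted region's expected
  variability far above the mean + 2 SD threshold, which is why the
  recovery property (all five flagged in ≥ 95 % of seeded runs) holds with
  margin rather than by luck.

What the generator does **not** emulate: indels and alignment error
(regions are generated aligned; gaps only via the missingness mask),
coalescent gene-tree discordance and incomplete lineage sorting,
within-region rate variation, recombination, paralogy/heteroplasmy, and
base-composition bias. Passing tests therefore demonstrate correctness of
the statistics and algorithms under the stated model, not robustness to
those real-data complications.

## Numerical and procedural choices

* Percentages: exact decimal arithmetic, half-up rounding (3 decimals for
  variability, 2 for rates).
* All inequalities in criteria are strict (> threshold, gap >, hotspot >),
  so ties fail rather than pass.
* Determinism: a single pipeline seed feeds every stochastic stage through
  a seed sequence; same configuration + seed reproduces every table byte
  for byte. Bootstrap and permutation draws use numpy Generator streams.
* Column coordinates are 0-based half-open internally; report tables print
  1-based inclusive spans.
* Desk-scale defaults used by the acceptance script: 200 bootstrap
  replicates and 499 permutations — Monte-Carlo noise on supports and
  p-values at these sizes is well below the decision thresholds they feed;
  the library defaults remain 1000/999.

## Known limitations

* The NJ/bootstrap tree path is a substitute for maximum-likelihood
  analysis; on real data, supply an ML tree with supports instead.
* The ASAP scorer is a surrogate (above); use it for relative comparisons
  within a study, not to reproduce web-server output.
* The barcoding-gap criterion uses pairwise extremes, so a single outlier
  individual can flip a verdict; that sensitivity is inherent to the
  criterion, not smoothed away.
* Median-joining with many reticulations can add many median vectors;
  interpretation of individual medians as ancestral haplotypes is not
  warranted, only the connection structure.
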