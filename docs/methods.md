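# Methods

`receptoire` quantifies whether plant immune-receptor gene families expand
and contract together across species. This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Receptor identification

Each species contributes one annotated proteome. Proteins are first reduced
to primary transcripts: one isoform per gene, the longest, with ties broken
by lexicographically smallest protein id. (Annotation databases differ in
how they flag a "primary" model; longest-isoform is the standard proxy and
the choice is logged.) The searched-gene total of a species is the number
of primary transcripts — the denominator of every percentage.

Classification is rule-based on precomputed Pfam domain hits (HMMER
`--domtblout` tables or an equivalent 9-column TSV) plus a transmembrane
summary:

| Family | Rule |
|---|---|
| LRR-RLK | length >= 250 AA, kinase hit (PF00069, E <= 1e-10), LRR hit (any of 14 LRR families, E <= 1e-2) |
| LRR-RLP | length >= 150 AA, LRR hit, **no** kinase hit at the kinase threshold, C3F hit (E <= 1e-10, alignment >= 140 AA), >= 1 TM helix |
| NB-ARC | length >= 150 AA, NB-ARC hit (PF00931, E <= 1e-10) |
| LysM-RLK/RLP | length >= 150 AA, LysM hit (PF01476, permissive E <= 1000), >= 1 TM helix; split by kinase-hit presence |

Conventions that the rules leave open, fixed here:

* Thresholds apply to the **full-sequence** E-value (matching `hmmsearch -E`
  semantics) and are **inclusive** on the passing side; the C3F length
  filter uses alignment (`ali`) coordinates.
* Pfam accessions match version-tolerantly (`PF00069.26` satisfies a
  `PF00069` rule), so any Pfam release works.
* The four family rules are evaluated independently; a protein satisfying
  several rules (e.g. NB-ARC plus kinase plus LRR) is counted in every
  matching family. Such proteins are rare, logged, and reported.
* A candidate that satisfies every sequence-level LRR-RLP requirement but
  has no TM record raises an error rather than guessing; for LysM
  candidates, whose domain search is deliberately permissive, a missing TM
  record counts as no helix.
* A built-in sliding-window Kyte–Doolittle predictor (window 19, mean
  hydropathy > 1.6, merged runs) can stand in for a missing TM table. It is
  a coarse screen, not a topology model.

### Subgroup assignment

LRR-RLK candidates are assigned to one of the 20 canonical subgroups
(I–XV, with the VI/VII/VIII/X splits) by their kinase domain: the envelope
of the highest-scoring kinase hit (ties: smallest envelope start) is
extracted and locally aligned (Smith–Waterman, BLOSUM62, gap open 11 /
extend 1) against a reference panel of subgroup-labelled kinase domains;
the best-scoring panel entry wins, provided its score reaches a floor
(default 50 bits — a length-scaled stand-in for an aligner E-value cut of
1e-10; aligner E-value calibration is tool-specific, so the floor is a
plain configurable score). Below the floor the candidate is
"unclassified". Reference panels built from full-length receptors are
pruned through the same kinase/LRR filters the candidates face.

## Percentage normalization and correlation

Counts are normalized per species as `count / searched_total * 100`.
Percentages are invariant under whole-genome duplication (both numerator
and denominator double), which is the reason to correlate percentages
rather than raw counts across species of wildly different proteome sizes.
Derived columns — LRR-RLK excluding subgroup XII, and LRR-RLP plus XII —
are computed as count sums before normalization.

The correlation suite computes the sample Pearson r of each receptor
column against %NB-ARC with a two-sided t-test (df = n − 2) and Bonferroni
adjustment across the executed suite (k = number of tests actually run).
Species with zero percentages can be excluded per pair via a flag, since
published analyses sometimes drop null cells. p-values below double
precision print as "< 1e-300" and are stored as 0.

## Phylogeny-aware tests

Percentage vectors become distance matrices via absolute difference
(the natural 1-D Euclidean metric; no metric is canonical here), the
species tree via patristic distances. The Mantel statistic is the Pearson
correlation of upper-triangle entries; its p-value permutes rows/columns
of one matrix simultaneously, one-sided ("greater", the vegan default),
with the add-one estimator p = (1 + #{r_perm >= r_obs}) / (N + 1), so p is
never 0 and the test is exact-level. Permuted statistics tied with the
observed one (to 1e-9) count as "at least as extreme" — required for
validity on small label sets where the permutation distribution has
symmetry ties. The partial Mantel statistic is the first-order partial
correlation of condensed matrices; permutation is applied to the first
matrix, the control correlation r_BC staying fixed. Defaults: 10,000
permutations (tests use 99–4,999 for speed). FDR correction is
Benjamini–Hochberg. Species present in the table but absent from the tree
are dropped with a log message (published trees rarely cover every
genome). A Spearman flavour of the Mantel statistic is deliberately not
implemented; Pearson on distances is what the cited convention computes.

## Genomic co-clustering test

Whether group A genes (say, LRR-RLK subgroup XII) lie closer to group B
genes (NB-ARC) than chance expects: the observed statistic is the mean,
over A genes, of the closest distance to a B gene on the same
chromosome/scaffold. Distance is the inter-interval gap in bp (overlap or
abutment = 0), strand-agnostic; gene-start-to-gene-start is available as
an alternative convention but gap is the default because it does not
depend on gene length. A genes with no same-sequence B gene are undefined
and excluded from the mean (any finite sentinel would distort it); the
excluded count is reported. A gene never measures distance to itself
(identical gene id), while co-located distinct genes legitimately score 0.
The null resamples m = |B| genes uniformly **without replacement** from
the gene universe that was searched for group B (1,000 times by default;
with-replacement available for sensitivity checks), and
p = (1 + #{null mean <= observed}) / (N + 1), one-sided "closer".

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
a desk scale, with full ground truth:

* **Counts.** A species-level latent factor z_s ~ N(0,1) (overall
  investment in immune receptors) enters every family's log-rate:
  N_fs ~ Poisson(exp(a_f + b_f z_s)). Shared positive loadings create
  correlated family sizes. `calibrate_loading` solves closed-form moment
  equations (lognormal moments of the rates, Poisson conditional moments,
  exact inverse moments of the uniform proteome size) for the loading that
  hits a target percentage-scale Pearson r; the closed form is verified
  against large-sample Monte Carlo in the tests.
* **Default conditions** (chosen once): 300 species; mean counts 60
  LRR-RLK, 80 LRR-RLP, 7 LysM-RLK, 2.5 LysM-RLP, 200 NB-ARC; searched
  totals uniform on [900, 940]. These are scaled-down proteomes (real
  totals are tens of thousands); Pearson correlation is scale-free, so the
  correlation structure — the object of study — is preserved while a full
  300-species replicate stays at a few seconds. Two deliberate constraints
  on the totals range: it is *narrow*, so the shared denominator
  contributes negligible covariance between percentages (with all loadings
  zero the families must come out uncorrelated), and it sits *well above*
  the planted-count tail, so the searched total never collides with the
  planted sum (a collision couples denominator to numerator exactly at
  high-leverage species and visibly inflates the variance of the recovered
  correlation).
* **Proteomes.** Every planted receptor gets a protein record and hit/TM
  rows satisfying exactly one family rule, E-values sampled well inside
  the thresholds; decoys fail every rule in varied ways (no hits,
  kinase-only, LRR-only, all-domains-sub-threshold, short). Boundary
  fixtures are always planted: the first receptor of each family sits
  exactly at its inclusive threshold (250/150 AA, E = 1e-10/1e-2, C3F
  alignment 140), and decoys at 249/149 AA and C3F 139 pin the comparison
  direction. Sequences are random residue strings — classification
  consumes hit tables, not motifs — except planted LRR-RLKs, which embed a
  point-mutated copy of a panel kinase domain so subgroup assignment has
  signal. The reference panel itself is synthetic (random kinase-domain
  stand-ins, one per subgroup): random unrelated sequences are far apart
  under BLOSUM62, so best-hit assignment behaves as against a real panel.
* **Coordinates.** Genes are placed uniformly on a configurable
  chromosome; a configured fraction of group-A genes is instead planted
  within a window (default 50 kb) of an NB-ARC gene.
* **Tree.** Pure-birth (Yule) trees; optionally the latent factor evolves
  by Brownian motion along the tree, giving percentages phylogenetic
  signal of known strength (variance 0 = none).

What the generator does **not** emulate: real sequence evolution, HMMER
score distributions, annotation noise (split/merged gene models, missed
isoforms), assembly fragmentation, or biologically structured gene
clusters (tandem arrays). Passing tests therefore demonstrate that the
pipeline's logic and statistics are correct, not that the upstream domain
searches on real proteomes are sensitive or specific.

## Numerical and statistical notes

* Permutation p-values use the add-one rule and tie tolerance described
  above; minimum attainable p is 1/(N+1).
* The Fisher-z interval used in recovery checks, atanh(r) ± 1.96/sqrt(n−3),
  assumes bivariate normality. Percentages from the Poisson log-linear
  generator are mildly right-skewed, which inflates the sampling sd of
  atanh(r̂) by a few percent; measured coverage of the nominal 95% interval
  at the default conditions is ≈ 0.94–0.95. The generator's baselines were
  chosen large (hence loadings small) specifically to keep this gap small.
* Distance-matrix symmetry is enforced to 1e-12; patristic matrices from
  generated trees satisfy the four-point (additivity) condition, which the
  tests check.
* Deterministic behaviour everywhere: every stochastic routine takes a
  seed or `numpy.random.Generator`; identical seeds reproduce outputs
  bit-for-bit.

## Known limitations

* Subgroup assignment is best-hit against a panel; placement into
  per-subgroup phylogenies (an alternative published practice) is out of
  scope.
* The hydropathy TM fallback under-calls multi-pass topologies.
* The published per-species percentage table is not redistributable with
  this package; the loader accepts it as CSV (`species`, `clade`,
  `pct_<family>` columns) for users who obtain it, and the corresponding
  check in the test suite fails with a pointer until the file is supplied.
* Cross-chromosome gene pairs have undefined distance by design; on highly
  fragmented assemblies many group-A genes may be excluded from the
  co-clustering statistic (the excluded count is reported so this is
  visible).
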