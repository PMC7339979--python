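# Methods

This note documents the model, the synthetic-data generator that stands in
for the (non-redistributable) real inputs, the numerical and design choices,
and what the package's tests do and do not demonstrate about real data.

## The prediction model

**Inputs.** A PDC pharmacogenomic screen: a binary mutation matrix over a
fixed gene panel (cells × genes), per-drug chemical fingerprints
(fixed-length bit-vectors), and a cells × drugs dose-response matrix
AUC_DR with missing entries. Lower AUC_DR means a stronger response
(more sensitive); that convention is carried in the data model
(`PlantedRule.direction`) rather than hard-coded in any stage.

**Digitalization.** Edge labels on the cell–drug bipartite graph come from a
per-drug quantile split of AUC_DR (default the median, boundary `<=`).
Per-drug rather than global, because AUC_DR scales differ between compounds.
A global absolute threshold is available. The split is binary; if a
non-median quantile is chosen, the resulting class imbalance is handled by
inverse-prevalence instance weights in the classifiers. Any drug with fewer
than four measurements is rejected rather than thresholded on noise.

A property worth stating precisely: a median split reproduces a planted
bimodal sensitivity structure *exactly* only when each drug's sensitive
fraction is at least one half — otherwise the median falls on the resistant
mode and the split over-calls sensitivity. It can never under-call a truly
sensitive pair in the noiseless limit. The unit tests assert both facts.

**Kernels.** Jaccard similarity between mutated-gene sets (genomic side) and
the Tanimoto coefficient between fingerprint bit-vectors (chemical side) —
the same set statistic under its two field names. Both are bounded in
[0, 1], have unit diagonal, and are provably positive semidefinite; the
`KernelMatrix.validate` check asserts symmetry, unit diagonal and a minimum
eigenvalue ≥ −1e−8. Two all-zero vectors are defined to have similarity 1
(identical empty sets). A Gaussian-on-binary alternative
(`exp(−γ·‖x−y‖²)`) sits behind the same interface. No kernel centring or
normalisation is applied: both kernels are already commensurate and bounded.

**Pair representation.** A (cell, drug) pair is the concatenation of the
cell's genomic-kernel row over the anchor cells and the drug's
chemical-kernel row over the anchor drugs (anchors default to the full
training sets). This feeds random forests and SVMs identically, and lets an
out-of-training patient enter purely through kernel rows against the
anchors — no refit at prediction time.

**Training.** Grid-search with stratified, seeded 5-fold cross-validation,
scored by AUROC on held-out folds. The SVM grid is
C ∈ {0.01, 0.1, 1, 10, 100} × γ ∈ {1e−3, 1e−2, 0.1, 1, 10}; ties prefer the
smallest penalty, then the smallest width, so selection is deterministic.
The random forest uses a fixed 500-tree ensemble with default feature
subsampling (a single grid point), and the optional feed-forward network a
single 64-unit hidden layer with early stopping. The selected configuration
is refit on all pairs. The CV unit is the (cell, drug) pair by default,
matching how such models are usually evaluated; a leave-cells-out mode
(`cv_unit="cell"`) is provided because per-pair CV leaks cell identity
across folds (see *Generalisation* below).

**AUROC.** Computed by the rank-based Mann–Whitney construction (ties count
1/2). The test suite checks it against a brute-force O(P·N) pairwise oracle
to 1e−12.

**Patient ranking.** Scores are sensitive-class probabilities; the RBF-SVM
is wrapped in sigmoid (Platt) calibration so its outputs live in [0, 1].
Drugs are ranked per patient (ties broken lexicographically by drug id) and
summarised per mechanism class by the mean score; patients are assigned to
the argmax class. An average-linkage Euclidean hierarchical grouping over
the class-score rows is available behind a flag for figure-style clustering;
argmax is the default because it is deterministic and directly
interpretable. Patient metadata (ethnic group, tumour site) may be carried
as annotation columns but is never used as a feature.

### Generalisation: why the deployed default is the SVM

Under per-pair CV, each training cell's own anchor column contains an exact
1.0 self-similarity spike, so a tree ensemble can resolve cell identity and
effectively memorise each cell's per-class response. That inflates nothing
*within* the screen (the spec of the evaluation is per-pair), but it does
not transfer: on simulated patients the forest's class recovery collapses
(≈0.44 at the planted-cohort scale) while its CV AUROC stays ≈0.96. The
RBF-SVM learns a smooth function of the similarity profile and transfers
(≈0.88–0.98 recovery at the same scale, CV AUROC ≈0.95). All three
classifiers remain available behind one interface; the pipeline deploys the
SVM by default.

### Numerical choices

- SVM grid search reuses one precomputed RBF Gram matrix per γ across all C
  values and folds (mathematically identical to per-fit kernel evaluation);
  above 12,000 pairs the O(n²)-memory fast path is skipped automatically.
- Fold assignment is stratified by label and seeded; every stochastic
  component (simulation streams, CV shuffles, forest and calibration seeds)
  derives from explicit integer seeds, and the pipeline manifest records
  SHA-256 digests of every artifact so reruns can be compared byte for byte.
- Degenerate inputs fail loudly: single-class label sets, NaN features,
  all-missing drugs, mismatched panels or fingerprint lengths, conflicting
  genome builds, unknown ids.

## The synthetic-data generator

The simulator emulates the statistical shape of the study inputs: a
462-cell × 60-drug screen on a 91-gene somatic-mutation panel (the default
`SimConfig` scale), and paired tumour/germline exome variant calls.

- **Mutation profiles**: i.i.d. Bernoulli per gene. Default
  `mutation_rate = 0.5`. This is deliberately at the high end of what a
  recurrently-mutated cancer-gene panel shows (TP53 sits near 50% in gastric
  adenocarcinoma; most panel genes are lower): with a per-drug *median*
  digitalization, a planted genotype→class rule is identifiable exactly when
  the sensitive fraction per drug — which equals the target-gene mutation
  rate — is near one half. The default therefore makes the planted ground
  truth recoverable, which is the generator's purpose; rates representative
  of sparser genes can be set per experiment (several tests use 0.1–0.3).
- **Drugs and fingerprints**: mechanism classes assigned round-robin
  (default 6 classes over 60 drugs — a typical kinase-inhibitor MOA
  granularity; recovery experiments in the tests use 4). Each class owns
  `fingerprint_len/4` "core" bits always set for its members, plus random
  bits at density 0.1, which guarantees within-class Tanimoto similarity
  exceeds between-class similarity in expectation.
- **Dose-response**: AUC_DR = 0.7 − effect_size·[cell mutated in the
  class's target gene] + N(0, noise_sd), then a uniform `missing_frac` of
  entries masked. The 0.7 baseline simply keeps sensitive means positive at
  the default effect size of 0.5; real AUC_DR scales vary by screen and the
  per-drug digitalization is invariant to them. Uniform-at-random
  missingness is an assumption — real screens censor informatively.
- **Paired variant calls**: germline SNVs appear in tumour and normal;
  exactly `n_somatic` tumour-only SNVs are planted. Chromosomes are drawn
  from length-proportional weights with chromosome 7 tripled (emulating the
  chr7 SNP excess the pipeline is meant to surface), positions uniformly and
  uniquely per chromosome, substitution types from a 12-type distribution
  with C>T = G>A = 0.25 (transition-dominant, as in gastric tumour exomes)
  and the remaining ten types at 0.05. Written as minimal VCFv4.2, one ALT
  per record, 1-based positions, build declared via `##reference`.
- **Coverage**: constant depth per gene over 0-based half-open BED-style
  intervals, the shape produced by aggregating a bedtools-genomecov per-base
  track over an annotation.
- **Patients**: each simulated patient is assigned one drug class
  round-robin, guaranteed mutated in that class's target gene with the other
  class targets forced wild-type, and carries background mutations at the
  cohort rate elsewhere.

Reproducibility: one global integer seed feeds a splittable
`numpy.random.SeedSequence`; every output (mutations, fingerprints,
response, missingness, variants, patients) draws from its own child stream,
so outputs are individually stable. Identical configurations produce
byte-identical serialisations.

**What the simulator does not model**: raw reads and alignment artifacts,
indels and structural variants, copy number, expression, linkage between
genes, informative missingness, batch effects, and any real chemistry behind
the fingerprints. Passing the planted-recovery tests shows the pipeline's
machinery is correct and well-calibrated on data matching its assumptions —
not that comparable AUROCs would be reached on a real screen, where
signal-to-noise is far lower and mutation–response relationships are not
one-gene-per-class.

## Descriptive WES summaries

Somatic subtraction is an anti-join of tumour calls against matched germline
calls on (chrom, pos, ref, alt); it is idempotent and errors on declared
genome-build mismatches. Tallies cover the 24 canonical chromosomes and the
12 ordered substitution types *without* pyrimidine-strand collapsing (C>T
and G>A are reported separately, as the motivating analyses plot them);
both conserve per-sample record counts. Non-SNV alleles and non-canonical
contigs are dropped at the reader boundary with logged counts. Gene-level
coverage is the length-weighted mean depth over merged gene intervals with
uncovered bases counted as zero; it is exact interval arithmetic, linear
under depth scaling, and cross-checked against a per-base brute-force oracle
in the tests. Ranked-list overlap takes the top-k genes of two score tables
(ties at rank k broken lexicographically) and intersects them. Whether
tallies run on somatic-only or all tumour SNVs is an explicit CLI flag
(`--somatic-only/--all-snps`), since either convention is defensible.

## Problem sizes used in the checks

The planted recovery experiments run at 200 cells × 40 drugs × 91 genes with
4 classes, effect size 0.5, noise 0.1 (≈6,400 labeled pairs), 50 simulated
patients; tally checks use 5,000 SNVs; kernel validity uses 50 random small
cohorts; the determinism check runs the full pipeline twice at 80 × 20.
These sizes were chosen so the full battery completes in minutes on a single
CPU while keeping every statistical check comfortably powered.

## Known limitations

- The digitalization threshold of real screens is a modelling decision; the
  median default is a convention, not an estimate, and ordinal (>2-level)
  sensitivity is not supported.
- Per-pair CV overstates transfer performance (by design it is the screen's
  own evaluation unit); use `cv_unit="cell"` when the quantity of interest
  is generalisation to new samples.
- Expression-based kernels are not implemented; the genomic side is
  mutation-only, matching a panel-based deployment.
- Fingerprints are consumed as bit-strings; computing them from structures
  (SMILES) is out of scope.
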