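# Methods

## The question and the approach

TRFLP reads a community as a vector of labelled terminal-fragment (TRF)
peak areas. Reading those areas as relative genotype abundances is only
valid if the chain PCR → digestion → electrophoresis → peak calling is
effectively unbiased. `trflpsim` tests this by construction: communities of
*known* composition are pushed through a simulated (or real) measurement
chain, the resulting peak tables are processed with the standard filtering
rules, and the recovered profiles are compared against the bias-free
in silico prediction. Agreement is quantified at three levels —
between-community distance structure (Mantel tests), ordination geometry
(covariance PCA), and per-community diversity (Margalef, Gini-Simpson,
each regressed observed-on-predicted).

## Fragment arithmetic

Enzymes are defined by an IUPAC recognition pattern and a top-strand cut
offset: AluI = AG^CT (r = 4, c = 2, blunt), HinfI = G^ANTC (r = 5, c = 1,
3-nt 5′ overhang) — standard REBASE definitions. Both patterns are
reverse-complement palindromes, so scanning the stored strand finds every
double-stranded site; this is asserted at enzyme registration, and
non-palindromic enzymes require an explicit opt-out. Coordinates are
0-based half-open internally.

Two length conventions are provided. `labelled_strand` (default) measures
to the cut on the labelled strand itself and yields integers.
`duplex_mean` averages the top- and bottom-strand cut coordinates within
the site, i.e. site_start + r/2: identical to `labelled_strand` for blunt
AluI, but giving half-integer lengths (…+2.5) for HinfI. Published
predicted HinfI sizes for this assay end in .5, consistent with the
duplex-mean convention; the default remains `labelled_strand` and
cross-convention comparisons should use a ±2 bp tolerance.

Pseudo-TRFs — products of incomplete digestion — are enumerated exactly:
skipping any subset of the k cut sites leaves the labelled fragment ending
at the nearest retained cut (or the full amplicon for the empty subset),
so the reachable set is {distance to each cut beyond the first} ∪ {full
length} minus the complete-digest length. This equals brute-force
enumeration over all 2^k subsets (property-tested) at O(k) cost.
Sequences containing IUPAC ambiguity codes are readable from FASTA but are
rejected by digestion with an explicit error: an ambiguous base makes cut
certainty undecidable.

## Community templates

Nine templates over six genotypes: equal-abundance and broken-stick
designs at richness 4, 5 and 6, plus three two-genotype pairs at
(0.5+δ, 0.5−δ). Broken-stick proportions are MacArthur *expected* values
p_i = (1/n)·Σ_{k=i..n} 1/k (not a random partition) — deterministic,
summing to 1, strictly decreasing. The pair offsets default to
δ = 0, 0.025, 0.05; the original design's exact pair proportions are not
published, so these probe resolution at the few-percent scale and are
configurable, as are full custom template tables (TSV).

## Peak-table processing

Order of operations: channel/height/size filter → 2-bp binning → relative
abundance → cross-sample noise filter → split-peak pooling →
re-normalisation. Each rule is applied to the quantity it names:

- **Filter**: height strictly > 100 fluorescence units, size strictly
  > 100 bp (both worded as strict exceedances), dye restricted to the
  informative channel (HEX for AluI, FAM for HinfI; the complementary
  fragments are short and invariant).
- **Binning**: fixed half-open grid anchored at 100.0 bp, bins labelled by
  their lower edge. A fixed grid is chosen over clustering-based binning
  for determinism; the anchor is arbitrary but stated.
- **Noise filter**: a TRF bin is dropped everywhere if its mean relative
  area, over the samples *where it is present*, is ≤ 5% (inclusive, per
  the rule's wording "5% or less"). Idempotent by construction. Applied
  before pooling; the alternative order is not distinguishable from the
  published description.
- **Pooling**: capillary electrophoresis can render one TRF as 2–3 nearby
  peaks; bins matched to the same predicted complete TRF are summed under
  a canonical `genotype@size` label. Pseudo-TRF bins are deliberately not
  pooled — they are genuinely extra TRFs and should inflate observed
  richness, as they do in real data.
- **Matching**: an observed bin matches a predicted TRF when
  observed − predicted ∈ [−14, +2] bp, the empirical drift range (−13.4 to
  +1.1 bp) widened by ~1 bp. Nearest absolute deviation wins; ties go to
  the smaller predicted size; bins explicable only by pseudo-TRF lengths
  are flagged as such; the window is configurable.

## Bias simulator

The generator reproduces study conditions, not study data:

- **Genotypes**: rejection-sampled random sequences, length 527–548 bp and
  GC 39.7–41.7% (the reference amplicons' ranges), pairwise
  global-alignment identity ≤ 97% (the OTU delimitation cut-off; computed
  with edlib, trivially satisfied by random sequences), ≥ 2 AluI sites so
  the HEX channel can express pseudo-TRFs, and complete TRFs ≥ 120 bp and
  mutually ≥ 20 bp apart per enzyme. The 20 bp spacing mirrors the
  reference genotypes (whose TRFs sit ≥ 19–20 bp apart) and is a
  *physical* requirement: TRFs closer than the drift window cannot be
  unambiguously matched once drift and splitting act, so "uniquely sized"
  must be read on the drift scale.
- **Drift**: observed = predicted + a + b·predicted + N(0, σ), with
  a = −4.006 bp and b = −0.004343 fitted by least squares to the 21
  published predicted/observed size pairs of the assay (pseudo-TRF rows
  excluded), and σ = 1 bp jitter per peak.
- **Splitting**: with probability 0.7 a TRF's area is Dirichlet-split over
  2–3 peaks offset uniformly within ±4 bp — matching the observed 2–3
  similarly sized peaks spread over several bp.
- **Under-digestion**: a fraction pseudo_rate = 0.03 of a genotype's area
  (scaled by (richness−1)/(max_richness−1), since mixed templates
  under-digest more than single-genotype ones) is diverted equally across
  its pseudo-TRF lengths. The true magnitude in the original experiment is
  not published (only >99% completeness for single genotypes); 3% is a
  stated assumption kept ≤ 5%.
- **Noise and detection**: lognormal area noise with CV 0.10 (mean-1
  parameterisation), height = area/2, peaks below a 100-unit detection
  floor dropped. Replicate mixes perturb proportions with a 2% lognormal
  pipetting CV.

Per-sample randomness derives from one root seed via stable hashing of
(template, replicate, technical rep, enzyme), so datasets are reproducible
and insensitive to iteration order.

What the simulator does **not** model: chimera and heteroduplex formation
(the candidate mechanisms behind pseudo-TRFs are represented only as an
area-diversion rate), PCR cycle kinetics and primer mismatch, raw trace
shapes and size-standard calibration, and any genotype-specific
amplification bias. Passing tests therefore show that the *processing and
comparison machinery* is faithful and that the documented electrophoretic
artefacts do not destroy quantitative structure — they cannot certify any
particular wet-lab protocol.

## Comparison model

`TRFLPBiasModel` holds a predicted and an observed samples × TRFs matrix
(the two enzyme channels concatenated with weight 1/2 each, so each sample
row still sums to 1; how the original analysis combined channels is not
stated). PCA is covariance PCA — columns mean-centred, unscaled — via SVD
with a deterministic sign convention (largest-magnitude loading positive).
PCA is fitted on all 81 individual technical replicates; distances,
diversity and regressions use the 27 template-replicate means, which
reproduces the published regression degrees of freedom (1, 25).

Euclidean distances between PC scores default to *all* components
(equivalently, distances between mean-centred profiles, by PCA isometry),
following the stated "all PC scores" convention; restricting to the first
2 PCs is available and gives closely similar results here. The Mantel
statistic is the Pearson correlation of lower-triangle entries; the
one-sided p-value counts joint row/column permutations of the second
matrix with r at least the observed value, p = (count+1)/(n_perm+1),
n_perm = 10,000 by default. Margalef's N for fluorescence data is the
total filtered peak area per sample rounded to an integer (a choice, since
N is undefined for areas; results are insensitive at realistic totals
because N enters only through ln N). Simpson's index defaults to the
Gini-Simpson form 1 − Σp² (larger = more even), with the inverse form
available; the published analysis does not name its variant.

Degenerate inputs are handled explicitly: constant matrices yield zero
eigenvalues (not an error), all-zero abundance pairs get Bray-Curtis 0
with a warning, zero-variance distance triangles and zero-variance
regression predictors raise.

## Problem sizes and runtimes

The default study is the full design — 9 templates × 3 replicate mixes ×
3 technical reps = 81 samples per enzyme channel. One simulated study plus
analysis takes well under a second without permutations; a 10,000-
permutation Mantel pair adds a few seconds. The calibrated-regime sweep
uses 100 seeded full-design runs (~35 s), computing Mantel r only
(permutation p-values are irrelevant to the r ≥ 0.9 criterion). Property
suites check the digestion oracles on 1000 random sequences and exhaust
the 4! Mantel permutation group.

## Known limitations

- Pseudo-TRF areas are spread uniformly over a genotype's pseudo lengths;
  real under-digestion likely favours the fewest-missed-cuts products.
- The drift calibration pools both dye channels; per-dye fits are possible
  but under-determined with 21 pairs.
- The ANOVA + Tukey comparison of PC scores between templates, present in
  the original analysis, is deliberately omitted as routine.
- Margalef's index on fluorescence data inherits the arbitrariness of N;
  only its regression slope/R² across communities is meaningful, not its
  absolute value.
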