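# Methods

This note records the statistical model, the synthetic-data assumptions,
the numerical conventions and the genuinely open design choices behind
endokit. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential enrichment

**Input contract.** Analysis starts at protein-level reporter intensities
(linear scale, one column per TMT channel) plus a sample design table.
Peptide-to-protein rollup, isotopic-impurity correction and interference
modelling are upstream concerns and out of scope.

**Normalization.** Intensities are log2-transformed and each sample column
is median-centred. Median centring is scale-free, robust, and removes
constant per-channel loading offsets exactly. `QuantMatrix` carries a
`log_scale` flag so normalization is idempotent: already-normalized input
passes through unchanged rather than being log-transformed twice.

One consequence worth knowing: when a large fraction of the proteome is
truly enriched in the tagged channels (≈ 35% under the default synthetic
design), the tagged-sample medians absorb part of the signal, so background
proteins sit slightly below zero and enriched proteins slightly below the
planted effect. This is the familiar compositional bias of median polish,
visible in real volcano plots as a left-shifted background mode. The
planted-vs-background *contrast* remains unbiased, which is what the tests
assert.

**Test statistic.** Per protein, log2FC is the difference of group means in
log2 space. With `shrink=0` (the constructor default) significance comes
from the unequal-variance Welch t with Satterthwaite degrees of freedom —
the minimal assumption-free contract. At triplicate scale, however, the
Welch test has only ~4 residual df, which floors the attainable p value
(two-sided p ≈ 1e-3 even at t ≈ 8) so that essentially nothing survives
q ≤ 0.01 regardless of effect size. This is a property of the design, not
of any implementation. The `shrink` option therefore implements a
moderated t: the pooled within-protein variance is shrunk toward the
global mean variance with weight `w`,

    s²_post = (1 − w) s²_i + w · mean(s²),   df = d_i / (1 − w),

which is the empirical-Bayes posterior with a prior worth `d_i·w/(1−w)`
degrees of freedom (the limma idea with a fixed, user-chosen prior weight
instead of an estimated one). The pipeline default is `w = 0.9`
(prior worth 36 df at 3v3), appropriate when measurement noise is roughly
homoscedastic across proteins — true of the generator and approximately
true of TMT data. `w = 0` remains available for strict per-protein
inference. As `w → 0+` the statistic converges to the pooled-variance
Student t.

**Multiple testing and classification.** BH step-up across all proteins
actually tested in the contrast (≥ 2 observed replicates per arm; others
get null statistics and are excluded from the BH universe). A protein is
*enriched* when log2FC ≥ 1.0 and q ≤ 0.01 — directionality comes from the
fold-change gate, matching volcano-plot logic; p values are two-sided.
Missing values are never imputed.

## Term enrichment and abundance categories

Overrepresentation only (upper-tail hypergeometric, P[X ≥ k]); depletion is
not tested because the downstream question is which synaptic locations and
functions are *captured*. BH is applied within each term category
(location vs function separately), mirroring sub-ontology reporting.
The abundance pie classifies IP-selective proteins by whole-proteome
log2FC with a symmetric inclusive threshold of 1.0; the threshold is a
convention of this package (the source analyses do not state one) and is
configurable. Percentages are rounded to integers, so they can sum to
100 ± 1.

## Candidate cargo

The cargo filter is exact set arithmetic: TM count ≥ 1 AND cell-membrane
flag. Mapping external annotation exports (e.g. subcellular-location
strings) onto that boolean flag is configuration, not code, which keeps the
filter vocabulary-agnostic. TM count is kept as a count so reports can
split single- from multi-pass proteins. `cargo_fraction` rounds to integer
percent; an empty universe is an error rather than a 0.

## Motif scanning

* SNX27: hit iff residue −3 ∈ {S, T} and residue −1 ∈ Φ; −2 free. At most
  one hit per protein (anchored at the C-terminus). The context score
  counts {D, E, S, T} in positions −4..−8 — five residues immediately
  upstream of the core, covering the acidic/phospho positions that enhance
  PDZ binding. The score is reported, never used as a filter, because no
  principled cutoff exists.
* SNX17: every 6-residue window matching Φ-x-N-x-x-[F/Y]; overlapping hits
  all reported. When a TM-segment end is supplied, only the region
  C-terminal to it is scanned (cytosolic-tail assumption for type-I
  topology); topology itself is never inferred.
* Φ defaults to {A, V, L, I, M, F, W, Y} and is configurable — motif counts
  depend on this choice and no canonical enumeration exists. Nonstandard
  residues (X, U, B, Z) never match any position.
* Positions are reported 1-based from the N-terminus *and* as negative
  offsets from the C-terminus (−1 = last residue), since both conventions
  are common.

## Structure-screen triage and logos

Structure prediction is external; the package consumes its ipTM confidence
scores. Triage is strict (`iptm > 0.6`): a score exactly at the threshold
fails. Extreme selection sorts by ipTM descending with lexicographic
candidate-id tie-break, making top/bottom sets deterministic. PWMs use
add-0.1 smoothing per residue — enough to avoid log(0) in the information
content while perturbing n ≥ 10 logos negligibly — and weight all peptides
equally (no ipTM weighting; the alternative is defensible but less
transparent). SNX27 peptides are aligned at the C-terminus, SNX17 peptides
on the 6-residue core. Logo rendering is plain matplotlib text glyphs
scaled to per-position information content; the numerics (probabilities,
IC) are independent of any plotting library.

## Time-course clustering

Rows are z-scored with the sample (n−1) standard deviation — stated
explicitly so the worked example (1, 2, 3) → (−1, 0, 1) is unambiguous.
Constant rows cannot be z-scored and are dropped with a warning.
Clustering is k-means (best of 10 restarts, seeded, deterministic), with
clusters relabelled by descending size so ids are stable. k is a user
choice — no ground-truth k exists for real data — with an elbow diagnostic
(`TimecourseModel.elbow`) emitted to guide it; the synthetic default is
k = 3 matching the generator's templates.

## Synthetic-data generator

The generator emulates the statistical structure of a tagged-vs-untagged
organelle-IP study; its defaults are the study conditions used throughout
the tests:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 1000 | quantified proteome size |
| compartment fractions | 0.10 lyso / 0.10 endo / 0.15 PM | organelle residents (planted enriched set) |
| `enrichment_effect` | 2.0 log2 | planted tagged-vs-untagged effect |
| `noise_sd` | 0.3 log2 | per-measurement Gaussian noise |
| `n_replicates_per_group` | 3 | triplicate IPs per arm |
| `channel_offset_sd` | 0.2 log2 | per-channel loading offset (exercises normalization) |
| `baseline_log2_mean/sd` | 20 / 2 | protein abundance baseline |
| motif plant rates | 0.10 SNX27 / 0.25 SNX17 | ≈ 25 and 60 per 241 cargo |
| `seq_length_range` | 60–400 | uniform residue background |
| `iptm_high/low_params` | Beta(10, 3) / Beta(2.5, 8) | planted vs control ipTM modes |
| `timecourse_noise_sd` | 0.2 z units | trajectory noise (templates ≥ 3σ apart) |

Design choices: the residue background is uniform over the 20 standard
amino acids so motif statistics stay analytic (per-window SNX17 probability
= 0.4 · 0.05 · 0.1 = 0.002); intensities are emitted on the linear scale
(2^x) so consumers exercise the log transform; channel offsets are drawn
once per sample; an optional below-quantile masking mechanism produces
missing values (default off). Non-planted sequences are rejection-sampled
so their C-terminal triplet never matches the SNX27 pattern; incidental
internal SNX17 matches are permitted and recorded in the ground truth, or
suppressed entirely with `suppress_background_snx17` when exact
planted-count recovery is wanted. All randomness derives from one seed via
named substreams (CRC32 of the stream name spawns the child), so the full
bundle is byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: peptide-level quantification and rollup,
isotopic impurity and reporter-ion interference, intensity-dependent
(MNAR-beyond-threshold) missingness, protein-specific variance structure,
correlated co-complex abundances, compositional constraints of real TMT
plexes beyond a per-channel offset, and annotation errors. Results on real
exports depend additionally on the upstream search/quant engine, which this
package deliberately does not model.

## Numerical conventions and degenerate inputs

* BH is order-preserving and permutation-invariant (sort, step-up, restore).
* Hypergeometric p values are clamped to (0, 1]; a term equal to the
  universe necessarily gives p = 1.
* Welch/moderated statistics for proteins with < 2 observed replicates per
  arm are NaN and excluded from BH; all-missing sample columns are an error
  naming the sample.
* Empty enrichment tables, empty cargo sets and empty hit sets are valid
  inputs yielding empty (not error) outputs, except where a nonempty input
  is semantically required (empty PM universe, empty FASTA).
* Ties: extreme selection breaks ipTM ties by candidate id; cluster
  relabelling breaks size ties by original k-means label; both are
  deterministic.
* Problem sizes in the test and acceptance runs (1,000-protein matrices,
  20 replicate simulations, 241-protein motif studies, 300-protein
  time-courses) were chosen as the smallest sizes at which the binomial /
  sampling-distribution tolerances in the tests are sharp.

## Known limitations

* The moderated t assumes near-homoscedastic noise across proteins; with
  strongly protein-specific variance, `shrink` should be reduced.
* Exact reproduction of q values from the original MSstats-based analyses
  is not claimed (model and options differ); the package reproduces the
  decision rule and its operating characteristics, not historical tables.
* The SNX17 "related motifs" family beyond Φ-x-N-x-x-[F/Y] is not scanned.
* Motif counts depend on the configurable Φ set; there is no single
  canonical choice.
* k-means recovers convex, similarly-sized trajectory clusters; strongly
  imbalanced or non-spherical cluster structure in real differentiation
  data may require a different clusterer.
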