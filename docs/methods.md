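# Methods

## Model and procedure

`bqrecal` treats base-quality recalibration as a supervised learning
problem. On a training region the truth proxy for "this base is a
sequencing error" is disagreement with the reference; the model is a plain
(unregularized) logistic regression of that label on per-base covariates:
reported quality X₁, a separate indicator X₂ for quality-zero calls (many
base callers use Q0 to mark bad or randomly called bases, so their numeric
quality carries no information), the containing read's mean quality X₃
(flags reads that are bad throughout), the read position X₄, indicators
for the called base being A, C or G (T is the reference category), and one
indicator per flagged read position. Flagging is data-driven: a cycle is
flagged when its error count exceeds `multiplier × (total errors / read
length)`, default multiplier 1.5. This gives the strongly non-linear
error-vs-cycle profile at read ends its own degrees of freedom while the
linear X₄ term absorbs the gentle trend elsewhere.

Mismatch labels are contaminated by true variants and systematic alignment
artifacts. Two wholesale position-level removals protect the labels before
fitting: known-variant positions (from a TSV/VCF of chrom+pos), and any
position whose mismatch count strictly exceeds
`thresh = max(nerr, nraf × coverage)` (defaults nerr = 2, nraf = 0.05).
Removal means dropping *all* bases at the position — keeping the
reference-matching bases while relabeling the rest would bias the error
rate downward at exactly the positions we distrust.

Fitting uses maximum likelihood via iteratively reweighted least squares
(statsmodels GLM/Binomial; at most 25 iterations, tolerance 1e-8).
Training sets beyond `subset_size` rows (default 10 million, a memory
guard) are split into contiguous slices in input (coordinate) order — not
resampled, for reproducibility — fitted independently, and combined by the
element-wise median across subsets, which also damps any single aberrant
subset fit. Prediction applies the inverse logit to the linear predictor
and maps to an integer score by `floor(-10 * log10(p))`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `nerr` | 2 | max called errors tolerated at a position (count scale, guards low coverage) |
| `nraf` | 0.05 | max non-reference allele frequency tolerated (rate scale, guards high coverage) |
| `flag_multiplier` | 1.5 | per-cycle error count, as a multiple of the mean, above which a cycle is flagged |
| `subset_size` | 10,000,000 bases | max rows per logistic fit |
| `q_max` | 60 | cap on output scores (p ≈ 10⁻⁶); avoids absurd scores from extreme linear predictors |
| `max_train` | unset | cap on bases collected from the region, counted before any filtering |

Note on the defaults: `max(2, 0.05 × coverage)` switches from the count
criterion to the frequency criterion at 40× coverage (0.05 × 40 = 2); at
or above that coverage the tolerated error count grows with depth.

## Design choices

* **Coordinates.** User-facing regions are 1-based inclusive (samtools
  convention); internal arithmetic is 0-based half-open.
* **Read position** is the 1-based offset within the read as stored in the
  BAM record, i.e. aligned (reference) orientation — not the sequencing
  cycle for reverse-strand reads. The simulator emits forward-strand reads
  only, so the distinction is untested here; users aligning real
  paired/reverse data should be aware flagged positions mix orientations.
* **Training vs output scope.** Unmapped, secondary and duplicate reads
  are excluded from training (labels need trustworthy alignments) but every
  record is rewritten on output: prediction needs only read-level
  covariates, no reference, so the output BAM is complete.
* **Coverage for `thresh`** is counted over training-eligible bases (after
  N-dropping and known-variant exclusion), not raw pileup depth — the
  filter protects the labels, which only those bases carry. The comparison
  `n_nonref > thresh` is strict and unrounded, so a position sitting
  exactly at the threshold is kept.
* **Quality-zero bases** stay in the training set; X₂ separates them
  instead of dropping them, and they are recalibrated like any other base.
* **Degenerate subsets.** A subset with a single response class, a failed
  or non-converged fit, is skipped with a warning; a covariate column that
  is constant within a subset is dropped there and treated as absent (NaN)
  when medians are taken. A covariate constant in *every* subset gets
  coefficient 0.
* **Zero-error quality bins** have undefined empirical quality
  (−10·log₁₀ 0); they are capped at `q_max`, marked in the table, and kept
  in FWSE and plots — dropping them would hide overly pessimistic score
  bins. Empirical qualities are never rounded inside FWSE; rounding is for
  display only.
* **AUC** uses the tie-corrected rank-sum (Mann–Whitney) estimator:
  the probability that a random variant base outscores a random error
  base, ties counted ½. The discrimination filters mirror the training
  filter: error-class positions must satisfy
  `n_nonref ≤ max(nerr, nraf × coverage)`; variant-class positions must
  reach `n_nonref ≥ max(3, nraf × coverage)` so that weakly supported
  "variants" (which may themselves be errors) drop out.
* **X₃ at prediction time** uses original (not recalibrated) qualities,
  matching what the model was trained on.

## The simulator

`simdata` generates what the method needs to be tested against: uniform
random references; fixed-length (default 76 bp) single-end ungapped reads
at uniform positions; reported qualities drawn from a distribution
concentrated near Q40 with a low-quality tail (including Q0); true error
probability equal to `distortion_factor` (default 10) times the
reported-quality-implied probability, further multiplied by a per-cycle
profile elevated at read ends (up to 4× over the last 15 cycles, mildly at
the first 3); planted variant sites carried at a given allele frequency;
and systematic sites where every overlapping read is non-reference,
mimicking mapping artifacts. A per-base truth table (error flag, variant
flag) accompanies every BAM so calibration can be judged against actual
simulated errors rather than reference mismatches.

What it does **not** emulate: indels and clipping (reads are pure matches;
the extraction code paths for clips/indels are exercised by hand-built
records in the tests instead), reverse-strand reads, paired ends,
GC-dependent or dinucleotide error structure, and realistic
Illumina quality-string autocorrelation. Passing tests therefore show the
algorithm is implemented correctly and behaves as designed when its model
family contains the truth; they do not show how far real data depart from
that family.

## Problem sizes and numerical notes

The bundled study (`scripts/acceptance.py`) uses 100,000 76-bp reads over
a 200 kb reference (~38× coverage), training on the first 100 kb
(~2.8 million labeled bases, one subset) and evaluating on the held-out
half — large enough for stable coefficients and tight empirical-quality
bins, small enough to run in about a minute. The test suite uses 2,000-
to 50,000-read fixtures with fixed seeds. Logistic fits are
well-conditioned at these sizes; the only routine numerical guards are the
clipping of inverse-logit output away from exact 0/1 before the log
transform and the `q_max` cap.

## Known limitations

* Recalibration quality is bounded by alignment quality; mapping errors
  that are not position-systematic (and thus survive the `thresh` filter)
  contaminate the labels.
* One model per BAM: no per-read-group or per-lane stratification.
* Covariate set is deliberately small; dinucleotide/cycle-context effects
  present in real data are absorbed only insofar as they correlate with
  the included covariates.
* The reported-vs-empirical diagnostic on the training region is mildly
  optimistic; use `bqrecal evaluate` on a held-out region for an honest
  estimate (the bundled study shows train/test FWSE agree closely).
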