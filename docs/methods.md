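# Methods

## Model of the data

A targeted-capture ccfDNA library is modelled as a set of unique input
molecules ("fragments"), each ligated to a single 8-mer UMI and
amplified into a PCR family. Aligned reads are grouped into families by
*exact* equality of (chromosome, unclipped start, UMI, orientation) —
no fuzzy UMI clustering, matching the single-index/single-UMI adapter
design the pipeline targets. Three error processes are distinguished,
because the cascade treats them differently:

* **per-copy error** (sequencing and late-cycle PCR): independent
  across reads; removed by consensus collapsing;
* **early PCR error**: struck in the first amplification cycle, so all
  copies of one molecule agree on the wrong base; survives consensus
  but is private to one library and is removed by the shared-variant
  requirement across technical replicates;
* **systematic, position-specific error**: reproducible across samples;
  estimated from a panel of normals and removed by the Z-score
  threshold.

True variants enter at the molecule level: every PCR copy of a mutant
molecule carries the variant, which is why consensus collapsing
preserves signal while erasing per-copy noise.

## The cascade and its parameters

| parameter | default | units | role |
|---|---|---|---|
| concordance | 0.66 | fraction | consensus column passes only if the predominant base exceeds this fraction of covering reads (2/3 passes, 66/100 does not; integer comparison keeps the boundary exact) |
| min family size | 2 | copies | consensus reads from singleton families are discarded |
| Fisher side | greater | — | candidate calling is directional (case enriched); the default p ceiling of 1.0 passes everything, so the test annotates rather than filters |
| CHIP fold | 5 | × | variant seen in the WBC normal is kept only if case VAF ≥ 5× normal VAF (inclusive boundary; strict `>` available) |
| z_min | 2.576 | SD | two-sided 99% standard-normal critical value |
| z_cap | 100 | SD | reporting ceiling for Z-scores |
| min NRA per replicate | 4 | molecules | the ">3 nonreference alleles in each replicate" rule of the unbiased mode |
| tumor catalog min VAF | 0.01 | fraction | combined-replicate VAF floor for tumor mutations |
| absent threshold | 3 | molecules | tumor-informed mode: combined NRA ≤ 3 scored absent |

Consensus quality is the maximum supporting-read quality, not a
Bayesian combination — the collapsed quality is never used downstream,
so a calibrated posterior would add complexity without effect.

### Z-score details

For each (position, alt) the panel of normals contributes one VAF per
covered sample (zeros included); the model stores the mean and the
sample (n−1) SD. Scoring distinguishes three regimes:

* panel mean = SD = 0 (the panel never errs there): any positive case
  VAF scores at the cap. A nonreference allele at an error-free
  position is maximally surprising; the cohort's variant table shows
  the cap being reached at VAFs as low as 0.16%, which a finite floor
  could not reproduce.
* SD = 0 but mean > 0 (constant nonzero panel error, or a single-sample
  panel): the SD is floored at 1/(median panel depth) — the VAF quantum
  of one allele — to avoid dividing by zero.
* otherwise: ordinary (VAF − μ)/σ, capped.

Positions left uncovered by part of the panel are excluded from that
position's statistics and flagged; a position absent from the model
entirely scores at the cap (it is indistinguishable from error-free).

The geometric-mean shared Z is defined as 0 when either replicate Z is
≤ 0; such variants cannot pass the upstream threshold anyway, so this
choice only avoids imaginary values.

### Coordinates, ties, degenerate inputs

All internal coordinates are 0-based half-open; conversion to 1-based
happens only at the VCF/annotation boundary, property-tested as
lossless. A consensus-column tie cannot exceed 2/3 concordance, so ties
need no break rule — they yield N. Overlapping mate consensus reads of
one molecule (same UMI, opposite orientation) are counted once in the
pileup: agreement keeps one copy, disagreement blanks both. Zero-depth
positions raise on VAF computation rather than returning a sentinel.
VAF percentages are rounded half-even to two decimals, matching the
tabulated style of clinical reports.

Survival conventions: the KM median is the smallest event time with
S(t) ≤ 0.5 (undefined if never reached); tied events precede
censorings; the log-rank statistic carries no continuity correction.
Estimation and testing delegate to lifelines; the test suite checks
them against independent brute-force per-event-time oracles. Fisher's
exact test delegates to scipy and is checked against exact rational
hypergeometric enumeration.

## The synthetic-data generator

`simdata` emulates: molecule-level spikes at specified VAFs, truncated-
Poisson(3) family sizes, uniform 0.5% per-copy error (a realistic raw
Illumina substitution rate), optional fragment-level early-PCR error,
and systematic error sites shared across samples. Fragment length is
fixed (150 bp; size-selection biology is out of scope) and fragments
are placed uniformly within the target, so a 150 bp target gives
uniform depth — convenient for depth-conditioned experiments. Panels of
normals are consensus-collapsed with the same settings as cases before
fitting, as a real panel must be.

What it does **not** emulate: GC and capture bias, strand asymmetry,
FFPE deamination, fragmentomics, indels/MNVs (the pipeline is SNV-only)
and UMI sequencing errors. Passing simulation tests therefore
demonstrates the cascade's statistical behaviour under its own model
assumptions — suppression of independent and early-PCR noise, recovery
of molecule-level signal — not robustness to every artifact class of
real libraries. One realistic blemish is retained: with all fragments
at one start, 8-mer UMI birthday collisions occasionally merge two
molecules into one family.

## Problem sizes used by the test suite

Deterministic checks run at desk scale. Stochastic properties use:
100 error-only control replicate pairs at ~3,750× consensus depth per
replicate (~7,500× combined) for specificity (zero calls expected
through the full cascade); 100 seeds each at VAF 0.3%/~10,000× (detected,
binomial oracle P > 0.999) and VAF 0.02%/~5,000× (not detected, oracle
P < 0.02) for sensitivity; 100 seeds at VAF 1%/~2,500× for end-to-end
VAF unbiasedness (3σ binomial tolerance); panels of 5–7 samples for
systematic-rate recovery. These sizes make the full suite run in
minutes while keeping every bound derived from the binomial oracle
rather than tuned.

## Known limitations

* The annotation fixture is a synthetic COSMIC-like table with
  representative coordinates, sufficient for adjudication logic but not
  a database export.
* The packaged cohort carries unbiased-mode detection flags only;
  tumor-informed stratification requires user-supplied flags.
* The background model is per-position/alt mean-and-SD only — no
  trinucleotide-context priors, no strand-specific modelling.
* Replicate integration assumes exactly two technical replicates, as
  the assay prescribes.
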