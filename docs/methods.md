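# Methods

## The analysis model

`promtile` analyzes two-color promoter tiling arrays. The measured quantity
per probe is a pair of channel intensities — Cy5 for immunoprecipitated
chromatin, Cy3 for input genomic DNA — summarized as
M = log2(Cy5/Cy3) and A = ½(log2 Cy5 + log2 Cy3). The method assumes:

* probes are gene-scoped: each probe belongs to exactly one gene's design
  window, and enrichment runs never cross gene boundaries;
* most probes are unenriched, so array-wide location/scale statistics of
  the smoothed signal estimate the null distribution;
* dye bias is a smooth function of intensity (removable by loess on A);
* replicate arrays of one treatment measure the same probe set up to
  quality flags.

### Probe design

Each gene's TSS anchors a window of 5500 bp upstream and 2500 bp downstream
(strand-aware, clipped at chromosome edges with a warning). Probes of 60 nt
are tiled at a nominal 205 bp start-to-start spacing. The arithmetic does
not close exactly — 40 starts at 205 bp span 7995 bp, and a 60-mer starting
there would overrun the 8000 bp window — so the final probe is left-shifted
to end flush with the window edge. This preserves both the probe count (40
per full window) and the ~205 bp average spacing (203.6 bp realized).
Tiling is anchored at the window's 5′ end in gene orientation, so a − strand
design is the exact mirror of a + strand one; probe sequences are always
read from the + genomic strand (the array hybridizes both). A design-wide
filter drops probes whose 60-mer occurs more than once anywhere in the
design space (both copies) or whose composition exceeds 70% of a single
base. This filter is a plausible, transparent stand-in for whatever
reduction the original array vendor applied; nothing downstream depends on
its details.

### Normalization

Order of operations: flag filtering → background subtraction →
MA conversion → within-array loess → between-array A matching → replicate
averaging.

* **Background floor** — corrected intensity is max(fg − bg, 1.0). Local
  background estimates are noisy, so over-subtraction happens; flooring at
  1.0 keeps logs finite and is conservative (a floored probe has M = 0
  contribution only if both channels floor).
* **Loess span** — default 0.3, configurable. The asserted property is the
  outcome (per-A-decile mean of corrected M below 0.05 on data with an
  injected trend), not the span itself. Arrays under 50 probes skip the fit
  with a warning. Loess is not exactly idempotent — a second pass fits the
  residual wiggle of the first, of order noise/√(window count), observed
  ~5·10⁻⁵ median on test data — so the idempotency test uses a 10⁻³
  tolerance, far below the noise scale.
* **Between-array step** — quantile matching applied to A only, leaving M
  bitwise unchanged: each array's sorted A vector is replaced by the
  across-array mean of sorted vectors, assigned back by rank, ties
  receiving the mean of the tied reference positions (deterministic and
  order-invariant). Full two-channel quantile normalization is deliberately
  not offered: it would alter M. Because flag filtering can differ between
  slides, the pipeline applies this step to the probes common to all
  replicates; probes surviving on only some replicates keep their
  loess-normalized values and are averaged over the replicates that retain
  them, with a log note.

### Enrichment calling

The replicate-averaged M track of each gene is smoothed with a centered
1400 bp window: a probe's smoothed value is the mean over all probes of the
same gene whose centers lie within ±700 bp (inclusive). At 205 bp spacing
this pools ~7 probes. The threshold is computed array-wide over all
smoothed values as center + 2.5·SD. The center statistic defaults to the
median because the enriched tail inflates the mean; the SD is the plain
array-wide standard deviation, which is itself slightly inflated by true
peaks — making the threshold conservative in rich arrays and exact under
the null. Scope is the whole probe set, not per gene: a per-gene SD on ~40
probes would be unstable and saturated by any real peak.

A region is a maximal run of probes with smoothed signal strictly above
the threshold, adjacent in the gene's tiling order, of length ≥ 3.
Two runs separated by a single sub-threshold probe are *not* merged by
default (strict maximal-run semantics); `merge_gap` > 0 enables bridging.
A gene is bound iff it has ≥ 1 region; its highest-peak region represents
it in reports. Gene-level calls are monotone in both the threshold and the
minimum run length (property-tested); region *counts* are not, since a
higher threshold can split a region.

### Set comparison

Plain set arithmetic; the union of the two conditions' bound genes is the
candidate target list. Expression cross-referencing categorizes each
candidate as absent from the expression platform, present-but-unregulated,
or regulated in the epithelium, the non-epithelium, or both; percentages
are rounded to integers with explicit denominators (presence over all
candidates, regulation over the platform-present subset). Name matching
across platforms is a separate, explicit step (case-insensitive with an
optional alias map) so nomenclature losses stay visible.

### Response-element scanning

The scanner is a transparent consensus/PWM matcher, not a hidden-Markov
model: every (offset, spacer) pair is scored as two hexamer half-sites
against AGGTCA (Hamming distance; N always mismatches), in DR, IR or ER
arrangement, on both strands (the minus strand is scanned on the reverse
complement and mapped back; coordinates are always plus-strand, hit span
12 + spacer). Defaults — DR4, ≤ 3 mismatches per half-site, ≤ 4 total —
are set to accept the five experimentally validated DR4 TREs the package
ships as test fixtures while rejecting most random sequence. A log-odds
mode over a 4×6 weight matrix is available. Hidden-Markov scanners used in
the original studies score differently; genome-wide hit *counts* from this
scanner are therefore workflow analogues, not reproductions.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the experiment: one 8 kb
window per gene laid out on synthetic chromosomes, uniform-random base
composition, a fraction of genes bound in the treated condition
(default 10%) with a nested subfraction (default 3%) already bound in the
control — hormone treatment both recruits new sites and strengthens
existing ones, so control-bound genes are by default a subset of
treated-bound — duplicate arrays per condition, and an optional DR4 element
written into the genome at each peak center.

Signal model per probe: a shared lognormal baseline (log-mean 7.0, log-sd
0.8, i.e. median ≈ 1100 intensity units); Cy3 = baseline + additive
background (normal, mean 100, sd 20, clipped at 0); Cy5 = baseline ×
enrichment fold × dye-bias factor × multiplicative noise + its own
background. Reported background columns are independent draws from the
background distribution, so downstream subtraction is imperfect by
construction. Enrichment is a boxcar: fold 8 (treated) or 4 (control)
within ±700 bp of the gene's peak center, 1 outside — the 700 bp halfwidth
matches the scale of the 1400 bp smoothing window. Dye bias is a logistic
ramp on the log2 intensity (amplitude 0.8, centered at log2 intensity 10,
width 1.5), giving the classic banana-shaped MA plot that loess must
remove. Multiplicative noise is 2^N(0, 0.25), i.e. sd 0.25 on the M scale.
2% of probes are flagged low-quality. All parameters are free knobs of the
generator, not platform estimates: the raw-intensity noise model of real
scanners is not publicly characterized for this design.

Not emulated: sequence-dependent probe affinity, spatial slide artifacts,
cross-hybridization, and annotation error in TSS placement. Passing tests
therefore demonstrate that the pipeline recovers localized enrichment under
realistic noise, dye bias and background — not that it is robust to probe
behavior or annotation problems real arrays can show.

### Calibration figures computed by the test suite

* **Spike-in recovery** (200 genes, 20 treated-bound at fold 8, duplicate
  arrays, default pipeline, 20 seeds): mean gene-level sensitivity ≥ 0.9
  and false-discovery proportion ≤ 0.1; observed in this configuration the
  pipeline recovers essentially all spiked genes with near-zero false
  calls.
* **Null calibration** (enrichment fold 1 everywhere, 50 genes, 20 seeds):
  the 2.5·SD / 3-consecutive-probes criterion on smoothed, positively
  correlated noise has a small nonzero per-gene false-call rate; the suite
  budgets 5% on average, the expected scale for a 2.5-SD criterion after
  ~7-probe smoothing.

The test problem sizes (200 genes, 20 seeds) are the package's scaled-down
stand-in for a 17,000-gene array: per-gene geometry, probe counts and the
calling criterion are identical, only the number of genes differs, so
gene-level operating characteristics transfer up to the precision of the
array-wide SD estimate.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere in memory; BED on disk.
* Thresholding uses strict `>`; a zero-variance smoothed track warns and
  uses the center alone.
* Tiling of a window shorter than one probe returns an empty design with a
  warning; a window entirely off-chromosome is an error naming the gene.
* All randomness flows through explicit integer seeds via numpy
  `default_rng`; identical configuration and seeds give byte-identical
  outputs, and the pipeline's provenance report includes SHA-256 checksums
  of every output file.
* The orchestrator validates every parameter against its documented range
  before any stage runs and names the field and range in each violation.

## Known limitations

* The enrichment threshold has no formal false-discovery control
  (no permutation or model-based FDR); the 2.5·SD criterion is a fixed
  operating point.
* The uniqueness filter is a stand-in; real array designs also drop probes
  for synthesis and thermodynamic reasons this package does not model.
* The element scanner's hit counts are threshold-dependent and not
  comparable to HMM-based scanners beyond the fixtures it is calibrated on.
* Between-array normalization assumes the A distributions *should* match;
  treatments that change global ChIP efficiency violate this silently.
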