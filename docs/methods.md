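# Methods

## The measurement model

A 2-plex isobaric-label experiment compares two conditions (KO and WT) in
one MS run: each identified peptide carries two reporter-ion intensities,
and their ratio estimates the relative abundance of the parent protein in
the two samples. The package models each experiment as an independent
replicate of the whole preparation (animals pooled per genotype, labeled,
mixed and measured together), so the unit of replication for inference is
the experiment, not the animal or the peptide.

Peptide ratios are treated as multiplicative measurements: for protein *i*
in experiment *e*, peptide *j*,

    ln r_ije = ln ρ_i + b_ie + ε_ije,
    b_ie ~ N(0, σ_e²),   ε_ije ~ N(0, σ_p²)

where ρ_i is the true KO/WT fold change, b_ie the between-experiment
(biological + preparation) deviation and ε_ije peptide-level technical
noise. This two-tier structure is what makes a t-test across N = 3
experiments meaningful: without a between-experiment variance component,
per-experiment ratios would be nearly noise-free for well-covered proteins
and the test would have no null distribution to work against.

## Estimators and the differential call

* **Peptide → protein (within experiment):** geometric mean of the valid
  peptide ratios; spread as geometric SD (sample SD of log ratios,
  exponentiated; n−1 denominator). Geometric statistics are the natural
  choice under the multiplicative model; an arithmetic rollup is exposed
  for sensitivity analysis. Ratios are undefined (not zero, not dropped
  silently) when a reporter peak is missing or non-positive; proteins with
  a single valid peptide keep their ratio with an undefined spread.
* **Across experiments:** arithmetic mean and sample SD of the
  per-experiment ratios, restricted to proteins quantified in all
  experiments (configurable via `min_experiments`).
* **Differential test:** two-sample pooled-variance Student t-test of each
  protein's (mean, SD, n) against an internal reference protein whose
  ratio is ~1 in every experiment, df = n + n_ref − 2 (= 4 at n = 3),
  two-tailed, significance at raw p < 0.05, direction from mean ratio vs 1.
  The reference may be named in the configuration or chosen automatically
  (closest mean to 1; ties by smaller SD, then alphabetically). The
  summary-statistic and raw-ratio-vector entry points are algebraically
  identical (tested to 1e-12).

Two deliberate conventions follow the analysis this package reimplements
rather than current best practice, and both alternatives are available
behind flags:

* the test runs on **raw ratios** with **pooled variance**, which is what
  reproduces the published per-protein p-values from their printed summary
  statistics; the log-scale variant (`on_log_scale=True`) is statistically
  preferable — it respects the multiplicative error model and is exactly
  invariant under swapping the KO/WT labels — and Welch's unequal-variance
  form is available via `welch=True`;
* the significance call uses **uncorrected p-values** across the ~85
  protein tests. A Benjamini–Hochberg column is always emitted so users
  can see the FDR-controlled picture (in the bundled dataset no protein
  survives BH at 0.05); the raw-p call labels candidates for orthogonal
  validation, not controlled discoveries.

Identification is summarized per experiment by the decoy-estimated FDR of
above-threshold matches, 100·D/T. This form (rather than 2D/(T+D), also
available) is the one consistent with the published per-experiment values
under small integer decoy counts. The confidence cut is strict (>95%), and
boundary values are excluded on purpose.

## Over-representation and overlap

The ORA statistic is the one-sided hypergeometric upper tail (equivalent to
one-sided Fisher exact), the standard behind DAVID-style tools; the
EASE-penalized variant (k−1 successes) is available but off by default.
Fold enrichment is (k/n)/(K/N). Bonferroni and BH corrections are applied
within each GO namespace separately, mirroring per-category annotation
tables. Reproducing any external server's exact enrichment p-values is out
of scope because they depend on that server's background annotation counts;
the package validates the arithmetic identities (percent, fold enrichment,
correction formulas) and checks the hypergeometric tail against exhaustive
enumeration on small populations instead.

Gene symbols are normalized to the mouse convention (first letter upper
case) before any set operation, because published tables mix UniProt entry
names and gene symbols. Target-list overlaps are exact-symbol
intersections; known paralog/symbol discrepancies in printed lists (the
bundled FMRP-target list contains Sept4 where the proteome table has Sept7,
so the exact intersection is 40, printed as ~31% of 133) are surfaced in
logs rather than silently corrected.

## The synthetic-data generator

`raftdiff.simulate` draws datasets directly from the measurement model
above, plus the artifacts the pipeline must tolerate: independently missing
reporter peaks, sub-threshold-confidence PSMs, reversed-sequence decoy
records and keratin-like contaminants. Defaults (chosen once, as plausible
values for a small brain-membrane iTRAQ series): 3 experiments, 2–8
peptides per protein, σ_p = 0.2 and σ_e = 0.1 (natural-log scale; these
put cross-experiment SDs in the observed ~0.02–0.6 range), lognormal base
intensities (ln-mean 9, ln-SD 1, arbitrary units), 5% missing-peak
probability per channel, 10% sub-threshold PSMs, 5% decoy and 2%
contaminant records. Channel pairs alternate 113/114 and 117/118 across
experiments with the KO sample on the higher tag; the design table makes
the assignment explicit and swappable, since a real series' assignment is
a free choice.

What the generator does **not** emulate: reporter isotope-impurity
cross-talk (ratio compression), intensity-dependent missingness,
peptide-detectability and shared-peptide effects, or correlation between
animals pooled within an experiment. Passing calibration tests on this
generator therefore shows the statistical machinery is correct under its
stated assumptions, not that real iTRAQ data meet those assumptions —
in particular, real ratio compression biases fold changes toward 1.

`make_null_battery` produces independent all-null datasets (seeds s,
s+1, ...) for type-I-error estimation. Because every protein in a battery
shares one 3-replicate reference, rejection events within a battery are
correlated; calibration runs therefore use many small batteries (the test
suite uses 400 batteries of 20 proteins, ≈7,500 tests) rather than one
large one. Under the defaults the measured type-I error of the full
simulate → filter → quantify → test pipeline is near the nominal 0.05
(slightly inflated by heteroskedastic peptide counts across experiments);
the test asserts the 0.03–0.07 band.

## Numerical conventions and degenerate inputs

* MISSING is NaN internally and `NA` (or empty) in TSV; it is never
  conflated with 0. Record counts always reconcile: input = passing +
  confidence-rejected + decoys + contaminants.
* Zero pooled variance: p = 1 when the means are equal, p = 0 otherwise.
  Proteins with fewer than two replicate ratios cannot be tested and are
  excluded from the model fit (and from `min_experiments`-filtered
  combination); a single-replicate test request raises an
  insufficient-replication error.
* The automatic reference tie-break is deterministic (|mean−1|, then SD,
  then symbol) so runs are reproducible; all simulation randomness flows
  from one integer seed through spawned substreams.
* Published-table reproduction uses a ±0.003 absolute tolerance on
  p-values, the input-rounding limit of 2-digit means and 3-digit SDs.
  This reproduces the published significant/non-significant partition
  exactly (7 vs 78) and every p-value near the significance boundary;
  p-values far from the boundary (p ≳ 0.25) can deviate by a few
  hundredths under the same input rounding, which is why the validation
  harness checks the boundary rows and the partition rather than all 85
  p-values at the rounding tolerance.

## Known limitations

* No isotope-impurity correction or channel normalization (none is part of
  the reimplemented analysis).
* Protein inference is taken from the PSM's assigned accession; shared
  peptides are not reassigned.
* The reference-anchored test conditions on the chosen reference; a poor
  reference (unstable protein) biases every call. The automatic selector
  minimizes |mean − 1| but cannot detect a reference that is itself
  differentially abundant.
* Enrichment results depend entirely on the supplied GMT and universe; the
  package ships no annotation database.
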