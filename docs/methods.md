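# Methods

## Demultiplexing model

A multiplexed experiment yields one fragments file per Tn5 sample barcode.
For cell barcode *c* and sample *s*, *N_cs* is the number of fragment
records for *c* in *s*'s file (optionally the sum of the read-support
column; the default counts records, since the statistic is defined on
fragments). The fragment ratio is

    r_c = max_s N_cs / sum_s N_cs

and *c* is assigned to `argmax_s N_cs` when `r_c > threshold` (strict
inequality; `r_c` exactly at the threshold is ambiguous). The default
threshold is 0.6. Barcodes with `sum_s N_cs < min_fragments` (default 100)
are classed `low_count` before the threshold is consulted: sub-threshold
depth carries too little evidence either way and would otherwise inflate the
assigned fraction with noise barcodes. Ties at the argmax resolve to the
lexicographically smallest sample id; a tied barcode has `r <= 0.5`, so at
any threshold above 0.5 the tie rule affects reporting only, never
assignment.

The baseline is the incidence model: retain barcodes with `N_cs > 0` in
exactly one sample. Every multiplicity-1 barcode has `r = 1`, so with
`min_fragments = 0` the FR-assigned set is a superset of the
incidence-unique set (asserted as a property test).

**Why it works.** If a singlet's fragments each hop independently with
probability *h* to a uniformly chosen other sample, the true sample's count
is Binomial(n, 1−h), so `r` concentrates at 1−h with sd ~ sqrt(h(1−h)/n).
At h = 0.2 and n ≈ 2000, P(r ≤ 0.6) is a far binomial tail (~10⁻⁹⁰ scale);
assignment errors come only from very shallow cells. A cross-sample doublet
mixes two samples with proportion p ∈ [0.3, 0.7]; its top-sample ratio after
hopping is ≈ max(p, 1−p)(1−h) + small hop-back terms, which at h = 0.2 stays
below 0.6 for the whole mixing range — doublets are rejected by the same
threshold that accepts singlets. With only two samples at h = 0.5 both
samples expect half the fragments, `r → 0.5 < 0.6`, and the assigned
fraction collapses as depth grows: the method's phase boundary, exercised in
the tests.

**Splitting.** After assignment, only the fragments an assigned barcode has
in its assigned sample's own input are emitted to that sample's output; the
same barcode's fragments in other files are hopping artifacts and go to a
discard stream (a `merge_hopped` mode merges them into the assigned sample
instead, for users who prefer depth over purity). Ambiguous and low-count
barcodes are discarded entirely. The split is exactly conservative: every
input fragment appears in exactly one output.

## Synthetic data generator

`atacmux.simulate` emulates the structure of the multiplexed experiment so
the pipeline is testable end to end without external data. One seeded numpy
Generator drives all draws in a fixed, documented order; same-seed runs are
byte-identical on one implementation (cross-implementation bit-identity is
not promised, only distributional equivalence). Defaults are the package's
study conditions and are chosen once:

| parameter | default | why |
| --- | --- | --- |
| n_samples | 10 | ten-plex pooling, the design the method targets |
| cells_per_sample | 500 | ~5000 GEMs, a typical Chromium ATAC load |
| mean_fragments, dispersion | 2000, 2 | negative-binomial depth; overdispersion (shape 2) gives the long lower tail that stresses the low-count filter |
| hop_rate | 0.2 | per-fragment probability of a wrong sample barcode; no empirical per-fragment estimate exists for the real ten-plex data, so this is a working value, not a claim |
| doublet_rate | 0.05 | typical droplet co-encapsulation at this load; doublets are cross-sample only (same-sample doublets are invisible to demultiplexing) with mixing proportion U[0.3, 0.7] |
| genome_length, n_peaks, peak_width | 20 Mb, 2000, 400 bp | peaks cover 4% of the genome, so off-peak fragments rarely graze peaks and FRIP stays close to its target |
| frip_target | 0.35 | in-peak fragment probability, matching good-quality cryopreserved libraries |
| peak weights | Gamma(1) per peak, shared | heterogeneous peak accessibility; without it all peaks are statistically identical and cross-sample per-peak signal fractions cannot correlate |
| length mixture | 0.6·N(75, 25) + 0.4·N(200, 35), ≥ 20 bp | sub-nucleosomal + mono-nucleosomal modes of the ATAC fragment ladder |
| mito_fraction | 0.05 | modest mitochondrial contamination on a 16,571 bp chrM contig |

Fragment counts are floored at 1 so every simulated barcode is observable —
a zero-fragment cell exists in no fragments file and is meaningless to
demultiplexing; the floor keeps the truth table and the count matrix over
the same barcode universe.

Hopping is modeled per fragment with a uniform wrong-sample destination.
The real mechanism (free Tn5 inserts priming in GEMs) is known only
qualitatively; uniform misassignment is the maximum-entropy choice and
reproduces the qualitative multiplicity profile (nearly all barcodes seen in
many samples at realistic depth). Doublet fragments hop *from their emitting
component's* sample. The truth table tallies, per cell, total fragments and
fragments whose file label differs from their emitting sample; the tally is
exact by construction and asserted against the count matrix in tests.

**What the generator does not emulate:** read-level artifacts (sequencing
error, PCR duplication — support is always 1), chromatin context beyond
peaks (no sequence, one autosome), depth-dependent hopping, sample-specific
hop rates, ambient fragments, and same-sample doublets. Passing tests
therefore show the estimator's behaviour under independent per-fragment
hopping, not under every failure mode of real libraries; with real data the
incidence-unique fraction is typically a fifth or so rather than ~0, because
real depth spans orders of magnitude and shallow barcodes can stay unique by
chance.

## QC metrics

* **FRIP** — fraction of fragments (or read support) overlapping any merged
  peak by ≥ 1 bp, half-open semantics: fragment [10,20) does not touch peak
  [20,30). Merging uses bedtools semantics (overlapping or book-ended
  intervals join), making FRIP invariant to splitting a peak into adjacent
  halves.
* **TSS enrichment (pooled)** — each fragment contributes two insertion
  events, at `start` and `end − 1`. Events are profiled over ±2000 bp around
  all TSS with strand-aware offsets, normalized by the mean count over the
  outermost 100 positions on each side, smoothed with a 21-bp centered
  moving average; the score is the smoothed maximum. A zero background is
  floored at (total in-window events)/(window width × 1000), preserving
  "large score" semantics for delta-like profiles. A flat profile scores
  ~1.0.
* **TSS enrichment (per cell)** — mean insertion density over the central
  ±100 bp divided by the flank-edge density (floored at one event per
  window). The pooled max would reward single noisy positions in shallow
  cells; the central mean is the stabler per-cell convention. This is a
  deliberate mode difference.
* **Nucleosome signal** — (count of fragments with 147 < length ≤ 294) /
  (count with length ≤ 147); undefined (None/NaN) with no sub-nucleosomal
  fragments. Length is `end − start`; no Tn5 offset re-correction anywhere
  (fragments files are assumed already +4/−5 shifted upstream).
* **Mitochondrial fraction** — support-weighted fraction on contigs named
  `chrM`/`MT` (configurable).
* **Length histogram** — 1-bp bins; lengths above `max_length` (default
  1000) pool into bin `max_length + 1`, so counts always sum to the number
  of fragments.

## Peak comparison

Peak sets are merged on construction. `overlap_fraction(a, b)` is the
fraction of a's intervals overlapping ≥ 1 bp of b (asymmetric; report both
directions). Upset counts come in two modes, because "number of intersected
peaks" is ambiguous: **region** mode merges the union into connected regions
and counts regions per membership pattern (disjoint and exhaustive; agrees
with a per-base membership scan, the oracle in tests); **reference** mode
counts each interval of a designated reference set by which other sets it
overlaps — the natural way to phrase "peaks shared with the fresh sample".
The overlap predicate is ≥ 1 bp everywhere, generalized by a
`min_overlap_bp` parameter. Per-peak fraction-of-cells-with-signal is the
share of a sample's cells with ≥ 1 fragment overlapping the peak;
cross-sample correlation of these vectors (Pearson and Spearman, computed on
the shared/union peak set) is reported as None when either vector is
constant.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open, including the 1-bp sentinel
`chr1 0 1` exercised through every IO path. Metrics on empty fragment
streams raise an undefined-metric error rather than returning 0 (an empty
FRIP of 0 would masquerade as a terrible library); nucleosome signal with an
empty denominator is the one metric that returns an undefined *value*, since
the condition is data-dependent rather than degenerate input. gzip output is
written with a zeroed mtime and no embedded filename so identical inputs
produce identical bytes. Barcode comparison across samples strips a trailing
`-<digits>` GEM-group suffix by default (per-sample pipeline runs append
identical suffixes; stripping is safe and flag-controlled).

## Problem sizes used in validation

The test suite validates the classifier oracle-exactly on small matrices and
runs simulations between 10⁵ and 10⁷ fragments: the ten-plex recovery check
uses the full default conditions (10 × 500 cells, ~10 M fragments), the
monotonicity sweep uses 4 × 130 cells at five hop rates, and the phase
boundary uses 2 × 150 cells at 5000 fragments/cell. `scripts/acceptance.py`
runs the full default conditions once.

## Known limitations

* The hop-rate default is a modeling choice; the method's real-data
  performance depends on the empirical hop rate and depth distribution,
  which the generator only approximates.
* The FR classifier cannot separate a cross-sample doublet from a heavily
  hopped singlet near the threshold; both are (correctly) left ambiguous,
  but no explicit doublet score is produced.
* Peaks are consumed, never called; all peak-dependent metrics inherit the
  quality of the supplied peak set.
* Fragments files are read fully into memory for the vectorised paths; at
  typical per-sample sizes (10⁶–10⁸ records) this is fine on a workstation,
  but the streaming reader should be preferred for constrained environments.
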