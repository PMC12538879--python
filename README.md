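# atacmux

Fragment-ratio demultiplexing and quality control for Tn5-barcode-multiplexed
droplet scATAC-seq.

## The problem

Multiplexing scATAC-seq samples with custom Tn5 sample barcodes (tagment each
sample with its own barcoded transposome, pool, then run one 10x Chromium
reaction) is attractive for cost and batch-effect control, but it suffers
from **barcode hopping**: free, unbound Tn5 inserts survive pooling, enter
GEMs, and act as amplification primers, stamping a cell's fragments with the
wrong sample barcode. The result is that most cell barcodes appear in
several samples' fragments files, and the naive **incidence model** — keep
only barcodes observed in exactly one sample — throws away most of the data.

## The method

For cell barcode *c* and sample *s*, let *N<sub>cs</sub>* be the fragment
count observed for *c* in *s*'s fragments file. The **fragment ratio** is

&nbsp;&nbsp;&nbsp;&nbsp;*r<sub>c</sub>* = max<sub>s</sub> *N<sub>cs</sub>* / Σ<sub>s</sub> *N<sub>cs</sub>*

A barcode is assigned to its top sample when *r<sub>c</sub>* **strictly
exceeds** a threshold (default 0.6). Because hopping spreads a minority of a
cell's fragments thinly over the other samples, the true sample keeps the
majority and singlets pass easily, while cross-sample doublet GEMs mix two
samples near 50/50 and land below the threshold (ambiguous). Barcodes with
too few total fragments are set aside as low-count.

The package provides, as a library plus a thin `atacmux` CLI:

* `atacmux.demux` — count matrix *N<sub>cs</sub>*, fragment ratios,
  threshold assignment, incidence baseline, clean per-sample fragment
  splitting, reports;
* `atacmux.simulate` — a seeded generative model of the multiplexed
  experiment (hopping, cross-sample doublets, peaks/TSS, nucleosomal
  fragment-length mixture, mitochondrial contamination) with ground truth;
* `atacmux.qc` — FRIP, TSS enrichment, nucleosome signal, mitochondrial
  fraction, fragment-length histograms, pooled and per cell;
* `atacmux.peaks` — peak-set overlap fractions, upset intersection counts,
  per-peak fraction-of-cells-with-signal and its cross-sample correlation;
* `atacmux.io` — fragments.tsv(.gz) and BED3/BED6 reading/writing, 0-based
  half-open coordinates throughout.

## Worked example

```bash
python examples/01_simulate_and_demultiplex.py
```

```
simulated 793919 fragments for 1000 cells; 158709 fragments (20.0%) carry a hopped sample barcode
incidence-unique baseline: 0.0% of barcodes (seen in exactly one sample)
fragment-ratio assigned:   92.0% of barcodes (ambiguous 5.7%, low-count 2.3%)
against ground truth: singlet precision 1.0000, recall 0.9766; doublet leak-through 3.3%
```

Five samples of 200 cells each are pooled with a 20% per-fragment hop rate.
At ~800 fragments per cell, every cell leaks a few fragments into every
other sample, so *no* barcode is unique to one sample and the incidence
baseline retains 0%. The fragment ratio of a singlet concentrates at
1 − hop_rate = 0.8, far above the 0.6 threshold, so 92% of barcodes are
assigned — every one of them to the correct sample (precision 1.0) — while
doublets and shallow barcodes are left out deliberately.

The same pipeline from the shell:

```bash
atacmux simulate --config sim.yaml --out simdir
atacmux demux --sample s0=simdir/sample_0.fragments.tsv.gz \
              --sample s1=simdir/sample_1.fragments.tsv.gz ... --out demuxdir
atacmux evaluate --assignments demuxdir/assignments.tsv --truth simdir/truth.tsv
atacmux qc --fragments demuxdir/s0.fragments.tsv.gz \
           --peaks simdir/peaks.bed --tss simdir/tss.bed --out qc.json
atacmux compare-peaks --set a=peaks_a.bed --set b=peaks_b.bed --out cmpdir
```

`examples/02_qc_metrics.py` and `examples/03_peak_comparison.py` walk
through the QC and peak-comparison capabilities the same way.

## Documentation

`docs/methods.md` describes the generative model, the metric definitions and
their numerical conventions, parameter defaults, and known limitations.
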