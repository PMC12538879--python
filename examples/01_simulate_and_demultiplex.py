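"""Simulate a multiplexed scATAC-seq experiment and demultiplex it by fragment ratio.

Five Tn5-barcoded samples are pooled with a 20% per-fragment barcode-hopping
rate, so almost every cell barcode shows up in several samples' fragments
files. The incidence baseline (keep barcodes seen in exactly one sample)
collapses, while fragment-ratio thresholding (assign a barcode to its top
sample when that sample holds >60% of its fragments) recovers nearly all
singlets and leaves cross-sample doublets ambiguous.
"""

from atacmux import DemuxConfig, SimConfig, demultiplex, evaluate_assignment, simulate

config = SimConfig(
    n_samples=5,
    cells_per_sample=200,
    mean_fragments=800,
    hop_rate=0.2,
    doublet_rate=0.05,
    genome_length=5_000_000,
    n_peaks=500,
    seed=1,
)
sim = simulate(config)
print(f"simulated {sim.n_fragments} fragments for {len(sim.truth)} cells; "
      f"{sim.n_hopped_fragments} fragments ({sim.n_hopped_fragments / sim.n_fragments:.1%}) "
      "carry a hopped sample barcode")

matrix, records, table, summary = demultiplex(sim.fragments, DemuxConfig(min_fragments=100))
print(f"incidence-unique baseline: {summary['incidence_unique_fraction']:.1%} of barcodes "
      "(seen in exactly one sample)")
print(f"fragment-ratio assigned:   {summary['status_fractions']['assigned']:.1%} of barcodes "
      f"(ambiguous {summary['status_fractions']['ambiguous']:.1%}, "
      f"low-count {summary['status_fractions']['low_count']:.1%})")

metrics = evaluate_assignment(records, sim.truth)
print(f"against ground truth: singlet precision {metrics['singlet_precision']:.4f}, "
      f"recall {metrics['singlet_recall']:.4f}; "
      f"doublet leak-through {metrics['doublet_assigned_fraction']:.1%}")
print("-> high precision/recall means hopped fragments almost never flip a "
      "barcode's majority sample; doublets sit near 50/50 and fail the 0.6 cut.")
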