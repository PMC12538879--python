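"""Synthetic multi-sample scATAC fragment generator with barcode hopping.

Emulates the structure of a Tn5-barcode-multiplexed droplet scATAC-seq
experiment: S samples pooled after tagmentation, shared 16-bp cell barcodes,
free Tn5 inserts spreading a cell's fragments across other samples' files
("barcode hopping"), and cross-sample doublet GEMs. Coordinates are drawn
on one synthetic autosome plus a "chrM" contig; no sequence content is
generated because nothing downstream needs bases.

Generative procedure (all randomness from one seeded numpy Generator, in
this documented order, so same-seed runs are reproducible):

1. place ``n_peaks`` non-overlapping peaks of ``peak_width`` uniformly on
   the autosome; one TSS (random strand) sits at each peak center; each peak
   gets a relative accessibility weight ~ Gamma(``peak_weight_shape``, 1)
   (normalized), shared by all cells and samples, so per-peak signal
   fractions carry the peak-to-peak structure real peak sets have;
2. create ``cells_per_sample x n_samples`` unique 16-mer barcodes, each with
   a true sample; with probability ``doublet_rate`` a barcode is a doublet
   mixing two samples with proportion ~ U[0.3, 0.7];
3. per cell, draw a fragment count from a negative binomial with mean
   ``mean_fragments`` and shape ``dispersion`` (floored at 1 so every
   barcode is observable);
4. per fragment: with probability ``mito_fraction`` it lands uniformly on
   chrM; otherwise with probability ``frip_target`` its midpoint is uniform
   inside a random peak, else uniform outside all peaks; its length comes
   from a two-normal mixture (sub-nucleosomal weight ``nfr_weight``,
   truncated at >= 20 bp);
5. per fragment, with probability ``hop_rate`` the emitting sample label is
   replaced by a uniform draw over the other samples (doublet fragments hop
   from their emitting component's sample);
6. fragments are routed to per-sample files by their possibly-hopped label;
   truth records tally hopped counts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demux import AssignmentRecord, STATUS_ASSIGNED
from .errors import ConfigError, ConsistencyError
from .io import FRAGMENT_COLUMNS, GenomicInterval, TssSite, write_bed, write_fragments
from .peaks import PeakSet

TRUTH_COLUMNS = [
    "cell_barcode",
    "true_sample",
    "second_sample",
    "is_doublet",
    "n_fragments_total",
    "n_fragments_hopped",
]

_MIN_FRAGMENT_LENGTH = 20


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic multiplexed experiment.

    Defaults model a ten-plex HepG2-like run: 10 samples x 500 cells,
    overdispersed depth around 2000 fragments per cell, a 20% per-fragment
    hop rate, 5% cross-sample doublets, 35% of fragments in peaks, and the
    canonical sub-nucleosomal (75 +/- 25 bp) / mono-nucleosomal
    (200 +/- 35 bp) fragment-length mixture.
    """

    n_samples: int = 10
    cells_per_sample: int = 500
    hop_rate: float = 0.2
    doublet_rate: float = 0.05
    mean_fragments: float = 2000.0
    dispersion: float = 2.0
    genome_length: int = 20_000_000
    n_peaks: int = 2000
    peak_width: int = 400
    frip_target: float = 0.35
    peak_weight_shape: float = 1.0
    nfr_length_mean: float = 75.0
    nfr_length_sd: float = 25.0
    mono_length_mean: float = 200.0
    mono_length_sd: float = 35.0
    nfr_weight: float = 0.6
    mito_fraction: float = 0.05
    mito_length: int = 16_571
    chrom_name: str = "chr1"
    mito_name: str = "chrM"
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        if self.cells_per_sample < 1:
            raise ConfigError("cells_per_sample must be >= 1")
        for name, lo_ok in (("hop_rate", True), ("doublet_rate", True), ("mito_fraction", True)):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if not (0 < self.frip_target < 1):
            raise ConfigError("frip_target must be in (0, 1)")
        if not (0 < self.nfr_weight < 1):
            raise ConfigError("nfr_weight must be in (0, 1)")
        if self.mean_fragments <= 0 or self.dispersion <= 0:
            raise ConfigError("mean_fragments and dispersion must be positive")
        if self.peak_weight_shape <= 0:
            raise ConfigError("peak_weight_shape must be positive")
        if self.n_peaks * self.peak_width >= self.genome_length:
            raise ConfigError(
                f"cannot place {self.n_peaks} x {self.peak_width} bp peaks on a "
                f"{self.genome_length} bp genome"
            )

    @property
    def sample_names(self) -> list[str]:
        width = len(str(self.n_samples - 1))
        return [f"sample_{i:0{width}d}" for i in range(self.n_samples)]


@dataclass
class SimResult:
    """Everything one simulation run produces."""

    config: SimConfig
    fragments: dict[str, pd.DataFrame]
    truth: pd.DataFrame
    peaks: PeakSet
    tss: list[TssSite]
    #: per-fragment bookkeeping: emitting sample index vs file label index
    n_hopped_fragments: int = 0
    n_fragments: int = 0


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 16) -> np.ndarray:
    """Unique random barcodes of ACGT (re-draws the rare collisions)."""
    alphabet = np.array(list("ACGT"))
    codes = rng.integers(0, 4, size=(n, length))
    barcodes = np.array(["".join(row) for row in alphabet[codes]])
    # collisions at n << 4^16 are vanishingly rare, but correctness is cheap
    while len(np.unique(barcodes)) < n:
        _, first_idx = np.unique(barcodes, return_index=True)
        dup = np.setdiff1d(np.arange(n), first_idx)
        redraw = rng.integers(0, 4, size=(len(dup), length))
        barcodes[dup] = ["".join(row) for row in alphabet[redraw]]
    return barcodes


def _place_peaks(rng: np.random.Generator, cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping peak starts and the sorted free-space offsets used."""
    free = cfg.genome_length - cfg.n_peaks * cfg.peak_width
    gaps = np.sort(rng.integers(0, free + 1, size=cfg.n_peaks))
    starts = gaps + np.arange(cfg.n_peaks) * cfg.peak_width
    return starts, gaps


def simulate(config: SimConfig = SimConfig()) -> SimResult:
    """Run the generative model; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_names

    # 1. peaks and TSS
    peak_starts, gap_offsets = _place_peaks(rng, cfg)
    peak_ivs = [
        GenomicInterval(cfg.chrom_name, int(s), int(s + cfg.peak_width)) for s in peak_starts
    ]
    peaks = PeakSet(peak_ivs, name="true_peaks")
    peak_weights = rng.gamma(cfg.peak_weight_shape, 1.0, size=cfg.n_peaks)
    peak_weights /= peak_weights.sum()
    tss_strands = np.where(rng.random(cfg.n_peaks) < 0.5, "+", "-")
    tss = [
        TssSite(cfg.chrom_name, int(s + cfg.peak_width // 2), str(st))
        for s, st in zip(peak_starts, tss_strands)
    ]

    # 2. cells
    n_cells = cfg.cells_per_sample * cfg.n_samples
    barcodes = _random_barcodes(rng, n_cells)
    true_sample_idx = np.repeat(np.arange(cfg.n_samples), cfg.cells_per_sample)
    is_doublet = rng.random(n_cells) < cfg.doublet_rate
    second_shift = rng.integers(1, cfg.n_samples, size=n_cells)
    second_sample_idx = (true_sample_idx + second_shift) % cfg.n_samples
    mix = rng.uniform(0.3, 0.7, size=n_cells)

    # 3. per-cell depth (negative binomial, floored at 1)
    p = cfg.dispersion / (cfg.dispersion + cfg.mean_fragments)
    n_frags = rng.negative_binomial(cfg.dispersion, p, size=n_cells)
    n_frags = np.maximum(n_frags, 1)
    total = int(n_frags.sum())
    cell_of = np.repeat(np.arange(n_cells), n_frags)

    # emitting sample per fragment (doublets mix two samples)
    emit = true_sample_idx[cell_of].copy()
    from_second = is_doublet[cell_of] & (rng.random(total) >= mix[cell_of])
    emit[from_second] = second_sample_idx[cell_of][from_second]

    # 4. coordinates and lengths
    lengths = np.where(
        rng.random(total) < cfg.nfr_weight,
        rng.normal(cfg.nfr_length_mean, cfg.nfr_length_sd, size=total),
        rng.normal(cfg.mono_length_mean, cfg.mono_length_sd, size=total),
    )
    lengths = np.maximum(np.rint(np.abs(lengths)).astype(np.int64), _MIN_FRAGMENT_LENGTH)

    is_mito = rng.random(total) < cfg.mito_fraction
    in_peak = ~is_mito & (rng.random(total) < cfg.frip_target)

    mid = np.empty(total, dtype=np.int64)
    # peak fragments: weight-biased peak choice, uniform midpoint inside it
    k_peak = int(in_peak.sum())
    chosen = rng.choice(cfg.n_peaks, size=k_peak, p=peak_weights)
    mid[in_peak] = peak_starts[chosen] + rng.integers(0, cfg.peak_width, size=k_peak)
    # background fragments: uniform midpoint over non-peak space
    bg = ~is_mito & ~in_peak
    k_bg = int(bg.sum())
    free = cfg.genome_length - cfg.n_peaks * cfg.peak_width
    u = rng.integers(0, free, size=k_bg)
    mid[bg] = u + cfg.peak_width * np.searchsorted(gap_offsets, u, side="right")
    # mito fragments: uniform start
    k_m = int(is_mito.sum())
    mito_len = np.minimum(lengths[is_mito], cfg.mito_length - 1)
    lengths[is_mito] = mito_len
    mid[is_mito] = 0  # placeholder; starts drawn directly below

    start = np.clip(mid - lengths // 2, 0, None)
    end = start + lengths
    over = end > cfg.genome_length
    start[over] = cfg.genome_length - lengths[over]
    end[over] = cfg.genome_length
    if k_m:
        m_start = rng.integers(0, cfg.mito_length - mito_len + 1)
        start[is_mito] = m_start
        end[is_mito] = m_start + mito_len

    chrom = np.where(is_mito, cfg.mito_name, cfg.chrom_name)

    # 5. barcode hopping
    hop = rng.random(total) < cfg.hop_rate
    label = emit.copy()
    if hop.any():
        shift = rng.integers(1, cfg.n_samples, size=int(hop.sum()))
        label[hop] = (emit[hop] + shift) % cfg.n_samples

    frame = pd.DataFrame(
        {
            "chrom": pd.Categorical(chrom, categories=[cfg.chrom_name, cfg.mito_name]),
            "start": start,
            "end": end,
            "barcode": pd.Categorical.from_codes(cell_of, categories=list(barcodes)),
            "support": np.ones(total, dtype=np.int64),
            "_label": label,
        }
    )

    # 6. route to per-sample frames, position-sorted like real fragments files
    fragments: dict[str, pd.DataFrame] = {}
    for i, name in enumerate(samples):
        sub = frame[frame["_label"] == i]
        sub = sub.sort_values(["chrom", "start", "end"], kind="mergesort")
        fragments[name] = sub[FRAGMENT_COLUMNS].reset_index(drop=True)

    hopped_per_cell = np.bincount(cell_of[hop], minlength=n_cells)
    truth = pd.DataFrame(
        {
            "cell_barcode": barcodes,
            "true_sample": np.array(samples)[true_sample_idx],
            "second_sample": np.where(
                is_doublet, np.array(samples)[second_sample_idx], ""
            ),
            "is_doublet": is_doublet,
            "n_fragments_total": n_frags,
            "n_fragments_hopped": hopped_per_cell,
        }
    )
    return SimResult(
        config=cfg,
        fragments=fragments,
        truth=truth,
        peaks=peaks,
        tss=tss,
        n_hopped_fragments=int(hop.sum()),
        n_fragments=total,
    )


def write_simulation(result: SimResult, outdir: str | Path, compress: bool = True) -> dict[str, str]:
    """Write per-sample fragments files, truth table, peaks and TSS BEDs.

    Returns a mapping of logical output name to path. Same-seed runs produce
    byte-identical files (gzip members are written with mtime=0).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    ext = ".fragments.tsv.gz" if compress else ".fragments.tsv"
    for name, df in result.fragments.items():
        path = outdir / f"{name}{ext}"
        write_fragments(df, path, compress=compress)
        paths[name] = str(path)
    truth_path = outdir / "truth.tsv"
    result.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)
    peaks_path = outdir / "peaks.bed"
    write_bed(result.peaks, peaks_path)
    paths["peaks"] = str(peaks_path)
    tss_path = outdir / "tss.bed"
    write_bed(
        [GenomicInterval(t.chrom, t.position, t.position + 1, ".", t.strand) for t in result.tss],
        tss_path,
    )
    paths["tss"] = str(tss_path)
    return paths


def read_truth(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"second_sample": str}, keep_default_na=False)
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ConsistencyError(f"truth table missing columns {missing}")
    truth["is_doublet"] = truth["is_doublet"].astype(bool)
    return truth


def evaluate_assignment(
    assignments: list[AssignmentRecord],
    truth: pd.DataFrame,
) -> dict:
    """Score demultiplexing against simulation ground truth.

    Returns assigned fraction over all barcodes, precision (correct /
    assigned among singlets; None when no singlet was assigned), singlet
    recall (correctly assigned / all singlets), doublet leak-through
    (fraction of doublets that got assigned; None without doublets), and the
    incidence-model unique fraction derived from the per-sample counts.
    """
    table = pd.DataFrame(
        {
            "barcode": [r.barcode for r in assignments],
            "best_sample": [r.best_sample for r in assignments],
            "status": [r.status for r in assignments],
            "multiplicity": [
                sum(1 for v in r.per_sample_counts.values() if v > 0) for r in assignments
            ],
        }
    )
    got = set(table["barcode"])
    expected = set(truth["cell_barcode"])
    if got != expected:
        raise ConsistencyError(
            f"barcode universes differ: {len(got - expected)} unknown to truth, "
            f"{len(expected - got)} missing from assignments"
        )
    merged = table.merge(truth, left_on="barcode", right_on="cell_barcode", how="inner")
    n = len(merged)
    assigned = merged["status"] == STATUS_ASSIGNED
    singlet = ~merged["is_doublet"]
    correct = assigned & (merged["best_sample"] == merged["true_sample"])

    n_assigned_singlets = int((assigned & singlet).sum())
    precision = (
        float((correct & singlet).sum() / n_assigned_singlets) if n_assigned_singlets else None
    )
    n_singlets = int(singlet.sum())
    recall = float((correct & singlet).sum() / n_singlets) if n_singlets else None
    n_doublets = n - n_singlets
    doublet_leak = float((assigned & ~singlet).sum() / n_doublets) if n_doublets else None
    return {
        "n_barcodes": n,
        "assigned_fraction": float(assigned.mean()) if n else 0.0,
        "singlet_precision": precision,
        "singlet_recall": recall,
        "doublet_assigned_fraction": doublet_leak,
        "incidence_unique_fraction": float((merged["multiplicity"] == 1).mean()) if n else 0.0,
    }


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)


def config_from_dict(d: dict) -> SimConfig:
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulator parameters: {sorted(unknown)}")
    return SimConfig(**d)
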