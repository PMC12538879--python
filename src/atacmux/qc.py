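"""ATAC-seq quality-control statistics, pooled and per cell.

The metrics quantify signal-to-noise and library structure of chromatin
accessibility data: FRIP (fraction of fragments in peak regions), TSS
enrichment (fold-enrichment of Tn5 insertion events around transcription
start sites over distal background), nucleosome signal (mono-nucleosomal /
sub-nucleosomal fragment-length ratio), mitochondrial fraction, and the
fragment-length histogram whose bimodality reflects the nucleosomal ladder.

Conventions
-----------
* A fragment overlaps a peak if ANY base overlaps a merged peak interval
  (half-open intersection), the deepTools/Signac convention.
* Fragment length is ``end - start``; no Tn5 offset re-correction is applied
  (fragments files are assumed already +4/-5 shifted upstream).
* Each fragment contributes two Tn5 insertion events, at positions ``start``
  and ``end - 1`` (the outermost covered bases).
* Nucleosome-signal cutoffs follow the nucleosomal-DNA convention:
  sub-nucleosomal <= 147 bp, mono-nucleosomal 148-294 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import ConfigError, UndefinedMetricError
from .io import TssSite, as_frame
from .peaks import PeakSet

DEFAULT_MITO_NAMES = frozenset({"chrM", "MT"})

NFR_MAX = 147
MONO_MAX = 294


@dataclass
class QcReport:
    """Pooled QC metrics for one fragment collection."""

    frip: float | None
    tss_enrichment: float | None
    nucleosome_signal: float | None
    mito_fraction: float
    n_fragments: int
    length_histogram: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "frip": self.frip,
            "tss_enrichment": self.tss_enrichment,
            "nucleosome_signal": self.nucleosome_signal,
            "mito_fraction": self.mito_fraction,
            "n_fragments": self.n_fragments,
            "length_histogram": {str(k): int(v) for k, v in sorted(self.length_histogram.items())},
        }


def frip(fragments, peaks: PeakSet, weighting: str = "fragments") -> float:
    """Fraction of fragments (or read support) overlapping any peak by >=1 bp."""
    if weighting not in ("fragments", "reads"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    df = as_frame(fragments)
    if len(df) == 0:
        raise UndefinedMetricError("FRIP is undefined on an empty fragment stream")
    if len(peaks) == 0:
        return 0.0
    hit = peaks.fragment_overlap_mask(df)
    if weighting == "reads":
        support = df["support"].to_numpy()
        return float(support[hit].sum() / support.sum())
    return float(hit.mean())


def _insertion_sites(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Chrom + position arrays of both Tn5 insertion events per fragment."""
    chroms = np.concatenate([df["chrom"].to_numpy(), df["chrom"].to_numpy()])
    pos = np.concatenate([df["start"].to_numpy(), df["end"].to_numpy() - 1])
    return chroms, pos.astype(np.int64)


def tss_insertion_profile(fragments, tss: Iterable[TssSite], flank: int = 2000) -> np.ndarray:
    """Raw aggregate insertion counts at offsets -flank..+flank around TSS.

    Offsets are strand-oriented: for "-" TSS the offset sign is flipped, so
    positive offsets always point downstream of transcription.
    """
    tss = list(tss)
    if not tss:
        raise UndefinedMetricError("TSS enrichment requires at least one TSS")
    df = as_frame(fragments)
    chroms, pos = _insertion_sites(df)
    profile = np.zeros(2 * flank + 1, dtype=np.int64)
    order = np.argsort(chroms, kind="stable")
    chroms_s, pos_s = chroms[order], pos[order]
    # contiguous per-chromosome blocks with sorted positions
    uniq, starts_idx = np.unique(chroms_s, return_index=True)
    blocks = {}
    bounds = list(starts_idx) + [len(chroms_s)]
    for i, chrom in enumerate(uniq):
        block = np.sort(pos_s[bounds[i]:bounds[i + 1]])
        blocks[chrom] = block
    for site in tss:
        block = blocks.get(site.chrom)
        if block is None:
            continue
        lo = np.searchsorted(block, site.position - flank, side="left")
        hi = np.searchsorted(block, site.position + flank, side="right")
        offs = block[lo:hi] - site.position
        if site.strand == "-":
            offs = -offs
        np.add.at(profile, offs + flank, 1)
    return profile


def tss_enrichment(
    fragments,
    tss: Iterable[TssSite],
    flank: int = 2000,
    edge: int = 100,
    smooth_window: int = 21,
) -> tuple[float, np.ndarray]:
    """ENCODE-style aggregate TSS enrichment score and normalized profile.

    Insertion events are profiled over [-flank, +flank] around all TSS
    (strand-aware); the profile is normalized by the mean count over the
    outermost ``edge`` positions at both ends, smoothed with a centered
    moving average of width ``smooth_window``, and the score is the maximum
    of the smoothed normalized profile. A zero background is floored at
    (total in-window insertions) / (window width x 1000) so a sharply peaked
    profile still reports a large, finite score.
    """
    profile = tss_insertion_profile(fragments, tss, flank=flank).astype(float)
    total = profile.sum()
    if total == 0:
        raise UndefinedMetricError("no insertion events within any TSS window")
    background = float(np.concatenate([profile[:edge], profile[-edge:]]).mean())
    if background == 0:
        background = total / (len(profile) * 1000.0)
    normalized = profile / background
    smoothed = uniform_filter1d(normalized, size=smooth_window, mode="nearest")
    return float(smoothed.max()), smoothed


def nucleosome_signal(fragments, nfr_max: int = NFR_MAX, mono_max: int = MONO_MAX) -> float | None:
    """Mono-nucleosomal over sub-nucleosomal fragment-count ratio.

    Returns None (an undefined value, not an error) when no fragment is
    sub-nucleosomal.
    """
    df = as_frame(fragments)
    lengths = (df["end"] - df["start"]).to_numpy()
    sub = int((lengths <= nfr_max).sum())
    mono = int(((lengths > nfr_max) & (lengths <= mono_max)).sum())
    if sub == 0:
        return None
    return mono / sub


def mito_fraction(fragments, mito_names: Iterable[str] = DEFAULT_MITO_NAMES) -> float:
    """Support-weighted fraction of fragments on mitochondrial contigs."""
    df = as_frame(fragments)
    if len(df) == 0:
        raise UndefinedMetricError("mitochondrial fraction is undefined on an empty stream")
    mito = df["chrom"].isin(set(mito_names)).to_numpy()
    support = df["support"].to_numpy()
    return float(support[mito].sum() / support.sum())


def fragment_length_histogram(fragments, max_length: int = 1000) -> dict[int, int]:
    """Counts per 1-bp length bin; lengths > max_length pool into bin max_length + 1."""
    df = as_frame(fragments)
    lengths = (df["end"] - df["start"]).to_numpy()
    lengths = np.where(lengths > max_length, max_length + 1, lengths)
    vals, counts = np.unique(lengths, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def pooled_qc(
    fragments,
    peaks: PeakSet | None = None,
    tss: Iterable[TssSite] | None = None,
    mito_names: Iterable[str] = DEFAULT_MITO_NAMES,
    max_length: int = 1000,
) -> QcReport:
    """All pooled metrics in one pass; peak/TSS metrics are None when inputs absent."""
    df = as_frame(fragments)
    if len(df) == 0:
        raise UndefinedMetricError("QC is undefined on an empty fragment stream")
    frip_v = frip(df, peaks) if peaks is not None else None
    tss_v = tss_enrichment(df, list(tss))[0] if tss else None
    return QcReport(
        frip=frip_v,
        tss_enrichment=tss_v,
        nucleosome_signal=nucleosome_signal(df),
        mito_fraction=mito_fraction(df, mito_names),
        n_fragments=len(df),
        length_histogram=fragment_length_histogram(df, max_length=max_length),
    )


def per_cell_qc(
    fragments,
    peaks: PeakSet | None = None,
    tss: Iterable[TssSite] | None = None,
    cells: Iterable[str] | None = None,
    mito_names: Iterable[str] = DEFAULT_MITO_NAMES,
    flank: int = 2000,
    center: int = 100,
    edge: int = 100,
) -> pd.DataFrame:
    """Per-barcode QC table restricted to the given cell barcodes.

    Columns: n_fragments, frip, mito_fraction, nucleosome_signal, and
    tss_enrichment when TSS are given. The per-cell TSS score is the mean
    normalized insertion density over the central +/-``center`` bp rather
    than the smoothed maximum used by the pooled score — a deliberate mode
    difference that keeps shallow per-cell profiles from rewarding single
    noisy positions.
    """
    if cells is None:
        raise ConfigError("per-cell QC requires an explicit cell barcode set")
    cells = sorted(set(cells))
    if not cells:
        raise ConfigError("cell set must be nonempty")
    df = as_frame(fragments)
    df = df[df["barcode"].isin(cells)]
    out = pd.DataFrame(index=pd.Index(cells, name="barcode"))
    grouped = df.groupby("barcode", observed=True)
    out["n_fragments"] = grouped.size().reindex(cells, fill_value=0)

    lengths = df["end"] - df["start"]
    sub = (lengths <= NFR_MAX).groupby(df["barcode"], observed=True).sum().reindex(cells, fill_value=0)
    mono = (
        ((lengths > NFR_MAX) & (lengths <= MONO_MAX))
        .groupby(df["barcode"], observed=True)
        .sum()
        .reindex(cells, fill_value=0)
    )
    out["nucleosome_signal"] = np.where(sub > 0, mono / sub.replace(0, 1), np.nan)

    mito = df["chrom"].isin(set(mito_names))
    mito_n = mito.groupby(df["barcode"], observed=True).sum().reindex(cells, fill_value=0)
    out["mito_fraction"] = np.where(out["n_fragments"] > 0, mito_n / out["n_fragments"].replace(0, 1), np.nan)

    if peaks is not None:
        hit = pd.Series(peaks.fragment_overlap_mask(df), index=df.index)
        in_peak = hit.groupby(df["barcode"], observed=True).sum().reindex(cells, fill_value=0)
        out["frip"] = np.where(out["n_fragments"] > 0, in_peak / out["n_fragments"].replace(0, 1), np.nan)

    if tss is not None:
        out["tss_enrichment"] = _per_cell_tss(df, list(tss), cells, flank=flank, center=center, edge=edge)
    return out


def _per_cell_tss(
    df: pd.DataFrame,
    tss: list[TssSite],
    cells: list[str],
    flank: int,
    center: int,
    edge: int,
) -> np.ndarray:
    """Per-cell TSS score: central insertion density over flank-edge density."""
    if not tss:
        raise UndefinedMetricError("TSS enrichment requires at least one TSS")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for site in tss:
        tss_by_chrom.setdefault(site.chrom, []).append(site.position)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in tss_by_chrom.items()}

    barcodes = np.concatenate([df["barcode"].to_numpy()] * 2)
    chroms, pos = _insertion_sites(df)
    center_counts = pd.Series(0, index=pd.Index(cells, name="barcode"), dtype=np.int64)
    edge_counts = center_counts.copy()
    for chrom, sites in tss_by_chrom.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        p = pos[mask]
        bc = barcodes[mask]
        # nearest TSS distance decides which ring each insertion falls in
        j = np.searchsorted(sites, p)
        left = np.abs(p - sites[np.clip(j - 1, 0, len(sites) - 1)])
        right = np.abs(sites[np.clip(j, 0, len(sites) - 1)] - p)
        dist = np.minimum(left, right)
        in_center = dist <= center
        in_edge = (dist > flank - edge) & (dist <= flank)
        for sel, acc in ((in_center, center_counts), (in_edge, edge_counts)):
            if sel.any():
                got = pd.Series(bc[sel]).value_counts()
                acc.loc[got.index] += got.to_numpy()
    center_width = 2 * center + 1
    edge_width = 2 * edge
    center_rate = center_counts / center_width
    edge_rate = edge_counts / edge_width
    # floor the per-cell background at one event over the whole window
    floor = 1.0 / (2 * flank + 1)
    score = center_rate / np.maximum(edge_rate, floor)
    score[center_counts + edge_counts == 0] = np.nan
    return score.to_numpy(dtype=float)


def filter_cells(table: pd.DataFrame, thresholds: Mapping[str, tuple[float | None, float | None]]) -> pd.DataFrame:
    """Subset a per-cell QC table to barcodes passing all (min, max) bounds.

    ``thresholds`` maps a metric column to an inclusive (min, max) pair;
    either bound may be None. Rows with NaN in a thresholded metric fail.
    """
    mask = pd.Series(True, index=table.index)
    for metric, (lo, hi) in thresholds.items():
        if metric not in table.columns:
            raise ConfigError(f"unknown QC metric {metric!r}")
        col = table[metric]
        ok = col.notna()
        if lo is not None:
            ok &= col >= lo
        if hi is not None:
            ok &= col <= hi
        mask &= ok
    return table[mask]
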