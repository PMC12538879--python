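"""Internal interval arithmetic on merged, sorted interval arrays.

All functions operate on half-open intervals. Peak sets are represented
per-chromosome as two parallel sorted numpy arrays (starts, ends) of merged,
non-overlapping intervals, which makes every overlap query a pair of binary
searches.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GenomicInterval


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort intervals and merge overlapping or book-ended ones (bedtools merge semantics)."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.name)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.name))
    return merged


def build_index(merged: Iterable[GenomicInterval]) -> Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends, global_index) arrays for merged intervals."""
    index: dict[str, tuple[list, list, list]] = {}
    for i, iv in enumerate(merged):
        starts, ends, idx = index.setdefault(iv.chrom, ([], [], []))
        starts.append(iv.start)
        ends.append(iv.end)
        idx.append(i)
    return {
        chrom: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64), np.asarray(g, dtype=np.int64))
        for chrom, (s, e, g) in index.items()
    }


def overlaps_any(
    chroms: pd.Series,
    starts: np.ndarray,
    ends: np.ndarray,
    index: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Boolean mask: does query interval i overlap any indexed interval by >=1 bp?"""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    hit = np.zeros(len(starts), dtype=bool)
    chrom_values = np.asarray(chroms)
    for chrom in pd.unique(chrom_values):
        entry = index.get(chrom)
        if entry is None:
            continue
        pstarts, pends, _ = entry
        mask = chrom_values == chrom
        qs, qe = starts[mask], ends[mask]
        # first merged interval whose end > query start; overlap iff it starts before query end
        j = np.searchsorted(pends, qs, side="right")
        ok = j < len(pstarts)
        sub = np.zeros(len(qs), dtype=bool)
        sub[ok] = pstarts[j[ok]] < qe[ok]
        hit[mask] = sub
    return hit


def overlap_pairs(
    chroms: pd.Series,
    starts: np.ndarray,
    ends: np.ndarray,
    index: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """All (query_i, merged_interval_global_j) pairs overlapping by >=1 bp."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    chrom_values = np.asarray(chroms)
    q_out: list[np.ndarray] = []
    p_out: list[np.ndarray] = []
    all_idx = np.arange(len(starts))
    for chrom in pd.unique(chrom_values):
        entry = index.get(chrom)
        if entry is None:
            continue
        pstarts, pends, gidx = entry
        mask = chrom_values == chrom
        qidx = all_idx[mask]
        qs, qe = starts[mask], ends[mask]
        lo = np.searchsorted(pends, qs, side="right")
        hi = np.searchsorted(pstarts, qe, side="left")
        counts = np.maximum(hi - lo, 0)
        total = int(counts.sum())
        if total == 0:
            continue
        rep_q = np.repeat(qidx, counts)
        # within-query offsets 0..count-1 added to each lo
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        rep_p = gidx[np.repeat(lo, counts) + offs]
        q_out.append(rep_q)
        p_out.append(rep_p)
    if not q_out:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(q_out), np.concatenate(p_out)
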