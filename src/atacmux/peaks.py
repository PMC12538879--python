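"""Peak-set containers and cross-sample peak comparisons.

Implements the comparisons used to judge whether preserved samples recover
the regulatory landscape of fresh ones: pairwise overlap fractions, upset
(intersection-pattern) counts over several per-sample peak sets, and the
per-peak fraction of cells showing signal, together with its cross-sample
correlation.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import intervals as _iv
from .errors import ConfigError, ConsistencyError, UndefinedMetricError
from .io import GenomicInterval, as_frame


class PeakSet:
    """A named set of sorted, merged, strand-less genomic intervals.

    Overlapping input intervals are merged on construction, so members are
    pairwise disjoint and sorted by (chrom, start, end).
    """

    def __init__(self, intervals: Iterable[GenomicInterval], name: str = ""):
        self.name = name
        self.intervals: list[GenomicInterval] = _iv.merge_intervals(intervals)
        self._index = _iv.build_index(self.intervals)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple], name: str = "") -> "PeakSet":
        return cls([GenomicInterval(c, s, e) for c, s, e, *_ in tuples], name=name)

    @classmethod
    def from_bed(cls, path, name: str = "") -> "PeakSet":
        from .io import read_bed

        return cls(read_bed(path, min_columns=3), name=name)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def index(self):
        return self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["chrom", "start", "end", "name", "strand"])

    def fragment_overlap_mask(self, fragments) -> np.ndarray:
        """Boolean per-fragment mask: overlaps any peak by >=1 bp."""
        df = as_frame(fragments)
        return _iv.overlaps_any(df["chrom"], df["start"].to_numpy(), df["end"].to_numpy(), self._index)


class MembershipPattern(NamedTuple):
    """One upset bar: the set of peak-set names and its region count."""

    pattern: frozenset
    count: int


def overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of intervals of ``a`` overlapping at least one interval of ``b``.

    Asymmetric by design; call twice to report both directions.
    """
    if len(a) == 0 or len(b) == 0:
        raise UndefinedMetricError("overlap fraction is undefined on an empty peak set")
    af = a.to_frame()
    hits = _iv.overlaps_any(af["chrom"], af["start"].to_numpy(), af["end"].to_numpy(), b.index)
    return float(hits.mean())


def upset_counts(
    sets: Sequence[PeakSet],
    mode: str = "region",
    reference: str | None = None,
    min_overlap_bp: int = 1,
) -> tuple[list[MembershipPattern], dict[str, int]]:
    """Intersection-pattern counts across >=2 peak sets, plus per-set totals.

    mode="region": merge the union of all sets into connected regions; each
    region's pattern is the set of inputs overlapping it, counts are regions
    per pattern (disjoint and exhaustive over covered bases).
    mode="reference": count each interval of the designated reference set by
    which other sets it overlaps.
    """
    if len(sets) < 2:
        raise ConfigError("upset comparison needs at least 2 peak sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ConfigError("peak-set names must be distinct")
    if min_overlap_bp < 1:
        raise ConfigError("min_overlap_bp must be >= 1")
    totals = {s.name: len(s) for s in sets}

    def _overlap_len(iv: GenomicInterval, other: PeakSet) -> int:
        best = 0
        entry = other.index.get(iv.chrom)
        if entry is None:
            return 0
        starts, ends, _ = entry
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        for j in range(lo, hi):
            best = max(best, min(iv.end, int(ends[j])) - max(iv.start, int(starts[j])))
        return best

    patterns: dict[frozenset, int] = {}
    if mode == "region":
        union = PeakSet([iv for s in sets for iv in s], name="union")
        for region in union:
            members = frozenset(
                s.name for s in sets if _overlap_len(region, s) >= min_overlap_bp
            )
            patterns[members] = patterns.get(members, 0) + 1
    elif mode == "reference":
        if reference is None or reference not in names:
            raise ConfigError("mode='reference' requires a reference name among the sets")
        ref = sets[names.index(reference)]
        others = [s for s in sets if s.name != reference]
        for iv in ref:
            members = frozenset(
                [reference] + [o.name for o in others if _overlap_len(iv, o) >= min_overlap_bp]
            )
            patterns[members] = patterns.get(members, 0) + 1
    else:
        raise ConfigError(f"unknown upset mode {mode!r}")
    out = [MembershipPattern(p, c) for p, c in patterns.items()]
    out.sort(key=lambda m: (-m.count, sorted(m.pattern)))
    return out, totals


def fraction_cells_with_signal(fragments, peaks: PeakSet, cells: Iterable[str]) -> pd.DataFrame:
    """Per-peak fraction of the given cells with >=1 overlapping fragment.

    Returns a frame aligned with ``peaks`` order: chrom, start, end,
    n_cells_with_signal, fraction.
    """
    cells = set(cells)
    if not cells:
        raise ConfigError("cell set must be nonempty")
    df = as_frame(fragments)
    df = df[df["barcode"].isin(cells)]
    qi, pj = _iv.overlap_pairs(df["chrom"], df["start"].to_numpy(), df["end"].to_numpy(), peaks.index)
    n_peaks = len(peaks)
    counts = np.zeros(n_peaks, dtype=np.int64)
    if len(qi):
        pairs = pd.DataFrame({"peak": pj, "barcode": df["barcode"].to_numpy()[qi]})
        uniq = pairs.drop_duplicates()
        got = uniq.groupby("peak").size()
        counts[got.index.to_numpy()] = got.to_numpy()
    out = peaks.to_frame()[["chrom", "start", "end"]].copy()
    out["n_cells_with_signal"] = counts
    out["fraction"] = counts / len(cells)
    return out


def signal_presence_correlation(
    x: Sequence[float],
    y: Sequence[float],
    union_peaks: PeakSet | None = None,
    called_in: dict[str, np.ndarray] | None = None,
) -> dict:
    """Pearson/Spearman correlation of two per-peak signal-presence vectors.

    The vectors must be aligned on the same (union) peak set. Returns the
    coefficients plus the paired per-peak table for scatter export; when
    ``called_in`` provides per-input boolean call masks, each peak is flagged
    by which input set(s) called it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConsistencyError(f"vector length mismatch: {len(x)} vs {len(y)}")
    if union_peaks is not None and len(union_peaks) != len(x):
        raise ConsistencyError("vectors are not aligned with the union peak set")
    table = pd.DataFrame({"x": x, "y": y})
    if union_peaks is not None:
        pf = union_peaks.to_frame()[["chrom", "start", "end"]]
        table = pd.concat([pf.reset_index(drop=True), table], axis=1)
    if called_in:
        for name, mask in called_in.items():
            table[f"called_in_{name}"] = np.asarray(mask, dtype=bool)
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        pearson = spearman = None
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    return {"pearson": pearson, "spearman": spearman, "n_peaks": len(x), "table": table}
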