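"""Fragment-ratio demultiplexing of Tn5-barcode-multiplexed scATAC-seq.

When several Tn5-barcoded samples are pooled before droplet encapsulation,
free unbound Tn5 inserts can enter GEMs and prime library amplification
under the wrong sample barcode ("barcode hopping"), so most cell barcodes
appear in more than one per-sample fragments file. The fragment ratio (FR)
of a cell barcode c is

    r_c = max_s N_cs / sum_s N_cs

where N_cs is the fragment count observed for barcode c in sample s. A
barcode is assigned to its top sample when r_c strictly exceeds a threshold
(default 0.6); barcodes failing the threshold are ambiguous (this is where
cross-sample doublets land), and barcodes with too few fragments overall are
set aside as low-count. The baseline this improves on is the incidence
model, which keeps only barcodes observed in exactly one sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError
from .io import as_frame, strip_barcode_suffix

STATUS_ASSIGNED = "assigned"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_LOW_COUNT = "low_count"


@dataclass(frozen=True)
class DemuxConfig:
    """Demultiplexing parameters.

    threshold: FR above which (strictly) a barcode is assigned; (0, 1].
    min_fragments: barcodes with fewer total fragments are low-count.
    count_weighting: "fragments" counts fragment records; "reads" sums the
        support column instead (sensitivity analysis).
    strip_suffix: drop trailing "-<digits>" GEM-group suffixes before
        comparing barcodes across samples.
    """

    threshold: float = 0.6
    min_fragments: int = 100
    count_weighting: str = "fragments"
    strip_suffix: bool = True

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise ConfigError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.min_fragments < 0:
            raise ConfigError("min_fragments must be non-negative")
        if self.count_weighting not in ("fragments", "reads"):
            raise ConfigError(f"unknown count_weighting {self.count_weighting!r}")


@dataclass
class AssignmentRecord:
    """Per-barcode demultiplexing result."""

    barcode: str
    best_sample: str | None
    fragment_ratio: float
    total_fragments: int
    per_sample_counts: dict = field(repr=False, default_factory=dict)
    status: str | None = None


class CountMatrix:
    """Barcode x sample fragment-count table N_cs.

    Wraps an integer DataFrame with barcodes as the index and sample
    identifiers as (lexicographically sorted) columns; rows that are zero
    everywhere are never stored.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.astype(np.int64)
        if (counts < 0).any().any():
            raise ConfigError("fragment counts must be non-negative")
        counts = counts.loc[counts.sum(axis=1) > 0]
        if counts.columns.duplicated().any():
            raise ConfigError("duplicate sample identifiers")
        if counts.index.duplicated().any():
            raise ConfigError("duplicate barcode identifiers")
        self.counts = counts.sort_index(axis=0).sort_index(axis=1)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)


def _stripped(barcodes: pd.Series) -> pd.Series:
    """Strip GEM-group suffixes, touching the data only when suffixes exist."""
    uniq = pd.unique(barcodes)
    mapping = {b: strip_barcode_suffix(b) for b in uniq}
    if all(k == v for k, v in mapping.items()):
        return barcodes
    return barcodes.map(mapping)


def count_matrix(
    per_sample_fragments: Mapping[str, object],
    config: DemuxConfig = DemuxConfig(),
) -> CountMatrix:
    """Build N_cs from per-sample fragment collections.

    ``per_sample_fragments`` maps sample id to a fragment stream or frame.
    Barcodes absent from a sample get N_cs = 0.
    """
    samples = list(per_sample_fragments)
    if len(samples) < 2:
        raise ConfigError("demultiplexing requires at least 2 samples")
    if len(set(samples)) != len(samples):
        raise ConfigError("duplicate sample identifiers")
    pieces = []
    for sample, frags in per_sample_fragments.items():
        df = as_frame(frags)
        barcodes = _stripped(df["barcode"]) if config.strip_suffix else df["barcode"]
        if config.count_weighting == "reads":
            counts = df["support"].groupby(barcodes.to_numpy()).sum()
        else:
            counts = barcodes.value_counts()
        counts.name = sample
        counts.index = counts.index.astype(str)
        pieces.append(counts)
    table = pd.concat(pieces, axis=1).fillna(0).astype(np.int64)
    table.index.name = "barcode"
    return CountMatrix(table)


def fragment_ratio(matrix: CountMatrix) -> list[AssignmentRecord]:
    """Compute per-barcode FR and best sample (status left unset).

    Ties at the maximal count resolve to the lexicographically smallest
    sample id; tied barcodes have r <= 0.5 and are therefore ambiguous at
    any threshold above 0.5, so the tie rule affects reporting only.
    """
    if len(matrix) == 0:
        raise ConfigError("count matrix is empty")
    counts = matrix.counts
    totals = counts.sum(axis=1)
    best = counts.idxmax(axis=1)  # columns sorted, idxmax takes the first max
    ratios = counts.max(axis=1) / totals
    records = []
    values = counts.to_numpy()
    samples = matrix.samples
    for i, barcode in enumerate(counts.index):
        records.append(
            AssignmentRecord(
                barcode=barcode,
                best_sample=best.iloc[i],
                fragment_ratio=float(ratios.iloc[i]),
                total_fragments=int(totals.iloc[i]),
                per_sample_counts={s: int(v) for s, v in zip(samples, values[i])},
            )
        )
    return records


def assign(records: Iterable[AssignmentRecord], config: DemuxConfig = DemuxConfig()) -> list[AssignmentRecord]:
    """Set the status of each record under the threshold and count filter.

    The threshold is strict: r exactly equal to it is ambiguous.
    """
    out = []
    for rec in records:
        if rec.total_fragments < config.min_fragments:
            status = STATUS_LOW_COUNT
        elif rec.fragment_ratio > config.threshold:
            status = STATUS_ASSIGNED
        else:
            status = STATUS_AMBIGUOUS
        out.append(replace(rec, status=status))
    return out


class IncidenceSummary(NamedTuple):
    """Per-barcode sample multiplicity and the unique-barcode fraction."""

    multiplicity: pd.Series
    unique_fraction: float


def incidence_model(matrix: CountMatrix) -> IncidenceSummary:
    """Baseline retention: barcodes observed in exactly one sample.

    Returns each barcode's sample multiplicity (number of samples with
    N_cs > 0) and the fraction of barcodes with multiplicity exactly 1.
    """
    if len(matrix) == 0:
        raise ConfigError("count matrix is empty")
    multiplicity = (matrix.counts > 0).sum(axis=1)
    multiplicity.name = "multiplicity"
    return IncidenceSummary(multiplicity, float((multiplicity == 1).mean()))


def split_fragments(
    per_sample_fragments: Mapping[str, object],
    assignments: Iterable[AssignmentRecord],
    config: DemuxConfig = DemuxConfig(),
    merge_hopped: bool = False,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Route every input fragment to its assigned sample's output or to discard.

    For an assigned barcode, only fragments observed in the assigned
    sample's own input are emitted there; the same barcode's fragments in
    OTHER samples' files are hopping artifacts and go to the discard stream
    (``merge_hopped=True`` merges them into the assigned sample instead).
    Fragments of ambiguous and low-count barcodes are all discarded. Every
    input fragment ends up in exactly one output.
    """
    by_barcode: dict[str, AssignmentRecord] = {}
    for rec in assignments:
        if rec.status is None:
            raise ConsistencyError("assignments must have status set (run assign first)")
        by_barcode[rec.barcode] = rec
    outputs: dict[str, list[pd.DataFrame]] = {s: [] for s in per_sample_fragments}
    discards: list[pd.DataFrame] = []
    for sample, frags in per_sample_fragments.items():
        df = as_frame(frags)
        if len(df) == 0:
            continue
        keys = _stripped(df["barcode"]) if config.strip_suffix else df["barcode"]
        uniq = pd.unique(keys)
        unknown = [b for b in uniq if b not in by_barcode]
        if unknown:
            raise ConsistencyError(
                f"{len(unknown)} barcodes in sample {sample!r} missing from assignments "
                f"(e.g. {unknown[0]!r})"
            )
        dest = keys.map(
            {
                b: (by_barcode[b].best_sample if by_barcode[b].status == STATUS_ASSIGNED else None)
                for b in uniq
            }
        )
        if merge_hopped:
            keep = dest.notna()
            for target in pd.unique(dest[keep]):
                outputs[target].append(df[dest == target])
            discards.append(df[~keep])
        else:
            keep = dest == sample
            outputs[sample].append(df[keep])
            discards.append(df[~keep])
    empty = as_frame([])
    out_frames = {
        s: (pd.concat(parts, ignore_index=True) if parts else empty.copy())
        for s, parts in outputs.items()
    }
    discard = pd.concat(discards, ignore_index=True) if discards else empty.copy()
    return out_frames, discard


def demux_report(
    assignments: Iterable[AssignmentRecord],
    matrix: CountMatrix,
) -> tuple[pd.DataFrame, dict]:
    """Per-barcode assignment table plus a run summary.

    The table carries barcode, best sample, FR (6 decimals on export),
    total, status and one count column per sample. The summary reports
    status counts and fractions, the incidence-model unique fraction,
    per-sample assigned-cell counts, and per-sample FR quartiles (barcodes
    grouped by their best sample, as in post-assignment FR distributions).
    """
    records = list(assignments)
    samples = matrix.samples
    table = pd.DataFrame(
        {
            "cell_barcode": [r.barcode for r in records],
            "best_sample": [r.best_sample for r in records],
            "fragment_ratio": [r.fragment_ratio for r in records],
            "total_fragments": [r.total_fragments for r in records],
            "status": [r.status for r in records],
        }
    )
    for s in samples:
        table[f"count_{s}"] = [r.per_sample_counts.get(s, 0) for r in records]
    n = len(records)
    status_counts = table["status"].value_counts().to_dict() if n else {}
    incidence = incidence_model(matrix)
    assigned = table[table["status"] == STATUS_ASSIGNED]
    per_sample_assigned = {
        s: int((assigned["best_sample"] == s).sum()) for s in samples
    }
    fr_quartiles = {}
    for s, grp in table.groupby("best_sample"):
        q = grp["fragment_ratio"].quantile([0.25, 0.5, 0.75])
        fr_quartiles[s] = {"q25": float(q.loc[0.25]), "median": float(q.loc[0.5]), "q75": float(q.loc[0.75])}
    summary = {
        "n_barcodes": n,
        "status_counts": {k: int(status_counts.get(k, 0)) for k in (STATUS_ASSIGNED, STATUS_AMBIGUOUS, STATUS_LOW_COUNT)},
        "status_fractions": {
            k: (int(status_counts.get(k, 0)) / n if n else 0.0)
            for k in (STATUS_ASSIGNED, STATUS_AMBIGUOUS, STATUS_LOW_COUNT)
        },
        "incidence_unique_fraction": incidence.unique_fraction,
        "per_sample_assigned": per_sample_assigned,
        "fr_quartiles_by_best_sample": fr_quartiles,
    }
    return table, summary


def demultiplex(
    per_sample_fragments: Mapping[str, object],
    config: DemuxConfig = DemuxConfig(),
) -> tuple[CountMatrix, list[AssignmentRecord], pd.DataFrame, dict]:
    """Convenience pipeline: counts -> FR -> assignment -> report."""
    matrix = count_matrix(per_sample_fragments, config)
    records = assign(fragment_ratio(matrix), config)
    table, summary = demux_report(records, matrix)
    return matrix, records, table, summary
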