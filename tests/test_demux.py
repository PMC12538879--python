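"""Fragment-ratio computation, thresholding, incidence baseline, splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atacmux import (
    DemuxConfig,
    Fragment,
    assign,
    count_matrix,
    demultiplex,
    demux_report,
    fragment_ratio,
    incidence_model,
    split_fragments,
)
from atacmux.demux import CountMatrix
from atacmux.errors import ConfigError, ConsistencyError
from tests.conftest import make_frags


def matrix_from_counts(counts: dict[str, dict[str, int]]) -> CountMatrix:
    """{barcode: {sample: N_cs}} -> CountMatrix."""
    return CountMatrix(pd.DataFrame(counts).T.fillna(0))


def brute_force_assignments(raw: dict[str, list[Fragment]], threshold, min_fragments):
    """First-principles re-computation: plain loops over raw fragment lists."""
    barcodes = sorted({f.barcode for frags in raw.values() for f in frags})
    samples = sorted(raw)
    out = {}
    for bc in barcodes:
        counts = {s: sum(1 for f in raw[s] if f.barcode == bc) for s in samples}
        total = sum(counts.values())
        best = min((s for s in samples if counts[s] == max(counts.values())))
        r = counts[best] / total
        if total < min_fragments:
            status = "low_count"
        elif r > threshold:
            status = "assigned"
        else:
            status = "ambiguous"
        out[bc] = (best, r, total, status)
    return out


class TestCountMatrix:
    def test_direct_count(self):
        frags = {
            "A": make_frags(("chr1", 0, 10, "ACGT"), ("chr1", 5, 15, "ACGT")),
            "B": make_frags(("chr1", 0, 10, "ACGT")),
        }
        m = count_matrix(frags)
        assert m.counts.loc["ACGT", "A"] == 2
        assert m.counts.loc["ACGT", "B"] == 1

    def test_zero_fill_keeps_row(self):
        frags = {"A": make_frags(("chr1", 0, 10, "ACGT")), "B": []}
        m = count_matrix(frags)
        assert m.counts.loc["ACGT", "B"] == 0
        assert "ACGT" in m.barcodes

    def test_read_weighting_sums_support(self):
        frags = {
            "A": make_frags(("chr1", 0, 10, "ACGT", 3), ("chr1", 5, 15, "ACGT", 2)),
            "B": make_frags(("chr1", 0, 10, "ACGT", 1)),
        }
        m = count_matrix(frags, DemuxConfig(count_weighting="reads"))
        assert m.counts.loc["ACGT", "A"] == 5

    def test_single_sample_rejected(self):
        with pytest.raises(ConfigError, match="2 samples"):
            count_matrix({"A": make_frags(("chr1", 0, 10, "ACGT"))})

    def test_suffix_stripping_merges_barcodes_across_samples(self):
        frags = {
            "A": make_frags(("chr1", 0, 10, "ACGT-1")),
            "B": make_frags(("chr1", 0, 10, "ACGT-1")),
        }
        assert count_matrix(frags).barcodes == ["ACGT"]
        kept = count_matrix(frags, DemuxConfig(strip_suffix=False))
        assert kept.barcodes == ["ACGT-1"]


class TestFragmentRatio:
    def test_direct_evaluation(self):
        recs = fragment_ratio(matrix_from_counts({"BC": {"A": 70, "B": 30}}))
        assert recs[0].best_sample == "A"
        assert recs[0].fragment_ratio == pytest.approx(0.7)
        assert recs[0].total_fragments == 100

    def test_tie_breaks_lexicographically_and_stays_ambiguous(self):
        recs = assign(fragment_ratio(matrix_from_counts({"BC": {"B": 50, "A": 50}})),
                      DemuxConfig(min_fragments=0))
        assert recs[0].best_sample == "A"
        assert recs[0].fragment_ratio == pytest.approx(0.5)
        assert recs[0].status == "ambiguous"

    def test_single_sample_barcode_has_ratio_one(self):
        recs = fragment_ratio(matrix_from_counts({"BC": {"A": 1, "B": 0, "C": 0}}))
        assert recs[0].fragment_ratio == 1.0
        assert recs[0].best_sample == "A"

    def test_per_sample_ratios_sum_to_one(self):
        m = matrix_from_counts({"x": {"A": 3, "B": 5, "C": 1}, "y": {"A": 2, "B": 0, "C": 2}})
        for rec in fragment_ratio(m):
            ratios = np.array(list(rec.per_sample_counts.values())) / rec.total_fragments
            assert abs(ratios.sum() - 1.0) < 1e-12


class TestAssign:
    @pytest.mark.parametrize(
        "r_counts,total,min_frags,expected",
        [
            ({"A": 61, "B": 39}, 100, 0, "assigned"),     # r = 0.61 > 0.6
            ({"A": 60, "B": 40}, 100, 0, "ambiguous"),    # r = 0.6 exactly: strict
            ({"A": 950, "B": 50}, 1000, 100, "assigned"),
            ({"A": 9, "B": 1}, 10, 100, "low_count"),     # count filter wins
        ],
    )
    def test_threshold_semantics(self, r_counts, total, min_frags, expected):
        assert sum(r_counts.values()) == total
        recs = assign(
            fragment_ratio(matrix_from_counts({"BC": r_counts})),
            DemuxConfig(min_fragments=min_frags),
        )
        assert recs[0].status == expected


class TestIncidenceModel:
    def test_multiplicities(self):
        m = matrix_from_counts({"x": {"A": 5, "B": 0}, "y": {"A": 5, "B": 1}})
        inc = incidence_model(m)
        assert inc.multiplicity.loc["x"] == 1
        assert inc.multiplicity.loc["y"] == 2

    def test_unique_fraction(self):
        m = matrix_from_counts(
            {"x": {"A": 5, "B": 0}, "y": {"A": 5, "B": 1}, "z": {"A": 0, "B": 3}}
        )
        assert incidence_model(m).unique_fraction == pytest.approx(2 / 3)


class TestSplitFragments:
    def setup_method(self):
        self.frags = {
            "A": make_frags(*[("chr1", i, i + 10, "KEEP") for i in range(7)]),
            "B": make_frags(*[("chr1", i, i + 10, "KEEP") for i in range(3)]
                            + [("chr1", 50, 60, "AMBI"), ("chr1", 70, 80, "AMBI")]),
        }
        self.frags["A"] = self.frags["A"] + make_frags(
            ("chr1", 100, 110, "AMBI"), ("chr1", 120, 130, "AMBI")
        )
        cfg = DemuxConfig(min_fragments=0)
        m = count_matrix(self.frags, cfg)
        self.records = assign(fragment_ratio(m), cfg)
        self.cfg = cfg

    def test_assigned_barcode_keeps_only_its_samples_fragments(self):
        outs, discard = split_fragments(self.frags, self.records, self.cfg)
        assert len(outs["A"]) == 7  # KEEP assigned to A (7 of 10 fragments)
        assert len(outs["B"]) == 0
        # 3 hopped KEEP fragments + 4 ambiguous AMBI fragments discarded
        assert len(discard) == 7

    def test_conservation(self):
        outs, discard = split_fragments(self.frags, self.records, self.cfg)
        n_in = sum(len(v) for v in self.frags.values())
        assert sum(len(v) for v in outs.values()) + len(discard) == n_in

    def test_merge_hopped_mode_moves_fragments(self):
        outs, discard = split_fragments(self.frags, self.records, self.cfg, merge_hopped=True)
        assert len(outs["A"]) == 10  # all KEEP fragments merged into A
        assert len(discard) == 4

    def test_unknown_barcode_is_consistency_error(self):
        extra = dict(self.frags)
        extra["A"] = extra["A"] + make_frags(("chr1", 0, 5, "GHOST"))
        with pytest.raises(ConsistencyError, match="GHOST"):
            split_fragments(extra, self.records, self.cfg)

    def test_empty_inputs_give_empty_outputs(self):
        outs, discard = split_fragments({"A": [], "B": []}, [], DemuxConfig())
        assert all(len(v) == 0 for v in outs.values())
        assert len(discard) == 0


class TestDemuxReport:
    def test_summary_fractions(self):
        # 9 barcodes seen only in A (assigned, r = 1); one split 50/50 (ambiguous)
        frags = {
            "A": make_frags(*[("chr1", i, i + 5, bc) for bc in "QRSTUVWXY" for i in range(3)],
                            ("chr1", 0, 5, "Z")),
            "B": make_frags(("chr1", 0, 5, "Z")),
        }
        cfg = DemuxConfig(min_fragments=0)
        _, _, table, summary = demultiplex(frags, cfg)
        assert summary["n_barcodes"] == 10
        assert summary["status_fractions"]["assigned"] == pytest.approx(0.9)

    def test_no_hopping_limit_matches_incidence(self):
        frags = {
            "A": make_frags(("chr1", 0, 5, "AAAA"), ("chr1", 6, 11, "AAAA")),
            "B": make_frags(("chr1", 0, 5, "CCCC")),
        }
        _, _, _, summary = demultiplex(frags, DemuxConfig(min_fragments=0))
        assert summary["status_fractions"]["assigned"] == 1.0
        assert summary["incidence_unique_fraction"] == 1.0


# ---------------------------------------------------------------------------
# properties


@st.composite
def raw_fragment_universe(draw):
    n_samples = draw(st.integers(2, 4))
    samples = [f"s{i}" for i in range(n_samples)]
    barcodes = draw(st.lists(st.sampled_from(["b1", "b2", "b3", "b4", "b5"]),
                             min_size=1, max_size=5, unique=True))
    raw = {s: [] for s in samples}
    for bc in barcodes:
        for s in samples:
            k = draw(st.integers(0, 10))
            raw[s].extend(Fragment("chr1", i, i + 10, bc) for i in range(k))
    # every barcode must be observed somewhere
    for bc in barcodes:
        if not any(f.barcode == bc for frags in raw.values() for f in frags):
            raw[samples[0]].append(Fragment("chr1", 0, 10, bc))
    return raw


@settings(derandomize=True, max_examples=60, deadline=None)
@given(raw=raw_fragment_universe(), threshold=st.sampled_from([0.5, 0.6, 0.75]),
       min_fragments=st.sampled_from([0, 5]))
def test_oracle_equivalence(raw, threshold, min_fragments):
    """fragment_ratio/assign agree with an exhaustive first-principles loop."""
    cfg = DemuxConfig(threshold=threshold, min_fragments=min_fragments)
    records = assign(fragment_ratio(count_matrix(raw, cfg)), cfg)
    oracle = brute_force_assignments(raw, threshold, min_fragments)
    assert len(records) == len(oracle)
    for rec in records:
        best, r, total, status = oracle[rec.barcode]
        assert rec.best_sample == best
        assert rec.fragment_ratio == pytest.approx(r, abs=1e-12)
        assert rec.total_fragments == total
        assert rec.status == status


@settings(derandomize=True, max_examples=40, deadline=None)
@given(raw=raw_fragment_universe())
def test_threshold_monotonicity(raw):
    """Raising the threshold never increases the number of assigned barcodes."""
    m = count_matrix(raw, DemuxConfig(min_fragments=0))
    base = fragment_ratio(m)
    counts = [
        sum(r.status == "assigned" for r in assign(base, DemuxConfig(threshold=t, min_fragments=0)))
        for t in (0.3, 0.5, 0.6, 0.8, 0.95)
    ]
    assert counts == sorted(counts, reverse=True)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(raw=raw_fragment_universe())
def test_assigned_dominates_incidence_unique(raw):
    """Every multiplicity-1 barcode has r = 1 and is assigned at min_fragments=0."""
    cfg = DemuxConfig(min_fragments=0)
    m = count_matrix(raw, cfg)
    records = {r.barcode: r for r in assign(fragment_ratio(m), cfg)}
    inc = incidence_model(m)
    unique = set(inc.multiplicity[inc.multiplicity == 1].index)
    assigned = {bc for bc, r in records.items() if r.status == "assigned"}
    assert unique <= assigned
    for bc in unique:
        assert records[bc].fragment_ratio == 1.0
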