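"""Combined chemical-shift changes, peak matching, and restraint selection."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilbind.csp import (
    ActiveResidueSet,
    AssignedPeak,
    CSPRecord,
    ThresholdRule,
    classify_significant,
    combined_shift,
    export_restraints,
    match_peaks,
    select_interacting_residues,
)
from fibrilbind.synthetic import SyntheticConfig, gen_peak_tables

BRI2_PARTNER = [115, 130, 132, 139, 140, 141, 142, 143, 145, 156, 157, 158]


class TestCombinedShift:
    @pytest.mark.parametrize(
        "dh,dhet,scale,expected",
        [
            (0.0, 0.0, 2.0, 0.0),
            (0.0, 2.0, 2.0, 1.0),  # reduces to delta_het/2
            (0.03, 0.4, 2.0, 0.20223748416156685),  # sqrt(0.04 + 0.0009)
        ],
    )
    def test_values(self, dh, dhet, scale, expected):
        assert combined_shift(dh, dhet, scale) == pytest.approx(expected, abs=1e-15)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        dh=st.floats(-2, 2, allow_nan=False),
        dhet=st.floats(-10, 10, allow_nan=False),
        s=st.floats(0.1, 10),
    )
    def test_sign_symmetry_and_homogeneity(self, dh, dhet, s):
        v = combined_shift(dh, dhet)
        assert combined_shift(-dh, dhet) == v
        assert combined_shift(dh, -dhet) == v
        assert combined_shift(s * dh, s * dhet) == pytest.approx(s * v, rel=1e-12)


def _peak(idx, w1, w2, name="A", pair="C-H"):
    return AssignedPeak(idx, name, pair, w1, w2, 1.0)


class TestMatchPeaks:
    def test_identity_query_all_unique_zero_delta(self):
        ref = [_peak(i, 40.0 + i, 3.0 + 0.1 * i) for i in range(1, 6)]
        recs = match_peaks(ref, list(ref))
        assert all(r.category == "unique" for r in recs)
        assert all(r.delta_comb == 0.0 for r in recs)

    def test_generator_doubling_recovered(self):
        ref, qry = gen_peak_tables(
            perturbed_residues={28}, doubling=True, cfg=SyntheticConfig(),
            perturbation_H=0.08, perturbation_hetero=0.6,
        )
        recs = {r.residue_index: r for r in match_peaks(ref, qry)}
        assert recs[28].category == "doubled"
        assert recs[28].delta_comb == pytest.approx(
            combined_shift(0.08, 0.6), rel=1e-12
        )
        assert all(r.category == "unique" for i, r in recs.items() if i != 28)

    def test_close_reference_peaks_marked_overlapped(self):
        ref = [_peak(1, 40.00, 3.00), _peak(2, 40.05, 3.01), _peak(3, 50.0, 4.0)]
        qry = [_peak(1, 40.00, 3.00), _peak(2, 40.05, 3.01), _peak(3, 50.0, 4.0)]
        recs = {r.residue_index: r for r in match_peaks(ref, qry)}
        assert recs[1].category == "overlapped"
        assert recs[2].category == "overlapped"
        assert recs[3].category == "unique"

    def test_missing_and_ambiguous(self):
        ref = [_peak(1, 40.0, 3.0), _peak(2, 45.0, 3.5)]
        qry = [  # residue 2 absent; residue 1 has two shifted candidates
            _peak(1, 41.0, 3.2),
            _peak(1, 42.0, 3.4),
        ]
        recs = {r.residue_index: r for r in match_peaks(ref, qry)}
        assert recs[1].category == "ambiguous"
        assert recs[2].category == "missing"

    def test_duplicate_reference_rows_rejected(self):
        ref = [_peak(1, 40.0, 3.0), _peak(1, 41.0, 3.1)]
        with pytest.raises(ValueError):
            match_peaks(ref, [])

    def test_row_order_invariance(self):
        ref, qry = gen_peak_tables(
            perturbed_residues={10, 20, 30}, doubling=True, cfg=SyntheticConfig()
        )
        recs1 = match_peaks(ref, qry)
        rng = random.Random(0)
        ref2, qry2 = list(ref), list(qry)
        rng.shuffle(ref2)
        rng.shuffle(qry2)
        recs2 = match_peaks(ref2, qry2)
        assert recs1 == recs2


class TestClassifyAndSelect:
    def _records(self, deltas, category="unique"):
        return [
            CSPRecord(i + 1, d, 0.0, d, category) for i, d in enumerate(deltas)
        ]

    def test_flat_table_flags_nothing_under_mean_sd(self):
        flags = classify_significant(self._records([0.2] * 6))
        assert not any(flags.values())

    def test_outlier_flagged_by_hand_computed_rule(self):
        deltas = [0.01, 0.02, 0.01, 0.02, 0.50]
        cutoff = np.mean(deltas) + np.std(deltas)  # hand rule on the toy table
        flags = classify_significant(self._records(deltas))
        expect = {i + 1: d > cutoff for i, d in enumerate(deltas)}
        assert flags == expect
        assert flags[5] and not flags[1]

    def test_absolute_zero_threshold_flags_any_nonzero(self):
        flags = classify_significant(
            self._records([0.0, 0.001, 0.3]), ThresholdRule("absolute", 0.0)
        )
        assert flags == {1: False, 2: True, 3: True}

    def test_overlapped_and_missing_excluded(self):
        recs = self._records([0.1, 0.1]) + [
            CSPRecord(3, 9.0, 0.0, 9.0, "overlapped"),
            CSPRecord(4, 0.0, 0.0, 0.0, "missing"),
        ]
        flags = classify_significant(recs, ThresholdRule("absolute", 0.05))
        assert 3 not in flags and 4 not in flags

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            classify_significant(self._records([0.1], category="missing"))

    def test_select_empty_when_nothing_flagged(self):
        out = select_interacting_residues(
            self._records([0.1, 0.1, 0.1]), ThresholdRule("absolute", 1.0)
        )
        assert out.residues == []

    def test_doubled_residue_appears_once(self):
        recs = [
            CSPRecord(7, 0.5, 0.0, 0.5, "doubled"),
            CSPRecord(7, 0.4, 0.0, 0.4, "unique"),
            CSPRecord(8, 0.01, 0.0, 0.01, "unique"),
        ]
        out = select_interacting_residues(recs, ThresholdRule("absolute", 0.1))
        assert out.residues == [7]

    def test_ambiguous_excluded_on_request(self):
        recs = [
            CSPRecord(5, 0.5, 0.0, 0.5, "ambiguous"),
            CSPRecord(6, 0.5, 0.0, 0.5, "unique"),
            CSPRecord(7, 0.01, 0.0, 0.01, "unique"),
        ]
        incl = select_interacting_residues(recs, ThresholdRule("absolute", 0.1), True)
        excl = select_interacting_residues(recs, ThresholdRule("absolute", 0.1), False)
        assert incl.residues == [5, 6]
        assert excl.residues == [6]


class TestExportRestraints:
    def _sets(self, fibril, partner=BRI2_PARTNER):
        return (
            ActiveResidueSet(fibril, 0.0, "test"),
            ActiveResidueSet(partner, 0.0, "test"),
        )

    def test_fibril_rows_replicated_across_subunits(self):
        f, p = self._sets([27, 28])
        rows = export_restraints(f, p, n_subunits=3)
        fibril_rows = [r for r in rows if r["molecule"] == "fibril"]
        assert len(fibril_rows) == 6
        assert sorted({r["chain"] for r in fibril_rows}) == ["A", "B", "C"]

    def test_partner_list_size(self):
        # the chaperone's predicted client-contact residues: 12 positions
        f, p = self._sets([27])
        rows = export_restraints(f, p, n_subunits=1)
        assert len([r for r in rows if r["molecule"] == "partner"]) == 12

    def test_single_subunit_row_count(self):
        f, p = self._sets([27, 28, 30])
        rows = export_restraints(f, p, n_subunits=1)
        assert len([r for r in rows if r["molecule"] == "fibril"]) == 3

    def test_empty_side_rejected(self):
        f, p = self._sets([27])
        with pytest.raises(ValueError):
            export_restraints(ActiveResidueSet([], 0.0, ""), p)
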