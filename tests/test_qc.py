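"""Four-rule marker selection: examples, idempotence, rule exactness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scafqtl import qc
from scafqtl.types import NUCLEOTIDES, ScaffoldIndex


class TestPanelStats:
    def test_panel_frequency_is_mean_over_called(self):
        df = pd.DataFrame(
            [
                {"marker_id": "s_1", "scaffold": "s", "position": 1, "accession": "x",
                 "A": 0.5, "C": 0.5, "G": 0, "T": 0},
                {"marker_id": "s_1", "scaffold": "s", "position": 1, "accession": "y",
                 "A": 1.0, "C": 0.0, "G": 0, "T": 0},
            ]
        )
        stats = qc.panel_allele_stats(df)
        assert stats.loc["s_1", "A"] == pytest.approx(0.75)

    def test_call_rate_counts_missing_accessions(self):
        rows = [
            {"marker_id": "s_1", "scaffold": "s", "position": 1, "accession": a,
             "A": 0.6, "C": 0.4, "G": 0, "T": 0}
            for a in ("w", "x", "y")
        ]
        stats = qc.panel_allele_stats(pd.DataFrame(rows), n_accessions=4)
        assert stats.loc["s_1", "call_rate"] == pytest.approx(0.75)

    def test_three_accession_toy_matches_hand_computation(self):
        rows = [
            {"marker_id": "m", "scaffold": "s", "position": 1, "accession": "x",
             "A": 0.2, "C": 0.3, "G": 0.5, "T": 0.0},
            {"marker_id": "m", "scaffold": "s", "position": 1, "accession": "y",
             "A": 0.1, "C": 0.6, "G": 0.3, "T": 0.0},
            {"marker_id": "m", "scaffold": "s", "position": 1, "accession": "z",
             "A": 0.0, "C": 0.9, "G": 0.0, "T": 0.1},
        ]
        stats = qc.panel_allele_stats(pd.DataFrame(rows))
        assert stats.loc["m", "A"] == pytest.approx(0.1)
        assert stats.loc["m", "C"] == pytest.approx(0.6)
        assert stats.loc["m", "G"] == pytest.approx(0.8 / 3)
        assert stats.loc["m", "T"] == pytest.approx(0.1 / 3)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            qc.panel_allele_stats(pd.DataFrame(columns=["marker_id", "accession", *NUCLEOTIDES]))


class TestSelectMarkers:
    def test_rules_and_first_violation_reported(self, toy_freq_table):
        result = qc.select_markers(toy_freq_table)
        rej = result.rejections.set_index("marker_id")["rule"]
        assert rej["s1_20"] == "maf"  # panel major frequency 0.993 > 0.98
        assert rej["s2_5"] == "biallelic"  # top-two sum 0.9 < 0.95
        assert rej["s2_9"] == "sd"  # SD of major frequency is 0
        assert result.panel.markers == ["s1_10"]

    def test_scores_are_major_allele_frequencies(self, toy_freq_table):
        result = qc.select_markers(toy_freq_table)
        # panel major allele of s1_10 is A (0.533 vs C 0.467)
        assert result.panel.meta.at["s1_10", "major_allele"] == "A"
        assert result.panel.scores.loc["x", "s1_10"] == pytest.approx(0.9)
        assert result.panel.scores.loc["z", "s1_10"] == pytest.approx(0.2)

    def test_call_rate_rule_applied_first(self, toy_freq_table):
        dropped = toy_freq_table[
            ~((toy_freq_table.marker_id == "s2_5") & (toy_freq_table.accession == "z"))
        ]
        result = qc.select_markers(dropped, n_accessions=3)
        rej = result.rejections.set_index("marker_id")["rule"]
        assert rej["s2_5"] == "call_rate"

    def test_idempotence_on_simulated_panel(self, small_panel):
        panel, _, _ = small_panel
        freq = qc.scores_to_frequency_table(panel)
        first = qc.select_markers(freq)
        freq2 = qc.scores_to_frequency_table(first.panel)
        second = qc.select_markers(freq2)
        assert second.panel.markers == first.panel.markers
        pd.testing.assert_frame_equal(second.panel.scores, first.panel.scores)
        assert second.rejections.empty

    def test_empty_survivor_set_returns_empty_matrix(self, toy_freq_table):
        strict = qc.QCThresholds(sd_min=1.0)  # nothing can pass
        result = qc.select_markers(toy_freq_table, strict)
        assert result.n_selected == 0


@st.composite
def frequency_tables(draw):
    """Random small frequency tables exercising every rule boundary."""
    n_acc = draw(st.integers(min_value=3, max_value=6))
    n_mark = draw(st.integers(min_value=1, max_value=8))
    rng = np.random.default_rng(draw(st.integers(min_value=0, max_value=2**31 - 1)))
    rows = []
    for j in range(n_mark):
        kind = rng.integers(0, 4)
        for i in range(n_acc):
            if kind == 0:  # common biallelic with variation
                a = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9])
                f = [a, 1 - a, 0.0, 0.0]
            elif kind == 1:  # near fixed
                a = rng.choice([0.99, 1.0])
                f = [a, 1 - a, 0.0, 0.0]
            elif kind == 2:  # tri-allelic
                f = [0.5, 0.35, 0.15, 0.0]
            else:  # no variation
                f = [0.6, 0.4, 0.0, 0.0]
            rows.append({"marker_id": f"s_{j}", "scaffold": "s", "position": j + 1,
                         "accession": f"a{i}", "A": f[0], "C": f[1], "G": f[2], "T": f[3]})
    return pd.DataFrame(rows)


class TestRuleExactness:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(frequency_tables())
    def test_survivors_pass_and_rejects_fail_on_recheck(self, table):
        n_acc = table["accession"].nunique()
        result = qc.select_markers(table)
        rej = result.rejections.set_index("marker_id")["rule"]
        for mid, rows in table.groupby("marker_id"):
            expected = qc.check_marker(rows, n_acc)
            if mid in result.panel.markers:
                assert expected == ""
            else:
                assert rej[mid] == expected


class TestSummary:
    def test_coverage_arithmetic(self):
        meta = pd.DataFrame(
            {"marker_id": ["a_1", "a_2", "b_1"], "scaffold": ["a", "a", "b"],
             "position": [1, 2, 1], "major_allele": ["A"] * 3, "minor_allele": ["C"] * 3}
        ).set_index("marker_id")
        scores = pd.DataFrame(np.full((2, 3), 0.5), index=["x", "y"], columns=meta.index)
        from scafqtl.types import MarkerPanel

        result = qc.QCResult(panel=MarkerPanel(scores, meta), rejections=pd.DataFrame(columns=["marker_id", "rule"]))
        index = ScaffoldIndex(pd.Series([100, 200], index=["a", "b"]))
        summary = qc.qc_summary(result, index, genome_size_bp=1000)
        assert summary["n_scaffolds"] == 2
        assert summary["covered_length_bp"] == 300
        assert summary["genome_fraction"] == pytest.approx(0.3)

    def test_unplaced_scaffold_excluded_from_length(self):
        meta = pd.DataFrame(
            {"marker_id": ["a_1", "c_1"], "scaffold": ["a", "c"], "position": [1, 1],
             "major_allele": ["A"] * 2, "minor_allele": ["C"] * 2}
        ).set_index("marker_id")
        scores = pd.DataFrame(np.full((2, 2), 0.5), index=["x", "y"], columns=meta.index)
        from scafqtl.types import MarkerPanel

        result = qc.QCResult(panel=MarkerPanel(scores, meta), rejections=pd.DataFrame(columns=["marker_id", "rule"]))
        index = ScaffoldIndex(pd.Series([100], index=["a"]))
        summary = qc.qc_summary(result, index)
        assert summary["covered_length_bp"] == 100
        assert summary["unplaced_scaffolds"] == ["c"]

    def test_zero_selected_markers(self):
        from scafqtl.types import MarkerPanel

        empty = qc.QCResult(
            panel=MarkerPanel(pd.DataFrame(index=["x"]), pd.DataFrame(columns=qc.META_COLUMNS[1:])),
            rejections=pd.DataFrame(columns=["marker_id", "rule"]),
        )
        summary = qc.qc_summary(empty)
        assert summary["n_selected"] == 0 and summary["n_scaffolds"] == 0
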