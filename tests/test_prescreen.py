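"""Short-read AS-APA prescreen: dPAU calls, CE filter, Fisher association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from utrlink.prescreen import (
    LENGTHENING,
    SHORTENING,
    UNCHANGED,
    call_lengthening,
    call_regulated_ce,
    candidate_genes,
    dpau_from_pau,
    dpau_table,
    fisher_exact_2x2,
)


def pau_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "apa_id", "utr_length", "utr_end", "PAU_s1", "TPM_s1"]
    )


class TestDpauFromPau:
    def test_longest_isoform_rule(self):
        rows = pau_frame(
            [("g", "g_P", 300, 1300, 70.0, 5.0), ("g", "g_D", 1200, 2200, 30.0, 5.0)]
        )
        assert dpau_from_pau(rows, "s1") == 30.0

    def test_unexpressed_gene_excluded(self):
        rows = pau_frame(
            [("g", "g_P", 300, 1300, 70.0, 0.0), ("g", "g_D", 1200, 2200, 30.0, 0.0)]
        )
        with pytest.raises(ValueError, match="not expressed"):
            dpau_from_pau(rows, "s1")

    def test_single_isoform_excluded(self):
        rows = pau_frame([("g", "g_P", 300, 1300, 100.0, 5.0)])
        with pytest.raises(ValueError, match="single-isoform"):
            dpau_from_pau(rows, "s1")

    def test_length_tie_broken_by_three_prime_coordinate(self):
        rows = pau_frame(
            [("g", "g_A", 1200, 1900, 55.0, 5.0), ("g", "g_B", 1200, 2200, 45.0, 5.0)]
        )
        assert dpau_from_pau(rows, "s1") == 45.0  # 3'-most end wins the tie


class TestCallLengthening:
    def dpau(self):
        # planted: g_len lengthens (20 -> 60), g_short shortens (60 -> 20),
        # g_fc lacks fold change, g_ns lacks significance
        return pd.DataFrame(
            {
                "gene_id": ["g_len", "g_short", "g_fc", "g_ns"],
                "a1": [20.0, 60.0, 40.0, 30.0],
                "a2": [22.0, 62.0, 41.0, 50.0],
                "a3": [18.0, 58.0, 39.0, 20.0],
                "b1": [60.0, 20.0, 50.0, 45.0],
                "b2": [62.0, 22.0, 51.0, 65.0],
                "b3": [58.0, 18.0, 49.0, 35.0],
            }
        )

    def test_planted_calls_match_rules(self):
        out = call_lengthening(self.dpau(), ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        calls = dict(zip(out["gene_id"], out["call"]))
        assert calls == {
            "g_len": LENGTHENING,     # FC = 3 > 2, significant
            "g_short": SHORTENING,    # FC = 1/3 < 0.5, significant
            "g_fc": UNCHANGED,        # FC = 1.25, inside (0.5, 2)
            "g_ns": UNCHANGED,        # FC = 1.45 and noisy
        }

    def test_zero_baseline_flagged_not_pseudocounted(self):
        d = pd.DataFrame(
            {"gene_id": ["g"], "a1": [0.0], "a2": [0.0], "b1": [50.0], "b2": [55.0]}
        )
        out = call_lengthening(d, ["a1", "a2"], ["b1", "b2"])
        assert np.isnan(out["fc"].iloc[0])
        assert out["call"].iloc[0] == UNCHANGED

    def test_threshold_monotone(self):
        # relaxing the FC threshold never removes a called gene
        strict = call_lengthening(self.dpau(), ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                                  fc_threshold=2.5)
        loose = call_lengthening(self.dpau(), ["a1", "a2", "a3"], ["b1", "b2", "b3"],
                                 fc_threshold=1.5)
        called_strict = set(strict.loc[strict["call"] != UNCHANGED, "gene_id"])
        called_loose = set(loose.loc[loose["call"] != UNCHANGED, "gene_id"])
        assert called_strict <= called_loose


class TestCallRegulatedCe:
    EVENTS = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "event_type": ["CE", "CE", "CE", "MXE", "CE"],
            "inc_level_diff": [0.25, 0.25, -0.21, 0.5, 0.15],
            "fdr": [0.01, 0.06, 0.04, 0.01, 0.01],
        }
    )

    def test_joint_threshold_filter(self):
        out = call_regulated_ce(self.EVENTS)
        assert set(out["gene_id"]) == {"g1", "g3"}  # g2 FDR, g4 type, g5 dPSI
        assert dict(zip(out["gene_id"], out["direction"])) == {
            "g1": "inclusion", "g3": "skipping",
        }

    def test_threshold_monotone(self):
        strict = set(call_regulated_ce(self.EVENTS, 0.05, 0.2)["gene_id"])
        loose = set(call_regulated_ce(self.EVENTS, 0.10, 0.1)["gene_id"])
        assert strict <= loose


def fisher_oracle(table):
    """Full enumeration over all 2x2 tables with the observed margins."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = hypergeom(n, c1, r1)
    p_obs = rv.pmf(a)
    return float(
        sum(rv.pmf(k) for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if rv.pmf(k) <= p_obs * (1 + 1e-9))
    )


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[5, 5], [5, 5]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),
            ([[10, 0], [0, 10]], 2 / 184756),
        ],
    )
    def test_exact_values(self, table, expected):
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_degenerate_margin_p_one(self):
        _, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            _, p = fisher_exact_2x2(table)
            assert p == 1.0
            return
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_oracle(table), rel=1e-7)


class TestCandidateGenes:
    def test_set_arithmetic_and_table(self):
        res = candidate_genes(
            {"g1", "g2"}, {"g2", "g3"}, {f"g{i}" for i in range(1, 11)}
        )
        assert res.candidates == ("g2",)
        assert res.table == ((1, 1), (1, 7))

    def test_disjoint_sets(self):
        res = candidate_genes({"g1"}, {"g2"}, {"g1", "g2", "g3"})
        assert res.candidates == ()
        assert 0 <= res.p <= 1

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            candidate_genes({"gX"}, set(), {"g1"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            candidate_genes(set(), set(), set())


def test_dpau_table_filters_and_values():
    pau = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2", "g3", "g3"],
            "apa_id": ["g1_P", "g1_D", "g2_P", "g3_P", "g3_D"],
            "utr_length": [300, 1200, 500, 200, 900],
            "utr_end": [1300, 2200, 1500, 1200, 1900],
            "PAU_s1": [70.0, 30.0, 100.0, 80.0, 20.0],
            "TPM_s1": [5.0, 5.0, 3.0, 0.0, 0.0],
            "PAU_s2": [60.0, 40.0, 100.0, 75.0, 25.0],
            "TPM_s2": [4.0, 4.0, 2.0, 1.0, 1.0],
        }
    )
    out = dpau_table(pau, ["s1", "s2"])
    # g2 single-isoform, g3 unexpressed in s1 -> only g1 kept
    assert list(out["gene_id"]) == ["g1"]
    assert out.iloc[0]["s1"] == 30.0 and out.iloc[0]["s2"] == 40.0
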