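"""Fold statistic, rowwise tests, FDR, representative calls, Venn logic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tspsr.diffexp import (
    AnalysisParams,
    Comparison,
    Direction,
    VennCell,
    TranscriptCall,
    TranscriptDECall,
    adjust_fdr,
    background_filter,
    call_de,
    compare_groups,
    direction_concordance,
    median_fold_difference,
    row_ttest,
    select_representative,
    summarize_gene_level,
    venn_categorize,
    venn_cell,
)

from conftest import make_study


def _matrix(rows, columns, values):
    return pd.DataFrame(values, index=rows, columns=columns, dtype=float)


A3 = ["a1", "a2", "a3"]
B3 = ["b1", "b2", "b3"]


class TestRowTtest:
    def test_closed_form_pooled_t(self):
        """t = (mean_a - mean_b) / (s_p * sqrt(1/nA + 1/nB)), df = nA+nB-2."""
        m = _matrix(["r"], A3 + B3, [[1, 2, 3, 4, 5, 6]])
        out = row_ttest(m, A3, B3)
        # hand computation: means 2 and 5, pooled variance 1, se = sqrt(2/3)
        t_hand = (2 - 5) / math.sqrt(2 / 3)
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert out.loc["r", "t"] == pytest.approx(t_hand)  # == -3.674
        assert out.loc["r", "p"] == pytest.approx(p_hand)  # == 0.0213
        assert out.loc["r", "t"] == pytest.approx(-3.674, abs=5e-4)
        assert out.loc["r", "p"] == pytest.approx(0.021, abs=5e-4)

    def test_identical_groups_and_zero_variance(self):
        m = _matrix(["r1", "r2"], A3 + B3, [[1, 2, 3, 1, 2, 3], [5, 5, 5, 5, 5, 5]])
        with pytest.warns(UserWarning, match="zero pooled variance"):
            out = row_ttest(m, A3, B3)
        assert out.loc["r1", "t"] == 0 and out.loc["r1", "p"] == 1
        assert out.loc["r2", "t"] == 0 and out.loc["r2", "p"] == 1

    def test_null_pvalues_uniform(self):
        """10^4 null rows: p-values consistent with U(0,1) by the KS test."""
        rng = np.random.default_rng(2024)
        m = pd.DataFrame(rng.normal(size=(10_000, 12)),
                         columns=[f"s{i}" for i in range(12)])
        out = row_ttest(m, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)])
        ks_p = stats.kstest(out["p"], "uniform").pvalue
        assert ks_p > 0.01


class TestFdr:
    def test_single_p_unchanged(self):
        assert adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_hand_computed_bh(self):
        # step-up: q_(i) = min_{j>=i} p_(j) * m / j -> all 0.04 here
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        # a second hand case with a non-trivial profile
        np.testing.assert_allclose(
            adjust_fdr([0.005, 0.04, 0.03, 0.9]),
            [0.02, 0.04 * 4 / 3, 0.04 * 4 / 3, 0.9],
            rtol=1e-9,
        )

    def test_bh_properties(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = adjust_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(200)
        np.testing.assert_allclose(adjust_fdr(p[perm]), q[perm])


class TestMfd:
    def test_identity_and_brute_force(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(7, 1, size=(5, 6)), columns=A3 + B3)
        mfd = median_fold_difference(m, A3, B3)
        brute = 2 ** (m[B3].median(axis=1) - m[A3].median(axis=1))
        np.testing.assert_allclose(mfd, brute)
        same = median_fold_difference(m, A3, A3)
        np.testing.assert_allclose(same, 1.0)

    def test_chain_closure_to_machine_precision(self):
        """mfd(N->P) * mfd(P->M) == mfd(N->M): ratio-of-medians identity."""
        rng = np.random.default_rng(4)
        cols_n = [f"n{i}" for i in range(5)]
        cols_p = [f"p{i}" for i in range(7)]
        cols_m = [f"m{i}" for i in range(5)]
        m = pd.DataFrame(rng.normal(7, 1.5, size=(50, 17)), columns=cols_n + cols_p + cols_m)
        np_ = median_fold_difference(m, cols_n, cols_p)
        pm = median_fold_difference(m, cols_p, cols_m)
        nm = median_fold_difference(m, cols_n, cols_m)
        np.testing.assert_allclose(np_ * pm, nm, rtol=1e-12)


class TestMfdProperties:
    """Structural invariants of the fold statistic on arbitrary log2 data."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.lists(st.floats(2.0, 14.0), min_size=9, max_size=9),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_closure_and_inversion(self, values):
        cols = [f"s{i}" for i in range(9)]
        m = pd.DataFrame(values, columns=cols, dtype=float)
        a, b, c = cols[:3], cols[3:6], cols[6:]
        ab = median_fold_difference(m, a, b)
        bc = median_fold_difference(m, b, c)
        ac = median_fold_difference(m, a, c)
        np.testing.assert_allclose(ab * bc, ac, rtol=1e-9)
        # reversing the contrast inverts the ratio
        np.testing.assert_allclose(
            median_fold_difference(m, b, a), 1.0 / ab, rtol=1e-9
        )
        assert (ab > 0).all()


class TestBackgroundFilter:
    def _study(self, rows):
        groups = {"a1": "NORMAL", "a2": "NORMAL", "b1": "PRIMARY", "b2": "PRIMARY",
                  "c1": "METASTASIS", "c2": "METASTASIS"}
        m = _matrix(list(rows), list(groups), list(rows.values()))
        return make_study(m, groups, background=5.0)

    def test_removed_only_if_below_in_all_groups(self):
        rows = {
            "below_all": [4, 4, 3, 3, 4.5, 4.5],     # bg-1, bg-2, bg-0.5 -> removed
            "above_primary": [4, 4, 6, 6, 4, 4],      # kept
            "above_all": [6, 6, 7, 7, 8, 8],          # kept
        }
        study = self._study(rows)
        out = background_filter(study, list(rows), AnalysisParams(background_level=5.0))
        assert out == ["above_primary", "above_all"]

    def test_identity_when_everything_expressed(self):
        rows = {"r1": [6] * 6, "r2": [7] * 6}
        study = self._study(rows)
        assert background_filter(study, list(rows), AnalysisParams(background_level=5.0)) == ["r1", "r2"]


class TestCallDe:
    @pytest.mark.parametrize(
        "q,mfd,de,direction",
        [
            (0.01, 1.35, True, Direction.UP),
            (0.01, 0.42, True, Direction.DOWN),
            (0.01, 1.1, False, Direction.NONE),
            (0.01, 0.9, False, Direction.NONE),   # 0.9 > 1/1.2
            (0.2, 2.0, False, Direction.NONE),
            (0.01, 1.2, True, Direction.UP),      # boundary inclusive
            (0.01, 1 / 1.2, True, Direction.DOWN),
        ],
    )
    def test_threshold_rule(self, q, mfd, de, direction):
        table = pd.DataFrame({"t": [1.0], "p": [q], "q": [q], "mfd": [mfd]}, index=["x"])
        out = call_de(table, AnalysisParams())
        assert bool(out.loc["x", "de"]) is de
        assert out.loc["x", "direction"] == direction.value

    def test_de_set_shrinks_with_stricter_thresholds(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(
            {
                "t": rng.normal(size=300),
                "p": rng.uniform(size=300),
                "q": rng.uniform(size=300),
                "mfd": 2 ** rng.normal(0, 0.5, size=300),
            }
        )
        loose = call_de(table, AnalysisParams(fdr_threshold=0.2, mfd_threshold=1.1))
        strict = call_de(table, AnalysisParams(fdr_threshold=0.05, mfd_threshold=1.4))
        assert set(strict.index[strict["de"]]) <= set(loose.index[loose["de"]])


def _call(tx, de, mfd=1.5, p=0.01, psr="x"):
    return TranscriptCall(
        transcript_id=tx, psr_id=psr, t=0.0, p=p, q=p, mfd=mfd, de=de,
        direction=Direction.UP if de and mfd > 1 else (Direction.DOWN if de else Direction.NONE),
    )


class TestRepresentative:
    def _result(self, rows):
        table = pd.DataFrame(rows).set_index("psr_id")
        from tspsr.diffexp import ComparisonResult
        return ComparisonResult(Comparison.NvsM, table, AnalysisParams())

    def test_lowest_p_significant_wins(self):
        res = self._result(
            [
                {"psr_id": "p1", "t": 2, "p": 0.01, "q": 0.01, "mfd": 1.5, "de": True, "direction": "UP"},
                {"psr_id": "p2", "t": 3, "p": 0.001, "q": 0.001, "mfd": 1.4, "de": True, "direction": "UP"},
                {"psr_id": "p3", "t": 0.1, "p": 0.9, "q": 0.9, "mfd": 1.0, "de": False, "direction": "NONE"},
            ]
        )
        calls = select_representative(res, {"p1": "T1", "p2": "T1", "p3": "T2"})
        assert calls["T1"].psr_id == "p2" and calls["T1"].de
        # no significant PSR: lowest-p reported, flagged not DE
        assert calls["T2"].psr_id == "p3" and not calls["T2"].de

    def test_tie_break_larger_fold_then_id(self):
        res = self._result(
            [
                {"psr_id": "pa", "t": 2, "p": 0.01, "q": 0.01, "mfd": 1.3, "de": True, "direction": "UP"},
                {"psr_id": "pb", "t": 2, "p": 0.01, "q": 0.01, "mfd": 0.5, "de": True, "direction": "DOWN"},
                {"psr_id": "pc", "t": 2, "p": 0.01, "q": 0.01, "mfd": 2.0, "de": True, "direction": "UP"},
            ]
        )
        calls = select_representative(res, {k: "T" for k in ("pa", "pb", "pc")})
        # |log2 0.5| == |log2 2.0| -> id breaks the tie between pb and pc
        assert calls["T"].psr_id == "pb"


class TestVenn:
    def test_cell_mapping_patterns(self):
        # TGM4-001-like: DOWN everywhere -> all three
        assert venn_cell(True, True, True) is VennCell.ALL_THREE
        # NAMPT-006-like: up then down, absent in N vs M -> the primary pair
        assert venn_cell(True, True, False) is VennCell.NvsP_PvsM
        assert venn_cell(False, False, False) is VennCell.NONE

    def test_categorize_and_counts(self):
        nvsp = {"T1": _call("T1", True, 0.68), "T2": _call("T2", True, 1.34), "T3": _call("T3", False)}
        pvsm = {"T1": _call("T1", True, 0.62), "T2": _call("T2", True, 0.73), "T3": _call("T3", False)}
        nvsm = {"T1": _call("T1", True, 0.42), "T2": _call("T2", False), "T3": _call("T3", False)}
        calls, counts = venn_categorize(nvsp, pvsm, nvsm, {"T1": "G1", "T2": "G2", "T3": "G3"})
        by_tx = {c.transcript_id: c.continuum_category for c in calls}
        assert by_tx == {
            "T1": VennCell.ALL_THREE,
            "T2": VennCell.NvsP_PvsM,
            "T3": VennCell.NONE,
        }
        assert counts["all_three"] == 1 and counts["NvsP_PvsM"] == 1
        assert sum(counts.values()) == 2  # never-DE transcripts not counted

    def test_universe_mismatch_rejected(self):
        nvsp = {"T1": _call("T1", True)}
        with pytest.raises(ValueError, match="universe"):
            venn_categorize(nvsp, {}, {}, {})


class TestConcordance:
    def _decall(self, tx, gene, directions):
        per = {}
        for comp, d in zip(Comparison, directions):
            de = d is not Direction.NONE
            per[comp] = TranscriptCall(
                transcript_id=tx, psr_id="x", t=0, p=0.01, q=0.01,
                mfd=1.5 if d is Direction.UP else (0.5 if d is Direction.DOWN else 1.0),
                de=de, direction=d,
            )
        cell = venn_cell(*(per[c].de for c in Comparison))
        return TranscriptDECall(tx, gene, per, cell)

    def test_discordant_siblings_flagged(self):
        # AGR2-like: one sibling DOWN, the other UP in the P vs M contrast
        a = self._decall("A-001", "AGR2L", [Direction.NONE, Direction.DOWN, Direction.NONE])
        b = self._decall("A-007", "AGR2L", [Direction.NONE, Direction.UP, Direction.NONE])
        (g,) = direction_concordance([a, b])
        assert not g.concordant
        assert g.discordant_pairs == [("A-001", "A-007", Comparison.PvsM)]

    def test_concordant_gene_and_singleton_excluded(self):
        # FGFR2-like: both siblings DOWN everywhere
        a = self._decall("F-008", "FGFR2L", [Direction.DOWN, Direction.DOWN, Direction.DOWN])
        b = self._decall("F-016", "FGFR2L", [Direction.DOWN, Direction.DOWN, Direction.DOWN])
        c = self._decall("K-001", "KCNMB1L", [Direction.UP, Direction.NONE, Direction.NONE])
        out = direction_concordance([a, b, c])
        assert [g.gene_id for g in out] == ["FGFR2L"]
        assert out[0].concordant


class TestGeneSummarization:
    def test_median_collapse(self):
        m = _matrix(["p1", "p2", "p3", "q1"], ["s1", "s2"], [[1, 2], [2, 3], [9, 4], [5, 5]])
        gm = summarize_gene_level(m, {"p1": "G", "p2": "G", "p3": "G", "q1": "H"})
        assert gm.loc["G", "s1"] == 2 and gm.loc["G", "s2"] == 3
        # a single-PSR gene passes through unchanged
        assert gm.loc["H"].tolist() == [5, 5]

    def test_transcript_signal_lost_at_gene_level(self):
        """One transcript shifted, sibling flat: DE at transcript resolution,
        not after consensus-gene summarization."""
        rng = np.random.default_rng(12)
        cols_n = [f"n{i}" for i in range(10)]
        cols_m = [f"m{i}" for i in range(10)]
        groups = {c: "NORMAL" for c in cols_n} | {c: "METASTASIS" for c in cols_m}
        base = rng.normal(7, 0.2, size=(3, 20))
        base[0, 10:] += 1.0  # PSR of transcript T_up shifted in metastasis
        m = pd.DataFrame(base, index=["psr_up", "psr_flat1", "psr_flat2"], columns=cols_n + cols_m)
        params = AnalysisParams(background_level=0.0)
        study = make_study(m, groups)
        res = compare_groups(study, list(m.index), Comparison.NvsM, params)
        assert bool(res.table.loc["psr_up", "de"])
        gene_m = summarize_gene_level(m, {p: "G" for p in m.index})
        gene_study = make_study(gene_m, groups)
        gene_res = compare_groups(gene_study, ["G"], Comparison.NvsM, params)
        assert not bool(gene_res.table.loc["G", "de"])
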