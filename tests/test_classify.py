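"""Tests for OSG classification, threshold pairing, calibration,
overlap counting and top-gene selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from organspec import (
    CalibrationError,
    OSGCall,
    ThresholdSet,
    calibrate_thresholds,
    call_osg,
    overlap_matrix,
    pair_thresholds,
    score_matrix,
    threshold_table,
    top_genes_per_organ,
)
from organspec.classify import read_calls, write_calls
from organspec.errors import OrganSpecError
from organspec.matrix import CountMatrix


def score_row(gene, organ, AE=12, RE=6.0, RZ=5.0, pvalue=1e-6, EE=2.0, AZ=8.0):
    return {
        "gene": gene, "organ": organ, "AE": AE, "EE": EE, "RE": RE,
        "AZ": AZ, "RZ": RZ, "pvalue": pvalue,
    }


class TestCallOsg:
    def test_all_four_criteria_must_hold(self):
        scores = pd.DataFrame(
            [
                score_row("g1", "liver"),                     # qualifies
                score_row("g2", "liver", AE=9),               # AE below 10
                score_row("g3", "liver", RE=3.9),             # RE below 4
                score_row("g4", "liver", RZ=3.9),             # RZ below 4
                score_row("g5", "liver", pvalue=2e-5),        # p above 1e-5
            ]
        )
        calls = call_osg(scores, ThresholdSet())
        assert [c.gene for c in calls] == ["g1"]

    def test_boundary_values_qualify(self):
        scores = pd.DataFrame([score_row("g", "liver", AE=10, RE=4.0, RZ=4.0, pvalue=1e-5)])
        assert len(call_osg(scores, ThresholdSet())) == 1

    def test_class_by_organ_count(self):
        scores = pd.DataFrame(
            [
                score_row("gAbs", "liver"),
                score_row("gRel", "liver"),
                score_row("gRel", "spleen"),
            ]
        )
        calls = {c.gene: c for c in call_osg(scores, ThresholdSet())}
        assert calls["gAbs"].cls == "absolute"
        assert calls["gRel"].cls == "relative"
        assert calls["gRel"].organs == frozenset({"liver", "spleen"})
        assert OSGCall("gNone").cls == "none"


class TestPairThresholds:
    def test_reference_ladder(self):
        assert pair_thresholds([2, 3, 4, 5, 6]) == [
            (1e-2, 2.0), (1e-3, 3.0), (1e-5, 4.0), (1e-7, 5.0), (1e-10, 6.0),
        ]

    def test_single_z_four(self):
        # normal tail at z=4 is 3.17e-5, which floors to 1e-5
        assert pair_thresholds([4]) == [(1e-5, 4.0)]

    def test_z_zero_floors_to_tenth(self):
        # tail is 0.5, floor of log10 is -1
        assert pair_thresholds([0]) == [(1e-1, 0.0)]

    def test_non_finite_rejected(self):
        with pytest.raises(OrganSpecError):
            pair_thresholds([float("nan")])


class TestThresholdTable:
    def test_counts_decompose_and_nest(self, calib_scores):
        pairs = pair_thresholds([2, 3, 4, 5, 6])
        table = threshold_table(calib_scores, pairs, min_RE=4.0, min_AE=10)
        assert (table["n_OSG"] == table["n_A_OSG"] + table["n_R_OSG"]).all()
        assert (table["n_OSG"].diff().dropna() <= 0).all()
        assert (table["n_R_OSG"].diff().dropna() <= 0).all()

    def test_empty_qualifying_set_is_zero_row(self):
        scores = pd.DataFrame([score_row("g", "liver", pvalue=0.9, RZ=0.0, RE=1.0, AE=1)])
        table = threshold_table(scores, [(1e-5, 4.0)], 4.0, 10)
        row = table.iloc[0]
        assert (row[["n_OSG", "n_R_OSG", "n_A_OSG", "pct_A_OSG"]] == 0).all()

    def test_planted_single_organ_genes_all_recovered_at_strict_pair(self):
        # 5 genes, each massively enriched in its own organ of a
        # 52-organ null background: at the strictest pair all five are
        # absolute OSGs and nothing else qualifies
        rng = np.random.default_rng(7)
        organs = [f"o{j:02d}" for j in range(52)]
        base = rng.poisson(20, size=(40, 52)) + 1
        for i in range(5):
            base[i, i] = 2000
        m = CountMatrix(pd.DataFrame(base, index=[f"g{i:02d}" for i in range(40)],
                                     columns=organs))
        scores = score_matrix(m)
        table = threshold_table(scores, pair_thresholds([6]), min_RE=4.0, min_AE=10)
        row = table.iloc[0]
        assert row["n_OSG"] == 5
        assert row["n_R_OSG"] == 0
        assert row["pct_A_OSG"] == 1.0


class TestCalibration:
    def test_rounding_of_ae_and_re_means_half_up(self):
        # AE mean over all cells is 9.625 -> rounds to 10; RE mean over
        # the cells passing AE >= 10 is 3.85 -> rounds to 4 (half of
        # those cells sit at RE 5.7 and still pass the calibrated
        # cutoff, the rest at 2.0 do not)
        ae = [10] * 14 + [7, 7]
        re = [5.7] * 7 + [2.0] * 7 + [0.5, 0.5]
        rows = [
            score_row(f"g{i}", "liver", AE=a, RE=r, RZ=5.0, pvalue=1e-12)
            for i, (a, r) in enumerate(zip(ae, re))
        ]
        scores = pd.DataFrame(rows)
        thresholds, _ = calibrate_thresholds(scores, target_pct_absolute=0.5)
        assert thresholds.min_AE == 10
        assert thresholds.min_RE == 4

    def test_selects_loosest_pair_meeting_purity(self, calib_scores):
        thresholds, table = calibrate_thresholds(calib_scores)
        assert thresholds.max_pvalue == 1e-5
        assert thresholds.min_RZ == 4.0
        # looser pairs fail the purity target, the selected one meets it
        assert (table["pct_A_OSG"].iloc[:2] < 0.95).all()
        assert table["pct_A_OSG"].iloc[2] >= 0.95

    def test_unreachable_purity_raises_with_table(self):
        # every qualifying gene is a two-organ (relative) OSG at every pair
        rows = []
        for i in range(6):
            rows.append(score_row(f"g{i}", "liver", RZ=7.0, pvalue=1e-12))
            rows.append(score_row(f"g{i}", "spleen", RZ=7.0, pvalue=1e-12))
        with pytest.raises(CalibrationError) as err:
            calibrate_thresholds(pd.DataFrame(rows))
        assert err.value.table is not None
        assert (err.value.table["pct_A_OSG"] == 0.0).all()


class TestNestedness:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_tightening_either_cutoff_never_adds_calls(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(rng.uniform(0.5, 30), size=(30, 20))
        counts[0, 0] += 200  # ensure at least one enriched cell sometimes
        m = CountMatrix(pd.DataFrame(counts, index=[f"g{i}" for i in range(30)],
                                     columns=[f"o{j}" for j in range(20)]))
        scores = score_matrix(m)
        pairs = pair_thresholds([0, 1, 2, 3])
        table = threshold_table(scores, pairs, min_RE=1.0, min_AE=1)
        assert (table["n_OSG"].diff().dropna() <= 0).all()
        assert (table["n_R_OSG"].diff().dropna() <= 0).all()

    def test_componentwise_stricter_thresholds_give_subset(self, demo_scores):
        loose = ThresholdSet(1e-3, 2.0, 2.0, 5)
        strict = ThresholdSet(1e-7, 5.0, 4.0, 20)
        loose_pairs = {(c.gene, o) for c in call_osg(demo_scores, loose) for o in c.organs}
        strict_pairs = {(c.gene, o) for c in call_osg(demo_scores, strict) for o in c.organs}
        assert strict_pairs <= loose_pairs


class TestOverlapMatrix:
    def test_absolute_calls_have_zero_off_diagonal(self):
        calls = [OSGCall("g1", frozenset({"liver"})), OSGCall("g2", frozenset({"brain"}))]
        m = overlap_matrix(calls)
        off = m.to_numpy() - np.diag(np.diag(m.to_numpy()))
        assert (off == 0).all()
        assert m.at["liver", "liver"] == 1

    def test_shared_gene_counts_once_per_pair(self):
        calls = [OSGCall("g1", frozenset({"liver", "spleen"}))]
        m = overlap_matrix(calls)
        assert m.at["liver", "spleen"] == 1
        assert m.at["spleen", "liver"] == 1

    def test_symmetric_and_diagonal_sums_to_call_sizes(self, demo_scores):
        calls = call_osg(demo_scores)
        m = overlap_matrix(calls)
        assert (m.to_numpy() == m.to_numpy().T).all()
        assert np.diag(m.to_numpy()).sum() == sum(len(c.organs) for c in calls)


class TestTopGenes:
    def _calls_and_scores(self, per_organ: dict[str, int]):
        rows, calls = [], []
        for organ, n in per_organ.items():
            for i in range(n):
                gene = f"{organ}_g{i}"
                rows.append(score_row(gene, organ, RZ=10.0 - i))
                calls.append(OSGCall(gene, frozenset({organ})))
        return pd.DataFrame(rows), calls

    def test_154_from_50_full_and_2_partial_organs(self):
        per_organ = {f"organ{i:02d}": 3 for i in range(50)}
        per_organ["peritoneum"] = 2
        per_organ["ureter"] = 2
        scores, calls = self._calls_and_scores(per_organ)
        top = top_genes_per_organ(scores, calls, n=3)
        assert sum(len(genes) for _o, genes in top) == 154

    def test_ranked_by_rz_then_pvalue_then_gene(self):
        rows = [
            score_row("gB", "liver", RZ=9.0, pvalue=1e-8),
            score_row("gA", "liver", RZ=9.0, pvalue=1e-8),
            score_row("gC", "liver", RZ=9.0, pvalue=1e-12),
            score_row("gD", "liver", RZ=11.0, pvalue=1e-6),
        ]
        calls = [OSGCall(g, frozenset({"liver"})) for g in ("gA", "gB", "gC", "gD")]
        (_, ranked), = top_genes_per_organ(pd.DataFrame(rows), calls, n=4)
        assert ranked == ["gD", "gC", "gA", "gB"]

    def test_n_larger_than_available_returns_all(self):
        scores, calls = self._calls_and_scores({"liver": 2})
        (_, genes), = top_genes_per_organ(scores, calls, n=5)
        assert len(genes) == 2

    def test_n_below_one_rejected(self):
        with pytest.raises(OrganSpecError):
            top_genes_per_organ(pd.DataFrame([score_row("g", "o")]), [], n=0)


class TestCallsIO:
    def test_write_read_round_trip(self, tmp_path, demo_scores):
        calls = call_osg(demo_scores)
        path = tmp_path / "calls.tsv"
        with open(path, "w") as fh:
            write_calls(calls, demo_scores, fh)
        back = read_calls(path)
        assert {(c.gene, frozenset(c.organs)) for c in back} == {
            (c.gene, frozenset(c.organs)) for c in calls
        }
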