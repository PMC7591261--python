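from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest

import phasecall as pc
from phasecall.errors import ValidationError
from _oracles import average_ranks, logrank_brute, spearman_rho_brute


class TestIntersection:
    def test_overlap(self):
        assert pc.intersect_downregulated(["A", "B", "C"], ["B", "C", "D"]) == ["B", "C"]

    def test_disjoint(self):
        assert pc.intersect_downregulated(["A"], ["B"]) == []

    def test_idempotent_and_sorted(self):
        assert pc.intersect_downregulated(["C", "A", "B"], ["B", "C", "A"]) == ["A", "B", "C"]


def _expr(rows, ids=None):
    df = pd.DataFrame(rows)
    df.index = ids or [f"g{i}" for i in range(len(df))]
    return df


class TestSpearmanScreen:
    def test_identical_and_reversed_anchors(self):
        anchor = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0, 8.0, 7.0, 9.0, 10.0])
        expr = _expr([anchor, -anchor])
        table, _ = pc.spearman_screen(expr, anchor)
        assert table.loc["g0", "rho"] == pytest.approx(1.0)
        assert table.loc["g1", "rho"] == pytest.approx(-1.0)

    def test_tie_case_matches_rank_pearson(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        table, _ = pc.spearman_screen(_expr([x]), y)
        assert table.loc["g0", "rho"] == pytest.approx(spearman_rho_brute(x, y), abs=1e-12)

    def test_matches_scipy_spearman(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 12))
        X[2] = np.round(X[2])  # introduce ties
        anchor = rng.normal(size=12)
        table, _ = pc.spearman_screen(_expr(list(X)), anchor)
        for i in range(10):
            rho, p = spearmanr(X[i], anchor)
            assert table.iloc[i]["rho"] == pytest.approx(rho, abs=1e-12)
            assert table.iloc[i]["p_value"] == pytest.approx(p, rel=1e-6)

    def test_exact_permutation_p_small_n(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=6)
        anchor = rng.normal(size=6)
        table, _ = pc.spearman_screen(_expr([x]), anchor)
        obs = abs(spearman_rho_brute(x, anchor))
        count = sum(
            abs(spearman_rho_brute(x, np.array(perm))) >= obs - 1e-12
            for perm in permutations(average_ranks(anchor))
        )
        assert table.loc["g0", "p_value"] == pytest.approx(count / factorial(6), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=15)
        anchor = rng.normal(size=15)
        t1, _ = pc.spearman_screen(_expr([x]), anchor)
        t2, _ = pc.spearman_screen(_expr([np.exp(3 * x)]), anchor**3 + 2 * anchor)
        assert t1.loc["g0", "rho"] == pytest.approx(t2.loc["g0", "rho"], abs=1e-12)
        assert t1.loc["g0", "p_value"] == pytest.approx(t2.loc["g0", "p_value"], rel=1e-9)

    def test_constant_anchor_rejected(self):
        with pytest.raises(ValidationError):
            pc.spearman_screen(_expr([np.arange(5.0)]), np.ones(5))

    def test_constant_gene_flagged_and_excluded(self):
        anchor = np.arange(12.0)
        expr = _expr([np.ones(12), anchor])
        table, summary = pc.spearman_screen(expr, anchor)
        assert bool(table.loc["g0", "constant"])
        assert np.isnan(table.loc["g0", "p_value"])
        assert summary["n_tested"] == 1

    def test_summary_fraction_positive(self):
        rng = np.random.default_rng(7)
        anchor = rng.normal(size=30)
        pos = [anchor + rng.normal(0, 0.1, 30) for _ in range(8)]
        neg = [-anchor + rng.normal(0, 0.1, 30) for _ in range(2)]
        table, summary = pc.spearman_screen(_expr(pos + neg), anchor)
        assert summary["n_significant"] == 10
        assert summary["fraction_positive"] == pytest.approx(0.8)


def _records(time, event, expr):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(time))],
            "time": time,
            "event": event,
            "expression": expr,
        }
    )


class TestKmMedianSplit:
    def test_identical_groups_chi2_zero(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        expr = [0, 0, 0, 0, 1, 1, 1, 1]  # split exactly replicates the data
        res = pc.km_median_split(_records(time, event, expr))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_six_subject_hand_oracle(self):
        """Alternating groups, no censoring: chi2 must equal the explicit
        risk-set computation over the 6 event times."""
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 1, 1, 1, 1, 1]
        expr = [1, 0, 1, 0, 1, 0]  # high group = subjects 1,3,5
        res = pc.km_median_split(_records(time, event, expr))
        chi2, p = logrank_brute(time, event, np.array(expr) == 1)
        assert res.chi2 == pytest.approx(chi2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_randomized_instances_match_riskset_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(10, 30))
            time = rng.exponential(5, n).round(2) + 0.01
            event = rng.integers(0, 2, n)
            expr = rng.normal(size=n)
            if event.sum() < 2:
                continue
            rec = _records(time, event, expr)
            res = pc.km_median_split(rec)
            high = expr > np.median(expr)
            chi2, p = logrank_brute(time, event, high)
            assert res.chi2 == pytest.approx(chi2, rel=1e-8)
            assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_median_ties_go_low(self):
        time = [1, 2, 3, 4, 5]
        event = [1] * 5
        expr = [1.0, 2.0, 2.0, 3.0, 4.0]
        res = pc.km_median_split(_records(time, event, expr))
        assert res.labels.tolist() == ["low", "low", "low", "high", "high"]

    def test_km_curve_is_empirical_survival_without_censoring(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1] * 8
        expr = [0, 0, 0, 0, 1, 1, 1, 1]
        res = pc.km_median_split(_records(time, event, expr))
        curve = res.curves["high"].set_index("time")["survival"]
        np.testing.assert_allclose(curve.loc[[1, 2, 3, 4]], [0.75, 0.5, 0.25, 0.0])

    def test_degenerate_split_rejected(self):
        rec = _records([1, 2, 3], [1, 1, 1], [1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            pc.km_median_split(rec)

    def test_group_relabel_symmetry(self):
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 0, 1, 1, 0, 1]
        res1 = pc.km_median_split(_records(time, event, [0, 0, 0, 1, 1, 1]))
        res2 = pc.km_median_split(_records(time, event, [1, 1, 1, 0, 0, 0]))
        assert res1.chi2 == pytest.approx(res2.chi2, rel=1e-9)


class TestThreeC:
    @pytest.mark.parametrize(
        "ds,dc,expected", [(5.0, 5.0, 1.0), (6.0, 5.0, 2.0), (3.0, 5.0, 0.25)]
    )
    def test_formula(self, ds, dc, expected):
        assert pc.three_c_interaction_frequency(ds, dc) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            pc.three_c_interaction_frequency(float("nan"), 1.0)
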