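import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binomtest

import phasecall as pc
from phasecall.errors import ValidationError
from _oracles import bh_naive, exact_test_brute


class TestEqualizePseudocounts:
    def test_equal_sizes_identity(self):
        X = np.array([[3.0, 5.0], [1.0, 2.0]])
        pseudo, common = pc.equalize_pseudocounts(X, [1e6, 1e6])
        np.testing.assert_allclose(pseudo, X, rtol=1e-12)
        assert common == pytest.approx(1e6)

    def test_geometric_mean_common_size(self):
        X = np.array([[10.0, 10.0]])
        pseudo, common = pc.equalize_pseudocounts(X, [1e6, 4e6])
        assert common == pytest.approx(2e6)
        np.testing.assert_allclose(pseudo, [[20.0, 5.0]])
        assert pseudo.sum() == pytest.approx(25.0)


class TestExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert pc.nb_exact_test([7, 8], [8, 7], 0.2) == 1.0

    def test_zero_total_gives_p_one(self):
        assert pc.nb_exact_test([0, 0], [0, 0], 0.1) == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("s_a,s_b", [(0, 12), (3, 9), (10, 2), (15, 15), (1, 0)])
    def test_matches_bruteforce_enumeration(self, phi, s_a, s_b):
        p = pc.nb_exact_test([s_a, 0.0], [s_b, 0.0], phi)
        assert p == pytest.approx(exact_test_brute(s_a, s_b, 2, 2, phi), abs=1e-10)

    @pytest.mark.parametrize("s_a,s_b", [(9, 3), (20, 5), (4, 4), (0, 7)])
    def test_poisson_limit_equals_binomial_test(self, s_a, s_b):
        """At phi=0 with equal group sizes the conditional split is
        binomial(1/2); the probability-mass rule is the exact binomial
        two-sided test."""
        p = pc.nb_exact_test([s_a / 2, s_a / 2], [s_b / 2, s_b / 2], 0.0)
        expected = binomtest(s_a, s_a + s_b, 0.5).pvalue
        assert p == pytest.approx(expected, abs=1e-10)

    def test_unequal_group_sizes_against_oracle(self):
        p = pc.nb_exact_test([4, 5, 6], [20, 21], 0.1)
        assert p == pytest.approx(exact_test_brute(15, 41, 3, 2, 0.1), abs=1e-10)

    @given(
        st.integers(min_value=0, max_value=40),
        st.integers(min_value=0, max_value=40),
        st.sampled_from([0.0, 0.05, 0.3]),
    )
    def test_label_swap_leaves_p_unchanged(self, s_a, s_b, phi):
        p1 = pc.nb_exact_test([s_a, 0], [s_b, 0], phi)
        p2 = pc.nb_exact_test([s_b, 0], [s_a, 0], phi)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            pc.nb_exact_test([-1, 2], [3, 4], 0.1)
        with pytest.raises(ValidationError):
            pc.nb_exact_test([1, 2], [3, 4], -0.1)


class TestDispersionEstimation:
    def _pseudo(self, phi, n_genes, seed):
        cfg = pc.SimConfig(
            n_genes=n_genes, frac_phase_specific=0.0, dispersion=phi, seed=seed,
            library_sizes=tuple([2_000_000] * 10),
        )
        cm, _ = pc.simulate_counts(cfg)
        cols = cm.samples_in_phase("G1") + cm.samples_in_phase("G1/S")
        return cm.counts[cols].to_numpy(float)

    def test_recovers_moderate_dispersion(self):
        Y = self._pseudo(0.2, 1000, seed=5)
        est = pc.estimate_common_dispersion(Y, ["a", "a", "b", "b"])
        assert 0.15 <= est.phi <= 0.25

    def test_poisson_data_gives_near_zero(self):
        Y = self._pseudo(0.0, 1000, seed=6)
        est = pc.estimate_common_dispersion(Y, ["a", "a", "b", "b"])
        assert est.phi <= 0.01

    def test_single_gene_warns_but_returns_finite(self):
        with pytest.warns(UserWarning, match="only 1 genes"):
            est = pc.estimate_common_dispersion(
                np.array([[5.0, 5.0, 5.0, 5.0]]), ["a", "a", "b", "b"]
            )
        assert np.isfinite(est.phi)

    def test_all_zero_rejected(self):
        with pytest.raises(pc.errors.ComputationError):
            pc.estimate_common_dispersion(np.zeros((3, 4)), ["a", "a", "b", "b"])


class TestLogFoldChange:
    @pytest.mark.parametrize(
        "a,b,prior,expected",
        [
            (10.0, 20.0, 0.0, 1.0),
            (0.0, 0.0, 0.5, 0.0),
            (0.0, 3.0, 0.5, np.log2(7.0)),
        ],
    )
    def test_values(self, a, b, prior, expected):
        assert pc.log_fold_change(a, b, prior) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry(self):
        assert pc.log_fold_change(3.0, 11.0, 0.5) == pytest.approx(
            -pc.log_fold_change(11.0, 3.0, 0.5)
        )


class TestBhFdr:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            pc.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert pc.bh_fdr([0.3])[0] == pytest.approx(0.3)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_naive_step_up(self, p):
        np.testing.assert_allclose(pc.bh_fdr(p), bh_naive(p), atol=1e-12)

    @given(st.permutations(list(np.linspace(0.001, 0.9, 12))))
    def test_permutation_invariance(self, p):
        q = pc.bh_fdr(p)
        order = np.argsort(p)
        np.testing.assert_allclose(np.array(q)[order], pc.bh_fdr(np.sort(p)), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            pc.bh_fdr([0.5, 1.5])


class TestTestPair:
    def test_identical_counts_not_called(self, fixture_run):
        _, _, result = fixture_run
        table = result.pairwise[("G1/S", "S")]
        # nulls are near-constant across phases: never DEGs
        nulls = [g for g in table.index if g.startswith("NULL_")]
        assert (table.loc[nulls, "deg_call"] == "none").all()

    def test_label_swap_antisymmetry(self, fixture_run):
        cm, _, result = fixture_run
        kept = cm.subset_genes(result.filter_mask.to_numpy())
        norm = result.normalization
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fwd = pc.test_pair(kept, "G1", "G1/S", norm)
            rev = pc.test_pair(kept, "G1/S", "G1", norm)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-9)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        up, down = fwd["deg_call"] == "up", rev["deg_call"] == "down"
        assert (up == down).all()

    def test_missing_phase_is_design_error(self, fixture_run):
        cm, _, result = fixture_run
        sub_samples = cm.samples[cm.samples["phase"] != "S"]
        sub = pc.CountMatrix(
            cm.counts[list(sub_samples["sample_id"])], sub_samples,
            cm.library_size[list(sub_samples["sample_id"])],
        )
        with pytest.raises(pc.errors.DesignError):
            pc.test_pair(sub, "S", "G2", result.normalization)
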