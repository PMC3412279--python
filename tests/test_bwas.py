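import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuromark.bwas import (
    BWASConfig,
    BinaryNetworkSet,
    binarize_networks,
    bwas_test,
    bwas_threshold,
    fdr_correct,
    link_counts,
    run_bwas,
)
from neuromark.connectivity import ConnectivityMatrix


def _mat(values):
    return ConnectivityMatrix(values=values, kind="partial")


def _counts_row(L_H, N_H, L_P, N_P):
    return pd.DataFrame(
        {"region_i": [0], "region_j": [1], "L_H": [L_H], "L_P": [L_P],
         "N_H": [N_H], "N_P": [N_P]}
    )


class TestBinarize:
    def test_zero_matrices_give_empty_networks(self):
        mats = [_mat(np.eye(4)) for _ in range(3)]
        nets = binarize_networks(mats, ["control"] * 3, n_timepoints=100)
        assert not nets.presence.any()

    def test_strong_link_present_under_significance_rule(self):
        # t-transform oracle: rho=0.9, T=231, n=10 -> p << 0.05
        v = np.eye(10)
        v[0, 1] = v[1, 0] = 0.9
        nets = binarize_networks([_mat(v)], ["patient"], n_timepoints=231)
        df = 231 - 10
        t = 0.9 * np.sqrt(df) / np.sqrt(1 - 0.81)
        assert 2 * stats.t.sf(t, df) < 0.05  # the oracle agrees
        assert nets.presence[0, 0]  # link (0,1) is the first upper-tri entry

    def test_proportional_rule_counts(self, rng):
        v = np.eye(10)
        iu = np.triu_indices(10, k=1)
        vals = rng.standard_normal(45) * 0.1
        v[iu] = vals
        v = np.maximum(v, v.T) + np.minimum(v, v.T) - np.diag(np.diag(v)) + np.eye(10) - np.eye(10)
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        nets = binarize_networks([_mat(v)], ["control"], rule="proportional",
                                 density=0.1)
        assert nets.presence[0].sum() == int(np.floor(0.1 * 45)) == 4

    def test_absolute_rule(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.5
        v[0, 2] = v[2, 0] = 0.1
        nets = binarize_networks([_mat(v)], ["control"], rule="absolute",
                                 abs_threshold=0.2)
        assert nets.presence[0].tolist() == [True, False, False]

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError, match="df"):
            binarize_networks([_mat(np.eye(10))], ["control"], n_timepoints=10)


class TestLinkCounts:
    def test_extreme_tallies(self):
        n_regions = 3
        presence = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 0]], dtype=bool)
        nets = BinaryNetworkSet(
            presence=presence, labels=np.array(["control", "control", "patient"]),
            n_regions=n_regions,
        )
        c = link_counts(nets)
        assert c.loc[0, "L_H"] == 2 and c.loc[0, "L_P"] == 0
        assert c.loc[0, "N_H"] == 2 and c.loc[0, "N_P"] == 1

    def test_matches_loop_tally_oracle(self, rng):
        n_regions, n_sub = 6, 20
        n_links = 15
        presence = rng.random((n_sub, n_links)) < 0.4
        labels = np.array(["control"] * 12 + ["patient"] * 8)
        nets = BinaryNetworkSet(presence=presence, labels=labels, n_regions=n_regions)
        c = link_counts(nets)
        for link in range(n_links):
            lh = sum(presence[s, link] for s in range(n_sub) if labels[s] == "control")
            lp = sum(presence[s, link] for s in range(n_sub) if labels[s] == "patient")
            assert c.loc[link, "L_H"] == lh
            assert c.loc[link, "L_P"] == lp

    def test_single_group_rejected(self):
        nets = BinaryNetworkSet(
            presence=np.zeros((2, 3), dtype=bool),
            labels=np.array(["control", "control"]), n_regions=3,
        )
        with pytest.raises(ValueError):
            link_counts(nets)


class TestProportionTest:
    def test_identical_proportions_give_half(self):
        res = bwas_test(_counts_row(50, 100, 50, 100))
        assert res.loc[0, "S_hat"] == 0.0
        assert res.loc[0, "p_value"] == pytest.approx(0.5)

    def test_hand_evaluated_example(self):
        # S = 0.30, sigma = sqrt(0.0016 + 0.0025) = 0.06403, p = Phi(-4.685)
        res = bwas_test(_counts_row(80, 100, 50, 100))
        assert res.loc[0, "S_hat"] == pytest.approx(0.30)
        assert res.loc[0, "sigma_hat"] == pytest.approx(0.064031, abs=1e-6)
        assert res.loc[0, "p_value"] == pytest.approx(1.40e-6, rel=0.01)

    def test_score_is_exact_proportion_difference(self, rng):
        for _ in range(20):
            lh, lp = rng.integers(0, 51, size=2)
            res = bwas_test(_counts_row(lh, 50, lp, 50))
            assert res.loc[0, "S_hat"] == lh / 50 - lp / 50

    def test_floor_and_ceiling_filter(self):
        low = bwas_test(_counts_row(1, 100, 1, 100))  # rho 0.01 / 0.01
        assert not low.loc[0, "retained"]
        high = bwas_test(_counts_row(99, 100, 100, 100))
        assert not high.loc[0, "retained"]
        mixed = bwas_test(_counts_row(1, 100, 99, 100))  # one low, one high
        assert mixed.loc[0, "retained"]
        mid = bwas_test(_counts_row(30, 100, 60, 100))
        assert mid.loc[0, "retained"]

    def test_degenerate_sigma(self):
        res = bwas_test(_counts_row(0, 50, 0, 50))
        assert res.loc[0, "p_value"] == 1.0
        res = bwas_test(_counts_row(50, 50, 0, 50))
        assert res.loc[0, "p_value"] == 0.0

    def test_two_sided_doubles(self):
        one = bwas_test(_counts_row(60, 100, 40, 100))
        two = bwas_test(
            _counts_row(60, 100, 40, 100), BWASConfig(p_convention="two_sided")
        )
        assert two.loc[0, "p_value"] == pytest.approx(
            2 * one.loc[0, "p_value"]
        )


class TestThreshold:
    def test_normal_quantile_example(self):
        assert bwas_threshold(0.06403, 0.05) == pytest.approx(0.10533, abs=2e-5)

    def test_limit_and_monotonicity(self):
        assert bwas_threshold(0.1, 0.4999) < 1e-3
        assert bwas_threshold(0.1, 0.01) > bwas_threshold(0.1, 0.05) > 0

    def test_invalid_alpha_rejected(self):
        for alpha in (0.0, 0.5, 0.7, -0.1):
            with pytest.raises(ValueError):
                bwas_threshold(0.1, alpha)

    def test_threshold_equivalent_to_p_below_alpha(self, rng):
        # p < alpha  <=>  |S| > S_th, for the one-tailed-of-absolute convention
        alpha = 0.05
        for _ in range(50):
            lh, lp = rng.integers(1, 100, size=2)
            res = bwas_test(_counts_row(lh, 100, lp, 100))
            s, sig, p = res.loc[0, ["S_hat", "sigma_hat", "p_value"]]
            if sig == 0:
                continue
            assert (p < alpha) == (abs(s) > bwas_threshold(sig, alpha))


class TestFDR:
    def test_all_ones_nothing_significant(self):
        df = bwas_test(
            pd.DataFrame({"region_i": [0] * 5, "region_j": range(1, 6),
                          "L_H": [50] * 5, "L_P": [50] * 5,
                          "N_H": 100, "N_P": 100})
        )
        out = fdr_correct(df, q=0.05)
        assert not out["significant"].any()

    def test_step_up_rule_by_hand(self):
        # 10 links at p=0.001 among 90 at p=0.9: BH keeps exactly the 10
        p = np.array([0.001] * 10 + [0.9] * 90)
        df = pd.DataFrame({
            "region_i": 0, "region_j": np.arange(100), "L_H": 0, "L_P": 0,
            "N_H": 1, "N_P": 1, "rho_H": 0.5, "rho_P": 0.5, "S_hat": 0.0,
            "sigma_hat": 1.0, "p_value": p, "retained": True,
        })
        out = fdr_correct(df, q=0.05)
        assert out["significant"].sum() == 10
        assert out.loc[:9, "significant"].all()

    def test_single_p_reduces_to_direct_comparison(self):
        df = pd.DataFrame({
            "region_i": [0], "region_j": [1], "L_H": [1], "L_P": [1],
            "N_H": [2], "N_P": [2], "rho_H": [0.5], "rho_P": [0.5],
            "S_hat": [0.1], "sigma_hat": [0.1], "p_value": [0.04],
            "retained": [True],
        })
        assert fdr_correct(df, q=0.05)["significant"].iloc[0]

    def test_only_retained_links_enter_correction(self):
        df = pd.DataFrame({
            "region_i": 0, "region_j": np.arange(4), "L_H": 0, "L_P": 0,
            "N_H": 1, "N_P": 1, "rho_H": 0.5, "rho_P": 0.5, "S_hat": 0.0,
            "sigma_hat": 1.0, "p_value": [0.01, 0.01, 0.01, 0.01],
            "retained": [True, True, False, False],
        })
        out = fdr_correct(df, q=0.05)
        assert out["q_value"].notna().tolist() == [True, True, False, False]
        assert not out.loc[2:, "significant"].any()


class TestCalibrationAndPower:
    def test_null_rejection_rate_matches_convention(self):
        # simulated null: occurrence probability 0.3 in both groups
        rng = np.random.default_rng(123)
        N, links = 200, 2000
        presence = rng.random((2 * N, links)) < 0.3
        alpha = 0.05
        # build counts directly (region bookkeeping irrelevant here)
        counts = pd.DataFrame({
            "region_i": 0, "region_j": np.arange(links),
            "L_H": presence[:N].sum(axis=0), "L_P": presence[N:].sum(axis=0),
            "N_H": N, "N_P": N,
        })
        as_printed = bwas_test(counts)
        rate1 = float((as_printed["p_value"] < alpha).mean())
        assert abs(rate1 - 2 * alpha) < 0.02
        two_sided = bwas_test(counts, BWASConfig(p_convention="two_sided"))
        rate2 = float((two_sided["p_value"] < alpha).mean())
        assert abs(rate2 - alpha) < 0.02

    def test_planted_links_recovered_with_fdr_control(self):
        # FDR control is meaningful on calibrated p-values, so the recovery
        # check runs under the two-sided convention; the one-tailed-of-
        # absolute form would make BH operate at an effective level of ~2q.
        N = 100
        n_null, n_planted = 1800, 200
        config = BWASConfig(p_convention="two_sided")
        sens, fdp = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            null = rng.random((2 * N, n_null)) < 0.3
            ctrl = rng.random((N, n_planted)) < 0.2
            pat = rng.random((N, n_planted)) < 0.6
            counts = pd.DataFrame({
                "region_i": 0, "region_j": np.arange(n_null + n_planted),
                "L_H": np.concatenate([null[:N].sum(0), ctrl.sum(0)]),
                "L_P": np.concatenate([null[N:].sum(0), pat.sum(0)]),
                "N_H": N, "N_P": N,
            })
            out = fdr_correct(bwas_test(counts, config), q=0.05)
            sig = out["significant"].to_numpy()
            true = np.zeros(n_null + n_planted, dtype=bool)
            true[n_null:] = True
            sens.append(sig[true].mean())
            fdp.append(sig[~true].sum() / max(sig.sum(), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdp) <= 0.1

    def test_run_bwas_pipeline_smoke(self, rng):
        presence = rng.random((30, 10)) < 0.5
        labels = np.array(["control"] * 15 + ["patient"] * 15)
        nets = BinaryNetworkSet(presence=presence, labels=labels, n_regions=5)
        out = run_bwas(nets)
        assert {"p_value", "q_value", "significant", "retained"} <= set(out.columns)
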