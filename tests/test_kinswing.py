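"""PWM construction and scoring, match calibration, network building,
the swing statistic and known-substrate validation."""

import numpy as np
import pandas as pd
import pytest

from epiphos.errors import FormatError
from epiphos.kinswing import (
    build_network,
    build_pwm,
    compute_swing,
    empirical_match_pvalues,
    known_substrate_average,
    match_pvalue,
    score_window,
    window_core,
)

CONS = "AAAAAAASAAAAAAA"


def _random_window(rng, center="S"):
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    f = rng.choice(aa, size=14)
    return "".join(f[:7]) + center + "".join(f[7:])


class TestBuildPWM:
    def test_unanimity_with_zero_pseudocount(self):
        pwm = build_pwm([CONS, CONS], "K1", "ST", pseudocount=0.0)
        assert pwm.freq[0, 0] == 1.0  # A at position 0
        assert pwm.n_seqs == 2

    def test_n_seqs_counts_duplicates(self):
        pwm = build_pwm([CONS, CONS, CONS], "K1", "ST")
        assert pwm.n_seqs == 3

    def test_pseudocount_formula(self):
        pwm = build_pwm([CONS], "K1", "ST", pseudocount=0.01)
        assert pwm.freq[0, 0] == pytest.approx(1.01 / 1.20)

    def test_columns_sum_to_one(self, rng):
        wins = [_random_window(rng) for _ in range(20)]
        pwm = build_pwm(wins, "K1", "ST")
        np.testing.assert_allclose(pwm.freq.sum(axis=0), 1.0, atol=1e-9)

    def test_padding_contributes_no_count(self):
        pwm = build_pwm(["_______S_______"], "K1", "ST", pseudocount=0.0)
        # non-center columns saw no residue at all
        assert pwm.freq[:, 0].sum() == 0.0

    def test_bad_window_length_is_format_error(self):
        with pytest.raises(FormatError):
            build_pwm(["AAASAAA"], "K1", "ST")

    def test_no_windows_is_format_error(self):
        with pytest.raises(FormatError):
            build_pwm([], "K1", "ST")


class TestScoreWindow:
    def test_consensus_scores_15_log2_20(self):
        pwm = build_pwm([CONS, CONS], "K1", "ST", pseudocount=0.0)
        assert score_window(pwm, CONS) == pytest.approx(15 * np.log2(20))

    def test_flat_pwm_scores_zero(self, rng):
        pwm = build_pwm([CONS], "K1", "ST")
        pwm.freq[:] = 1.0 / 20.0
        assert score_window(pwm, _random_window(rng)) == pytest.approx(0.0)

    def test_padded_window_scores_center_only(self):
        pwm = build_pwm([CONS, CONS], "K1", "ST", pseudocount=0.0)
        assert score_window(pwm, "_______S_______") == pytest.approx(np.log2(20))

    def test_incompatible_center_not_scored(self):
        pwm = build_pwm([CONS], "K1", "ST")
        assert np.isnan(score_window(pwm, "AAAAAAAYAAAAAAA"))


class TestMatchPvalue:
    def test_score_above_all_background(self, rng):
        pwm = build_pwm([CONS] * 5, "K1", "ST", pseudocount=0.01)
        bg = [_random_window(rng) for _ in range(1500)]
        p = match_pvalue(pwm, CONS, bg, n_draws=1000, seed=0)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_score_below_all_background_is_one(self):
        # background of consensus windows, query is heavily padded
        pwm = build_pwm([CONS] * 3, "K1", "ST", pseudocount=0.01)
        bg = [CONS] * 1200
        p = match_pvalue(pwm, "_______S_______", bg, n_draws=1000, seed=0)
        assert p == pytest.approx(1.0)

    def test_monotone_in_score(self, rng):
        bg_scores = rng.normal(size=1000)
        grid = np.linspace(-4, 4, 50)
        p = empirical_match_pvalues(grid, bg_scores)
        assert (np.diff(p) <= 1e-12).all()

    def test_pvalues_bounded(self, rng):
        bg_scores = rng.normal(size=1000)
        p = empirical_match_pvalues(rng.normal(size=200), bg_scores)
        assert (p >= 1.0 / 1001.0 - 1e-12).all() and (p <= 1.0).all()


class TestBuildNetwork:
    def test_threshold_selects_edges(self, rng):
        strong = build_pwm([CONS] * 10, "KSTRONG", "ST", pseudocount=0.01)
        bg = [_random_window(rng) for _ in range(400)]
        ids = [f"F{i}" for i in range(len(bg))] + ["HIT"]
        wins = bg + [CONS]
        net = build_network([strong], ids, wins, edge_p_threshold=0.01, seed=0)
        assert "HIT" in set(net["feature_id"])

    def test_tyrosine_feature_no_edge_to_st_kinase(self, rng):
        pwm = build_pwm([CONS] * 5, "K1", "ST")
        ids = ["Y1"]
        wins = ["AAAAAAAYAAAAAAA"]
        net = build_network([pwm], ids, wins, seed=0)
        assert net.empty

    def test_empty_pwm_set_empty_network(self, rng):
        net = build_network([], ["F1"], [CONS], seed=0)
        assert net.empty

    def test_deterministic_given_seed(self, rng):
        pwm = build_pwm([CONS] * 5, "K1", "ST")
        wins = [_random_window(rng) for _ in range(300)]
        ids = [f"F{i}" for i in range(300)]
        a = build_network([pwm], ids, wins, seed=3)
        b = build_network([pwm], ids, wins, seed=3)
        pd.testing.assert_frame_equal(a, b)


def _toy_network_results(rng, n_kinases=6, n_sub=200, planted=None):
    """Random bipartite network plus differential results; `planted`
    optionally maps a kinase index to (n_substrates, log2fc)."""
    subs = [f"F{i}" for i in range(n_sub)]
    lfc = rng.normal(0, 0.5, n_sub)
    p = rng.uniform(0, 1, n_sub)
    rows = []
    for k in range(n_kinases):
        chosen = rng.choice(n_sub, size=40, replace=False)
        for c in chosen:
            rows.append((f"K{k}", subs[c], 1.0, 0.01))
    net = pd.DataFrame(rows, columns=["kinase", "feature_id", "match_score",
                                      "match_p"])
    df = pd.DataFrame({"feature_id": subs, "log2fc": lfc, "p": p})
    pwms = [build_pwm([CONS] * 10, f"K{k}", "ST") for k in range(n_kinases)]
    return net, df, pwms


class TestComputeSwing:
    def test_all_up_kinase_hits_formula_endpoint(self, rng):
        net, df, pwms = _toy_network_results(rng)
        k0 = net[net["kinase"] == "K0"]["feature_id"]
        df.loc[df["feature_id"].isin(k0), ["log2fc", "p"]] = [1.0, 0.001]
        sw = compute_swing(net, df, pwms, n_perm=50, seed=0)
        row = sw[sw["kinase"] == "K0"].iloc[0]
        n_edges = row["n_edges"]
        expected = np.log(n_edges + 1) * np.log(10 + 1)
        # K0's substrates may also appear under other kinases; its own
        # proportions are exact
        assert row["p_pos_frac"] == 1.0 and row["p_neg_frac"] == 0.0
        assert row["swing_raw"] == pytest.approx(expected)

    def test_balanced_substrates_swing_zero(self, rng):
        net, df, pwms = _toy_network_results(rng)
        k0 = list(net[net["kinase"] == "K0"]["feature_id"])
        half = len(k0) // 2
        df.loc[df["feature_id"].isin(k0[:half]), ["log2fc", "p"]] = [1.0, 0.001]
        df.loc[df["feature_id"].isin(k0[half:]), ["log2fc", "p"]] = [-1.0, 0.001]
        sw = compute_swing(net, df, pwms, n_perm=50, seed=0)
        row = sw[sw["kinase"] == "K0"].iloc[0]
        assert row["swing_raw"] == pytest.approx(0.0)

    def test_antisymmetric_under_global_sign_flip(self, rng):
        net, df, pwms = _toy_network_results(rng)
        sw1 = compute_swing(net, df, pwms, n_perm=10, seed=0)
        df2 = df.assign(log2fc=-df["log2fc"])
        sw2 = compute_swing(net, df2, pwms, n_perm=10, seed=0)
        np.testing.assert_allclose(sw1["swing_raw"], -sw2["swing_raw"],
                                   atol=1e-12)

    def test_z_scores_standardized(self, rng):
        net, df, pwms = _toy_network_results(rng)
        sw = compute_swing(net, df, pwms, n_perm=10, seed=0)
        assert sw["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert sw["z"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_perm_p_lower_bound(self, rng):
        net, df, pwms = _toy_network_results(rng)
        sw = compute_swing(net, df, pwms, n_perm=100, seed=0)
        assert (sw["perm_p_pos"] >= 1 / 101 - 1e-12).all()
        assert (sw["perm_p_neg"] >= 1 / 101 - 1e-12).all()
        assert ((sw["n_pos"] + sw["n_neg"]) <= sw["n_edges"]).all()

    def test_deterministic_given_seed(self, rng):
        net, df, pwms = _toy_network_results(rng)
        a = compute_swing(net, df, pwms, n_perm=100, seed=9)
        b = compute_swing(net, df, pwms, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_sd_raises(self, rng):
        net = pd.DataFrame(
            {"kinase": ["K0", "K1"], "feature_id": ["F0", "F1"],
             "match_score": [1.0, 1.0], "match_p": [0.01, 0.01]}
        )
        df = pd.DataFrame({"feature_id": ["F0", "F1"],
                           "log2fc": [0.0, 0.0], "p": [1.0, 1.0]})
        pwms = [build_pwm([CONS], k, "ST") for k in ("K0", "K1")]
        with pytest.raises(ValueError, match="SD"):
            compute_swing(net, df, pwms, n_perm=10, seed=0)


class TestKnownSubstrateAverage:
    def _features(self):
        return pd.DataFrame(
            {
                "feature_id": ["f1", "f2", "f3", "f4", "f5"],
                "gene": ["G1", "G2", "G3", "G4", "G5"],
                "window": ["ABCDEFGSHIJKLMN", "BBCDEFGSHIJKLMN",
                           "CBCDEFGSHIJKLMN", "DBCDEFGSHIJKLMN",
                           "EBCDEFGSHIJKLMN"],
            }
        )

    def _diff(self, fcs, sig=True):
        return pd.DataFrame(
            {
                "feature_id": [f"f{i + 1}" for i in range(len(fcs))],
                "log2fc": fcs,
                "significant": [sig] * len(fcs),
            }
        )

    def _db(self, genes, windows, kinase="KIN1"):
        return pd.DataFrame(
            {
                "KINASE_GENE": [kinase] * len(genes),
                "SUB_GENE": genes,
                "SUB_POS": ["10"] * len(genes),
                "SITE_WINDOW": windows,
            }
        )

    def test_mean_of_matched_significant_substrates(self):
        feats = self._features()
        db = self._db(list(feats["gene"][:4]), list(feats["window"][:4]))
        out = known_substrate_average(self._diff([0.5, 0.5, 1.0, 2.0, 9.9]),
                                      feats, db)
        assert out["KIN1"] == pytest.approx(1.0)

    def test_minimum_four_substrates_required(self):
        feats = self._features()
        db = self._db(list(feats["gene"][:3]), list(feats["window"][:3]))
        out = known_substrate_average(self._diff([0.5, 0.5, 1.0, 2.0, 9.9]),
                                      feats, db)
        assert "KIN1" not in out.index

    def test_duplicate_gene_window_pairs_counted_once(self):
        feats = self._features()
        genes = list(feats["gene"][:4]) + [feats["gene"][0]]
        wins = list(feats["window"][:4]) + [feats["window"][0]]
        db = self._db(genes, wins)
        out = known_substrate_average(self._diff([0.5, 0.5, 1.0, 2.0, 9.9]),
                                      feats, db)
        assert out["KIN1"] == pytest.approx(1.0)

    def test_match_requires_identical_core_but_not_flanks(self):
        feats = self._features()
        # db window differs from f1's only outside the ±4 core
        altered = "ZZCDEFGSHIJKLZZ"
        assert window_core(altered) == window_core(feats["window"][0])
        db = self._db([feats["gene"][i] for i in range(4)],
                      [altered] + list(feats["window"][1:4]))
        out = known_substrate_average(self._diff([0.5, 0.5, 1.0, 2.0, 9.9]),
                                      feats, db)
        assert out["KIN1"] == pytest.approx(1.0)

    def test_core_mismatch_is_no_match(self):
        feats = self._features()
        bad = "ABCDEFGSHIJKLMN".replace("H", "Q")  # inside the core
        db = self._db([feats["gene"][i] for i in range(4)],
                      [bad] + list(feats["window"][1:4]))
        out = known_substrate_average(self._diff([0.5, 0.5, 1.0, 2.0, 9.9]),
                                      feats, db)
        assert "KIN1" not in out.index  # only 3 real matches remain
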