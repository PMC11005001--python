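"""Synthetic-data generator: determinism, planted truth bookkeeping,
moment calibration, missingness mechanism, motif coherence, and the
batch/protein-confound guarantees."""

import numpy as np
import pandas as pd
import pytest

from epiphos.design import Contrast, SampleDesign
from epiphos.differential import exclude_protein_driven, fit_moderated_test
from epiphos.ingest import (
    collapse_duplicates,
    filter_multiphospho,
    intensity_matrix,
    log2_transform,
    parse_phospho_table,
    parse_protein_table,
    passes_localization,
    remap_windows,
)
from epiphos.kinswing import build_pwm, score_encoded, encode_windows
from epiphos.preprocess import estimate_surrogate_variables, remove_surrogates
from epiphos.simulate import (
    KinaseActivation,
    PlantedEffect,
    ProteinChange,
    SimConfig,
    default_config,
    generate_experiment,
    generate_kinase_db,
    kinase_motifs,
)


def small_config(**kw) -> SimConfig:
    base = dict(
        n_features=900, n_proteins=240, n_kinases=8, n_db_substrates=15,
        planted_effects=[PlantedEffect(list(range(0, 60)), 1.0, "4h")],
        planted_kinases=[KinaseActivation(0, 1.0, 20, "4h")],
        planted_proteins=[ProteinChange(p, 1.0, "24h") for p in range(150, 160)],
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        cfg = small_config()
        a = generate_experiment(cfg, 7)
        b = generate_experiment(cfg, 7)
        pd.testing.assert_frame_equal(a.phospho_table, b.phospho_table)
        pd.testing.assert_frame_equal(a.protein_table, b.protein_table)
        assert a.fasta == b.fasta
        assert a.ground_truth == b.ground_truth

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config()
        p1 = generate_experiment(cfg, 3).write(tmp_path / "a")
        p2 = generate_experiment(cfg, 3).write(tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_differs(self):
        cfg = small_config()
        a = generate_experiment(cfg, 1)
        b = generate_experiment(cfg, 2)
        assert not a.phospho_table.equals(b.phospho_table)

    def test_kinase_db_deterministic(self):
        cfg = small_config()
        ka, ra = generate_kinase_db(cfg, 5)
        kb, rb = generate_kinase_db(cfg, 5)
        pd.testing.assert_frame_equal(ka, kb)
        pd.testing.assert_frame_equal(ra, rb)


class TestGroundTruth:
    def test_null_config_lists_zero_effects(self):
        cfg = SimConfig(n_features=300, n_proteins=100, n_kinases=4)
        gt = generate_experiment(cfg, 0).ground_truth
        assert gt["planted_effects"] == []
        assert gt["planted_kinases"] == []
        assert gt["planted_proteins"] == []
        assert gt["total_effect_by_feature_plex"] == {}

    def test_planted_ids_resolve_to_table_rows(self):
        cfg = small_config()
        exp = generate_experiment(cfg, 0)
        from epiphos.ingest import make_feature_id

        table_ids = set()
        for row in exp.phospho_table.itertuples(index=False):
            d = row._asdict()
            table_ids.add(
                make_feature_id(
                    d["gene"],
                    [int(x) for x in str(d["positions"]).split(";")],
                    str(d["residues"]).split(";"),
                    int(d["multiplicity"]),
                )
            )
        for eff in exp.ground_truth["planted_effects"]:
            assert set(eff["feature_ids"]) <= table_ids

    def test_out_of_range_feature_index_is_config_error(self):
        cfg = small_config(
            planted_effects=[PlantedEffect([10_000], 1.0, "4h")]
        )
        with pytest.raises(ValueError, match="out of range"):
            generate_experiment(cfg, 0)


class TestMoments:
    def test_mean_and_sd_match_config_within_2pct(self):
        cfg = SimConfig(
            n_features=5000, n_proteins=1200, n_kinases=4, missing_rate=0.0,
            duplicate_frac=0.0, n_batch=0,
        )
        exp = generate_experiment(cfg, 0)
        cols = [c for c in exp.phospho_table.columns if c.startswith("intensity_")]
        vals = np.log2(exp.phospho_table[cols].astype(float).to_numpy())
        expect_sd = np.hypot(cfg.baseline_sd, cfg.within_sd)
        assert vals.mean() == pytest.approx(cfg.baseline_mean, rel=0.02)
        assert vals.std() == pytest.approx(expect_sd, rel=0.02)


class TestMissingness:
    def _rate_and_bias(self, cfg, seed=0):
        exp = generate_experiment(cfg, seed)
        cols = [c for c in exp.phospho_table.columns if c.startswith("intensity_")]
        raw = exp.phospho_table[cols].astype(float).to_numpy()
        missing = raw == 0.0
        with np.errstate(divide="ignore"):
            logs = np.log2(np.where(missing, np.nan, raw))
        row_mean = np.nanmean(logs, axis=1)
        rate_by_row = missing.mean(axis=1)
        ok = np.isfinite(row_mean)
        r = np.corrcoef(row_mean[ok], rate_by_row[ok])[0, 1]
        return missing.mean(), r

    def test_overall_rate_near_target(self):
        cfg = small_config(duplicate_frac=0.0)
        rate, _ = self._rate_and_bias(cfg)
        assert rate == pytest.approx(0.25, abs=0.04)

    def test_left_censoring_low_intensity_rows_lose_more(self):
        rate, r = self._rate_and_bias(small_config(duplicate_frac=0.0))
        assert r < -0.5  # low-intensity rows have higher missing rates

    def test_mcar_mode_has_no_intensity_dependence(self):
        rate, r = self._rate_and_bias(small_config(duplicate_frac=0.0, mcar=True))
        assert abs(r) < 0.15


class TestLocalizationPlanting:
    def test_configured_fraction_fails_the_rule(self):
        cfg = small_config(duplicate_frac=0.0)
        exp = generate_experiment(cfg, 0)
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            paths = exp.write(td)
            records = parse_phospho_table(paths["phospho"], exp.design)
        failed = [r for r in records if not passes_localization(r)]
        n_fail_expected = int(round(cfg.loc_fail_frac * cfg.n_features))
        assert len(failed) == n_fail_expected
        failed_ids = {
            f"{r.gene}" for r in failed
        }
        # planted features never fail localization
        planted = {
            fid for eff in exp.ground_truth["planted_effects"]
            for fid in eff["feature_ids"]
        }
        gt_fail = set(exp.ground_truth["loc_fail_feature_ids"])
        assert not (planted & gt_fail)


class TestMotifCoherence:
    def test_zero_noise_substrates_equal_consensus(self):
        cfg = small_config(motif_noise=0.0)
        ks, _ = generate_kinase_db(cfg, 4)
        motifs = kinase_motifs(cfg, 4)
        for kin, grp in ks.groupby("KINASE_GENE"):
            assert set(grp["SITE_WINDOW"]) == {motifs[kin][0]}

    def test_own_substrates_score_higher_than_foreign(self):
        cfg = small_config(motif_noise=0.2)
        ks, _ = generate_kinase_db(cfg, 9)
        pwms = {
            kin: build_pwm(list(grp["SITE_WINDOW"]), kin,
                           "Y" if grp["SITE_WINDOW"].iloc[0][7] == "Y" else "ST")
            for kin, grp in ks.groupby("KINASE_GENE")
        }
        margins = []
        for kin, grp in ks.groupby("KINASE_GENE"):
            enc = encode_windows(list(grp["SITE_WINDOW"]))
            own = score_encoded(pwms[kin], enc).mean()
            foreign = np.mean([
                score_encoded(p, enc).mean()
                for k2, p in pwms.items() if k2 != kin
            ])
            margins.append(own - foreign)
        assert np.mean(margins) > 0
        assert min(margins) > 0


class TestProteinConfound:
    def test_exclusions_trace_back_to_planted_proteins(self):
        """Every phosphopeptide excluded by the protein filter belongs to a
        gene with a planted protein-level change."""
        cfg = small_config(missing_rate=0.10)
        exp = generate_experiment(cfg, 11)
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            paths = exp.write(td)
            records = parse_phospho_table(paths["phospho"], exp.design)
            records = remap_windows(records, str(paths["fasta"]))
            records = filter_multiphospho(records)
            features = collapse_duplicates(log2_transform(records))
            proteins = parse_protein_table(paths["protein"], exp.design)

        gene_of = {f.feature_id: f.gene for f in features}
        phospho_frames, protein_frames = [], []
        for plex in ("4h", "24h"):
            contrast = Contrast(f"P/M({plex})", plex, "pilocarpine", "mock")
            X, ids = intensity_matrix(features, exp.design, plex)
            from epiphos.preprocess import preprocess_plex

            res = preprocess_plex(X, ids, exp.design, plex, seed=0)
            genes = [gene_of[i] for i in res.feature_ids]
            phospho_frames.append(
                fit_moderated_test(res.matrix, res.feature_ids, res.design,
                                   contrast, genes=genes)
            )
            P = np.vstack([p.log2_intensity for p in proteins])[
                :, exp.design.indices(plex=plex)
            ]
            pres = preprocess_plex(P, [p.gene for p in proteins], exp.design,
                                   plex, seed=0, _rerun=True)
            protein_frames.append(
                fit_moderated_test(pres.matrix, pres.feature_ids, pres.design,
                                   contrast, genes=pres.feature_ids)
            )
        all_prot = pd.concat(protein_frames, ignore_index=True)
        planted_genes = {
            p["gene"] for p in exp.ground_truth["planted_proteins"]
        }
        for ph in phospho_frames:
            out = exclude_protein_driven(ph, all_prot)
            excluded_genes = set(out.loc[out["protein_excluded"], "gene"])
            assert excluded_genes <= planted_genes


class TestBatchPlanting:
    def test_fpr_without_correction_exceeds_with_on_confounded_design(self):
        """A mostly group-aligned batch with an identifiable within-group
        component biases the uncorrected test; surrogate correction
        reduces the null false-positive rate."""
        c = Contrast("P/M(4h)", "4h", "pilocarpine", "mock")
        worse = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            design = SampleDesign.default().subset(plex="4h")
            labels = np.array(design.group_labels())
            n = len(design)
            X = rng.normal(20, 1.5, (1500, 1)) + rng.normal(0, 0.5, (1500, n))
            within = np.zeros(n)
            for g in set(labels):
                gi = np.where(labels == g)[0]
                s = np.ones(gi.size)
                s[1::2] = -1
                within[gi] = s - s.mean()
            aligned = (labels == "pilocarpine").astype(float)
            aligned -= aligned.mean()
            batch = 0.4 * within + 1.0 * aligned
            load = rng.choice([-1.0, 1.0], 1500)
            load[rng.random(1500) >= 0.4] = 0.0
            Xb = X + load[:, None] * batch[None, :]
            ids = [str(i) for i in range(1500)]
            r_un = fit_moderated_test(Xb, ids, design, c)
            svs = estimate_surrogate_variables(Xb, design, plex="4h", seed=0)
            Xc = remove_surrogates(Xb, design, svs, plex="4h")
            r_co = fit_moderated_test(Xc, ids, design, c)
            worse += (r_un["p"] < 0.05).mean() > (r_co["p"] < 0.05).mean()
        assert worse >= 2
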