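"""Calibration and recovery studies run on synthetic data.

Each function performs one self-contained computation used both by the
acceptance checks and by the numbered analysis drivers: set arithmetic on
the published per-timepoint counts, null calibration of the moderated
test, planted-effect recovery, kinase-activity recovery and null
uniformity, and end-to-end determinism.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import Contrast, Sample, SampleDesign
from .differential import fit_moderated_test, persistence_and_overlap
from .kinswing import build_network, build_pwm, compute_swing
from .simulate import (
    AA,
    SimConfig,
    _noisy_window,
    default_config,
    generate_experiment,
    generate_kinase_db,
    kinase_motifs,
    simulate_two_group_matrix,
)

#: Published per-timepoint counts (4 h plex, 24 h plex, overlap) for
#: detected phosphopeptides, detected protein genes, and significant
#: phosphopeptides at the two timepoints.
PHOSPHO_DETECTED = (23_306, 22_940, 18_127)
PROTEIN_DETECTED = (5_765, 5_550, 5_264)
SIGNIFICANT_COUNTS = (6_497, 3_472, 1_248)


def _sets_from_counts(n_a: int, n_b: int, n_inter: int):
    """Explicit id sets realizing printed per-set counts and overlap."""
    a = {f"id{i}" for i in range(n_a)}
    b = {f"id{i}" for i in range(n_inter)} | {
        f"only_b{i}" for i in range(n_b - n_inter)
    }
    return a, b


def set_arithmetic() -> dict:
    """Union counts by inclusion–exclusion from the published per-timepoint
    counts, and the persistence percentage of significant phosphopeptides.

    The persistence percentage uses the 24 h count as denominator — the
    only denominator consistent with the published 36% figure
    (1,248/3,472)."""
    out = {}
    a, b = _sets_from_counts(*PHOSPHO_DETECTED)
    out["phospho_union"] = persistence_and_overlap(a, b)["n_union"]
    a, b = _sets_from_counts(*PROTEIN_DETECTED)
    out["protein_union"] = persistence_and_overlap(a, b)["n_union"]
    a, b = _sets_from_counts(*SIGNIFICANT_COUNTS)
    res = persistence_and_overlap(a, b)
    out["persistent_significant"] = res["n_intersection"]
    out["persistence_pct"] = 100.0 * res["n_intersection"] / res["n_b"]
    return out


def _two_group_design() -> SampleDesign:
    samples = [Sample(f"M{i}", "4h", "mock", 4.0, i) for i in range(1, 5)] + [
        Sample(f"P{i}", "4h", "pilocarpine", 4.0, i) for i in range(1, 5)
    ]
    return SampleDesign(samples)


_PM4 = Contrast("P/M(4h)", "4h", "pilocarpine", "mock")


def null_calibration(seed: int = 0, n_features: int = 5000,
                     n_seeds: int = 3) -> dict:
    """Type-I error of the moderated test on null data (no planted
    effects, 4 vs 4, within-group SD 0.5)."""
    design = _two_group_design()
    fracs, zero_runs = [], 0
    for i in range(n_seeds):
        X, _, ids = simulate_two_group_matrix(
            n_features, 4, 0, 0.0, 0.5, seed=seed + i
        )
        res = fit_moderated_test(X, ids, design, _PM4)
        fracs.append(float((res["p"] < 0.05).mean()))
        zero_runs += int(res["significant"].sum() == 0)
    return {
        "raw_p_fraction_per_seed": fracs,
        "raw_p_fraction_mean": float(np.mean(fracs)),
        "zero_discovery_runs": zero_runs,
        "n_seeds": n_seeds,
    }


def effect_recovery(seed: int = 0, n_features: int = 5000,
                    n_planted: int = 500, log2fc: float = 1.0,
                    sd: float = 0.5) -> dict:
    """Sensitivity and effect-size accuracy for planted fold changes
    (4 vs 4 replicates)."""
    design = _two_group_design()
    X, truth, ids = simulate_two_group_matrix(
        n_features, 4, n_planted, log2fc, sd, seed=seed
    )
    res = fit_moderated_test(X, ids, design, _PM4)
    est = res["log2fc"][truth]
    return {
        "bh_sensitivity": float(res["significant"][truth].mean()),
        "raw_p_sensitivity": float((res["p"][truth] <= 0.05).mean()),
        "median_effect_error": float(abs(np.median(est) - log2fc)),
        "n_planted": n_planted,
        "n_features": n_features,
    }


def _kinswing_inputs(n_kinases: int, n_features: int, seed: int,
                     planted_kinase: str | None = None,
                     n_planted: int = 40, planted_fc: float = 1.0):
    """Null feature windows and differential results, optionally with one
    kinase's substrates planted at a significant positive fold change."""
    cfg = SimConfig(n_kinases=n_kinases)
    ks, _ = generate_kinase_db(cfg, seed)
    pwms = []
    for kin, grp in ks.groupby("KINASE_GENE", sort=True):
        wins = list(grp["SITE_WINDOW"])
        st = [w for w in wins if w[7] in "ST"]
        ty = [w for w in wins if w[7] == "Y"]
        if st:
            pwms.append(build_pwm(st, kin, "ST"))
        if ty:
            pwms.append(build_pwm(ty, kin, "Y"))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    windows, ids = [], []
    for i in range(n_features):
        center = str(rng.choice(["S", "T", "Y"], p=[0.6, 0.3, 0.1]))
        f = rng.choice(list(AA), size=14)
        windows.append("".join(f[:7]) + center + "".join(f[7:]))
        ids.append(f"F{i}")
    lfc = rng.normal(0.0, 0.3, size=n_features)
    p = rng.uniform(0.0, 1.0, size=n_features)
    if planted_kinase is not None:
        motifs = kinase_motifs(cfg, seed)
        consensus, _cls = motifs[planted_kinase]
        for j in range(n_planted):
            windows.append(_noisy_window(consensus, 0.2, rng))
            ids.append(f"SUB{j}")
        lfc = np.concatenate([lfc, np.full(n_planted, planted_fc)])
        p = np.concatenate([p, rng.uniform(0.0, 0.05, size=n_planted)])
    diff = pd.DataFrame({"feature_id": ids, "log2fc": lfc, "p": p})
    return pwms, ids, windows, diff


def kinswing_recovery(seed: int = 0, n_runs: int = 20, n_kinases: int = 30,
                      n_features: int = 2000, n_perm: int = 1000) -> dict:
    """Planted kinase activation (40 substrates at +1, significant): how
    often does the planted kinase attain the maximum z with permutation
    p <= 0.05 across seeded runs?"""
    hits = 0
    for r in range(n_runs):
        run_seed = seed + 1000 * r + 1
        pwms, ids, windows, diff = _kinswing_inputs(
            n_kinases, n_features, run_seed, planted_kinase="KIN01"
        )
        net = build_network(pwms, ids, windows, seed=run_seed)
        sw = compute_swing(net, diff, pwms, n_perm=n_perm, seed=run_seed)
        top = sw.loc[sw["z"].idxmax()]
        if top["kinase"] == "KIN01" and top["perm_p_pos"] <= 0.05:
            hits += 1
    return {"hits": hits, "n_runs": n_runs}


def kinswing_null_uniformity(seed: int = 0, n_kinases: int = 50,
                             n_features: int = 2000,
                             n_perm: int = 1000) -> dict:
    """Kolmogorov–Smirnov distance of permutation p-values from U(0,1)
    under a global null (no planted kinase)."""
    pwms, ids, windows, diff = _kinswing_inputs(n_kinases, n_features, seed)
    net = build_network(pwms, ids, windows, seed=seed)
    sw = compute_swing(net, diff, pwms, n_perm=n_perm, seed=seed)
    return {
        "ks_pos": float(stats.kstest(sw["perm_p_pos"], "uniform").statistic),
        "ks_neg": float(stats.kstest(sw["perm_p_neg"], "uniform").statistic),
        "n_kinases": int(len(sw)),
    }


def pipeline_determinism(work_dir, seed: int = 1) -> dict:
    """Run the full synthetic pipeline twice with one seed and compare
    every output file byte for byte."""
    from .pipeline import run_pipeline

    work = Path(work_dir)
    cfg = default_config()
    exp = generate_experiment(cfg, seed)
    paths = exp.write(work / "inputs")
    ks, reg = generate_kinase_db(cfg, seed)
    ks_path = work / "inputs" / "kinase_substrates.tsv"
    reg_path = work / "inputs" / "regulatory_sites.tsv"
    ks.to_csv(ks_path, sep="\t", index=False)
    reg.to_csv(reg_path, sep="\t", index=False)

    def tree_hash(d: Path) -> dict:
        return {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.iterdir()) if p.is_file()
        }

    hashes = []
    for tag in ("run_a", "run_b"):
        run_pipeline(
            paths["phospho"], paths["protein"], paths["fasta"],
            paths["design"], work / tag, ks_db_path=ks_path,
            reg_db_path=reg_path, seed=seed, n_perm=500,
        )
        hashes.append(tree_hash(work / tag))
    return {
        "identical": hashes[0] == hashes[1],
        "n_files": len(hashes[0]),
    }
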