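"""End-to-end pipeline: ingest → preprocess → differential → kinase
inference → annotation, with a run manifest.

Each plex is processed independently (missingness filter, quantile
normalization, kNN imputation, surrogate-variable correction, outlier
screen with one re-run), then the four contrasts are tested, protein-level
exclusion applied, and downstream kinase/annotation summaries computed.
All outputs are plain tab-separated tables plus JSON summaries; reruns
with the same inputs and seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import STANDARD_CONTRASTS, SampleDesign
from .differential import (
    exclude_protein_driven,
    fit_moderated_test,
    median_protein_summary,
    persistence_and_overlap,
)
from .errors import PipelineError
from .ingest import (
    collapse_duplicates,
    features_to_frame,
    filter_multiphospho,
    intensity_matrix,
    load_fasta,
    log2_transform,
    parse_phospho_table,
    parse_protein_table,
    remap_windows,
)
from .kinswing import (
    build_network,
    build_pwm,
    compute_swing,
    known_substrate_average,
    load_kinase_substrate_db,
)
from .annotation import (
    build_ranked_gene_list,
    function_trends,
    load_regulatory_db,
    match_regulatory_sites,
)
from .preprocess import preprocess_plex


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(
    phospho_path,
    protein_path,
    fasta_path,
    design_path,
    out_dir,
    ks_db_path=None,
    reg_db_path=None,
    seed: int = 0,
    max_group_frac: float = 0.25,
    impute_k: int = 10,
    sva_mode: str = "regress",
    outlier_alpha: float = 1e-4,
    outlier_n_pcs: int = 2,
    edge_p_threshold: float = 0.05,
    fc_p_threshold: float = 0.05,
    n_perm: int = 1000,
    pwm_pseudocount: float = 0.01,
) -> dict:
    """Run every stage on files in the ingest dialect; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pipeline_version": __version__,
        "seed": seed,
        "parameters": {
            "missing.max_group_frac": max_group_frac,
            "impute.k": impute_k,
            "sva.mode": sva_mode,
            "outlier.alpha": outlier_alpha,
            "outlier.n_pcs": outlier_n_pcs,
            "edges.p": edge_p_threshold,
            "fc.p": fc_p_threshold,
            "n_perm": n_perm,
            "preprocess.order": "filter-missingness, quantile-normalize, impute, sva, outlier",
            "localization.single_site_threshold": 0.75,
        },
        "stages": {},
    }

    # ---- ingest ----------------------------------------------------------
    @_stage("ingest")
    def do_ingest():
        design = SampleDesign.from_tsv(design_path)
        records = parse_phospho_table(phospho_path, design)
        fasta = load_fasta(fasta_path)
        records = remap_windows(records, fasta)
        n_before = len(records)
        records = filter_multiphospho(records)
        features = collapse_duplicates(log2_transform(records))
        proteins = parse_protein_table(protein_path, design)
        manifest["stages"]["ingest"] = {
            "n_rows": n_before,
            "n_after_localization": len(records),
            "n_features": len(features),
            "n_protein_genes": len(proteins),
        }
        return design, features, proteins

    design, features, proteins = do_ingest()
    _write_tsv(features_to_frame(features, design), out / "phospho_features.tsv")

    feature_meta = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "gene": [f.gene for f in features],
            "window": [f.primary_window for f in features],
        }
    )
    gene_of = dict(zip(feature_meta["feature_id"], feature_meta["gene"]))

    # ---- preprocess + differential, per plex -----------------------------
    phospho_res = {}
    protein_res = {}
    preproc = {}
    for plex in design.plexes:
        @_stage("preprocess")
        def do_pre(plex=plex):
            X, ids = intensity_matrix(features, design, plex)
            res = preprocess_plex(
                X, ids, design, plex,
                max_group_frac=max_group_frac, impute_k=impute_k,
                sva_mode=sva_mode, outlier_alpha=outlier_alpha,
                outlier_n_pcs=outlier_n_pcs, seed=seed,
            )
            P, pids = (
                np.vstack([p.log2_intensity for p in proteins])[
                    :, design.indices(plex=plex)
                ],
                [p.gene for p in proteins],
            )
            col_keep = [
                i for i, s in enumerate(design.subset(plex=plex).sample_ids)
                if s not in res.removed_samples
            ]
            pres = preprocess_plex(
                P[:, col_keep], pids, res.design, plex,
                max_group_frac=max_group_frac, impute_k=impute_k,
                sva_mode=sva_mode, outlier_alpha=outlier_alpha,
                outlier_n_pcs=outlier_n_pcs, seed=seed, _rerun=True,
            )
            manifest["stages"][f"preprocess_{plex}"] = {
                "n_features_kept": len(res.feature_ids),
                "n_surrogates": res.n_sv,
                "removed_samples": res.removed_samples,
            }
            return res, pres

        res, pres = do_pre()
        preproc[plex] = res

        @_stage("differential")
        def do_diff(plex=plex, res=res, pres=pres):
            for contrast in [c for c in STANDARD_CONTRASTS if c.plex == plex]:
                genes = [gene_of[fid] for fid in res.feature_ids]
                dr = fit_moderated_test(
                    res.matrix, res.feature_ids, res.design, contrast, genes=genes
                )
                phospho_res[contrast.label] = dr
                pr = fit_moderated_test(
                    pres.matrix, pres.feature_ids, pres.design, contrast,
                    genes=pres.feature_ids,
                )
                protein_res[contrast.label] = pr
        do_diff()

    # ---- protein-level exclusion and summaries ---------------------------
    @_stage("differential")
    def do_exclusion():
        all_prot = pd.concat(protein_res.values(), ignore_index=True)
        for label, df in list(phospho_res.items()):
            phospho_res[label] = exclude_protein_driven(df, all_prot)
        for label, df in phospho_res.items():
            tag = label.replace("/", "").replace("(", "_").replace(")", "")
            _write_tsv(df, out / f"differential_phospho_{tag}.tsv")
        for label, df in protein_res.items():
            tag = label.replace("/", "").replace("(", "_").replace(")", "")
            _write_tsv(df, out / f"differential_protein_{tag}.tsv")

        def sig_ids(label):
            df = phospho_res[label]
            return set(df.loc[df["significant_filtered"], "feature_id"])

        summary = {
            "detected_phospho": persistence_and_overlap(
                phospho_res["P/M(4h)"]["feature_id"],
                phospho_res["P/M(24h)"]["feature_id"],
            ),
            "significant_phospho_PM": persistence_and_overlap(
                sig_ids("P/M(4h)"), sig_ids("P/M(24h)")
            ),
            "significant_phospho_DU": persistence_and_overlap(
                sig_ids("D/U(4h)"), sig_ids("D/U(24h)")
            ),
            "detected_protein_genes": persistence_and_overlap(
                protein_res["P/M(4h)"]["feature_id"],
                protein_res["P/M(24h)"]["feature_id"],
            ),
        }
        with open(out / "set_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        med = median_protein_summary(
            pd.concat(
                [phospho_res["P/M(4h)"], phospho_res["P/M(24h)"]],
                ignore_index=True,
            )
        )
        med.rename("median_sig_log2fc").to_frame().reset_index().to_csv(
            out / "median_protein_phospho.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        return summary

    set_summary = do_exclusion()
    manifest["stages"]["set_summary"] = set_summary

    # ---- kinase activity --------------------------------------------------
    if ks_db_path is not None:
        @_stage("kinswing")
        def do_kinswing():
            ks = load_kinase_substrate_db(ks_db_path)
            pwms = []
            for kin, grp in ks.groupby("KINASE_GENE", sort=True):
                wins = [w for w in grp["SITE_WINDOW"] if len(w) == 15]
                st = [w for w in wins if w[7] in "ST"]
                ty = [w for w in wins if w[7] == "Y"]
                if st:
                    pwms.append(build_pwm(st, kin, "ST", pseudocount=pwm_pseudocount))
                if ty:
                    pwms.append(build_pwm(ty, kin, "Y", pseudocount=pwm_pseudocount))
            for label, dr in phospho_res.items():
                meta = feature_meta[feature_meta["feature_id"].isin(dr["feature_id"])]
                net = build_network(
                    pwms, list(meta["feature_id"]), list(meta["window"]),
                    edge_p_threshold=edge_p_threshold, seed=seed,
                )
                swing = compute_swing(
                    net, dr, pwms, fc_p_threshold=fc_p_threshold,
                    n_perm=n_perm, seed=seed,
                )
                ksa = known_substrate_average(dr, meta, ks)
                tag = label.replace("/", "").replace("(", "_").replace(")", "")
                _write_tsv(swing, out / f"kinswing_{tag}.tsv")
                ksa.to_frame().reset_index().to_csv(
                    out / f"known_substrates_{tag}.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
            manifest["stages"]["kinswing"] = {"n_pwms": len(pwms)}
        do_kinswing()

    # ---- regulatory sites and ranked lists --------------------------------
    if reg_db_path is not None:
        @_stage("annotation")
        def do_annotation():
            reg = load_regulatory_db(reg_db_path)
            for label, dr in phospho_res.items():
                ann = match_regulatory_sites(feature_meta, dr, reg)
                trends = function_trends(ann)
                tag = label.replace("/", "").replace("(", "_").replace(")", "")
                _write_tsv(trends, out / f"function_trends_{tag}.tsv")
            background = set(feature_meta["gene"]) & {p.gene for p in proteins}
            for label in ("P/M(4h)", "P/M(24h)"):
                for direction in ("up", "down"):
                    rl = build_ranked_gene_list(
                        phospho_res[label], direction, background
                    )
                    tag = label.replace("/", "").replace("(", "_").replace(")", "")
                    pd.DataFrame({"gene": rl.genes}).to_csv(
                        out / f"ranked_genes_{tag}_{direction}.tsv",
                        sep="\t", index=False,
                    )
            manifest["stages"]["annotation"] = {"n_background_genes": len(background)}
        do_annotation()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
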