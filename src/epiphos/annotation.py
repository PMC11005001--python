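"""Regulatory-site trends, ranked gene lists, ordered enrichment, clustering.

Regulatory-site matching follows the same sequence-identity convention as
kinase-substrate matching: an identical gene name and an identical ±4
residue core around the phospho-acceptor; multi-phosphopeptides are
matched through their first site's window.  Ranked gene lists combine a
significance rank and a magnitude rank per phosphopeptide, deduplicated
to the best-ranked entry per gene, against a detected-gene background.
The ordered enrichment here is a minimal stand-in for external
ordered-query services: a plain hypergeometric tail minimized over all
ranked-list prefixes, BH-corrected across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .differential import adjust_bh
from .errors import FormatError
from .kinswing import window_core


# ---------------------------------------------------------------------------
# regulatory-site database

def load_regulatory_db(path) -> pd.DataFrame:
    """Tab-separated flat file: GENE, POS, SITE_WINDOW, FUNCTION, DIRECTION
    (direction in {induced, inhibited})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"GENE", "POS", "SITE_WINDOW", "FUNCTION", "DIRECTION"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"regulatory-site file lacks columns {sorted(missing)}")
    return df


def match_regulatory_sites(
    features: pd.DataFrame,
    diff_results: pd.DataFrame,
    reg_db: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate detected phosphopeptides with known site functions.

    `features` needs feature_id, gene, window.  Matching is by identical
    gene and identical ±4 window core.  When several features hit one
    (gene, window, function, direction) entry, the quantitative value with
    the largest magnitude is kept.  Output has one row per retained
    (feature, function, direction) with log2fc and the significance flag.
    """
    db = reg_db.copy()
    db["core"] = [window_core(w) for w in db["SITE_WINDOW"]]
    db = db.drop_duplicates(subset=["GENE", "core", "FUNCTION", "DIRECTION"])

    feats = features.copy()
    feats["core"] = [window_core(w) for w in feats["window"]]
    sig_col = (
        "significant_filtered"
        if "significant_filtered" in diff_results.columns
        else "significant"
    )
    dr = diff_results[["feature_id", "log2fc", sig_col]].rename(
        columns={sig_col: "significant"}
    )
    feats = feats.merge(dr, on="feature_id", how="inner")

    merged = db.merge(
        feats, left_on=["GENE", "core"], right_on=["gene", "core"], how="inner"
    )
    if merged.empty:
        return pd.DataFrame(
            columns=["function", "direction", "gene", "core", "feature_id",
                     "log2fc", "significant"]
        )
    # largest-magnitude tie-break on redundant matches
    merged["absfc"] = merged["log2fc"].abs()
    merged = merged.sort_values(
        ["FUNCTION", "DIRECTION", "GENE", "core", "absfc", "feature_id"],
        ascending=[True, True, True, True, False, True],
    ).drop_duplicates(subset=["FUNCTION", "DIRECTION", "GENE", "core"], keep="first")
    out = merged[
        ["FUNCTION", "DIRECTION", "GENE", "core", "feature_id", "log2fc", "significant"]
    ].rename(
        columns={"FUNCTION": "function", "DIRECTION": "direction", "GENE": "gene"}
    )
    return out.reset_index(drop=True)


def function_trends(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per (function, direction): median significant log2FC and perturbed
    sites as a percentage of all detected matched sites.  Functions with
    zero detected sites are absent; with detected but no significant
    sites the median is NaN and the percentage 0."""
    rows = []
    for (fn, dirn), grp in annotated.groupby(["function", "direction"], sort=True):
        n_det = len(grp)
        sig = grp[grp["significant"]]
        rows.append(
            {
                "function": fn,
                "direction": dirn,
                "n_detected": n_det,
                "n_perturbed": len(sig),
                "pct_perturbed": 100.0 * len(sig) / n_det,
                "median_log2fc": float(sig["log2fc"].median()) if len(sig) else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ranked gene lists

@dataclass
class RankedGeneList:
    genes: list[str]
    direction: str           # "up" | "down"
    contrast: str
    background: set[str] = field(repr=False)

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        extra = set(self.genes) - self.background
        if extra:
            raise ValueError(f"genes outside background: {sorted(extra)[:3]}")


def build_ranked_gene_list(
    diff_results: pd.DataFrame,
    direction: str,
    background: set[str],
) -> RankedGeneList:
    """Combined-rank list for one direction of one contrast.

    Significant features of the direction are ranked by ascending adjusted
    p (rank_sig) and by descending |log2FC| (rank_mag); the two ranks are
    summed and the list sorted ascending by the combined rank, ties broken
    by rank_sig then gene symbol.  Duplicate genes keep their best entry.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sig_col = (
        "significant_filtered"
        if "significant_filtered" in diff_results.columns
        else "significant"
    )
    df = diff_results[diff_results[sig_col]].copy()
    df = df[df["log2fc"] > 0] if direction == "up" else df[df["log2fc"] < 0]
    contrast = str(diff_results["contrast"].iloc[0]) if len(diff_results) else ""
    if df.empty:
        return RankedGeneList([], direction, contrast, background)
    rank_sig = stats.rankdata(df["adj_p"], method="average")
    rank_mag = stats.rankdata(-df["log2fc"].abs(), method="average")
    df = df.assign(rank_sig=rank_sig, combined=rank_sig + rank_mag)
    df = df.sort_values(["combined", "rank_sig", "gene"], kind="stable")
    df = df.drop_duplicates(subset="gene", keep="first")
    genes = [g for g in df["gene"] if g in background]
    return RankedGeneList(genes, direction, contrast, background)


# ---------------------------------------------------------------------------
# ordered enrichment (hypergeometric min over prefixes)

def load_gmt(path) -> dict[str, set[str]]:
    terms = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                terms[parts[0]] = set(parts[2:])
    return terms


def ordered_enrichment(
    ranked_genes: list[str],
    term_gene_sets: dict[str, set[str]],
    background: set[str],
    max_term_size: int | None = None,
) -> pd.DataFrame:
    """Minimal ordered-query enrichment: per term, the minimum over all
    prefixes L_1..L_n of the hypergeometric upper-tail probability of the
    observed overlap, then BH across terms.  Terms disjoint from the
    background (or larger than max_term_size after intersection) are
    skipped."""
    N = len(background)
    n_list = len(ranked_genes)
    rows = []
    for term, genes in term_gene_sets.items():
        T = genes & background
        K = len(T)
        if K == 0:
            continue
        if max_term_size is not None and K > max_term_size:
            continue
        member = np.fromiter((g in T for g in ranked_genes), dtype=bool, count=n_list)
        k_cum = np.cumsum(member)
        n_pref = np.arange(1, n_list + 1)
        if n_list == 0 or k_cum[-1] == 0:
            rows.append((term, K, 0, 0, 1.0))
            continue
        pvals = stats.hypergeom.sf(k_cum - 1, N, K, n_pref)
        best = int(np.argmin(pvals))
        rows.append((term, K, int(n_pref[best]), int(k_cum[best]), float(pvals[best])))
    df = pd.DataFrame(
        rows, columns=["term", "term_size", "best_prefix", "overlap", "p"]
    )
    if len(df):
        df["adj_p"] = adjust_bh(df["p"].to_numpy())
    else:
        df["adj_p"] = []
    return df.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# heatmap clustering

def cluster_heatmap(matrix: np.ndarray) -> dict:
    """Row and column leaf orders from complete-linkage hierarchical
    clustering on Euclidean distance.  Fewer than two rows (or columns)
    give the identity order on that axis."""
    X = np.asarray(matrix, dtype=float)

    def order_and_linkage(A):
        if A.shape[0] < 2:
            return list(range(A.shape[0])), None
        Z = linkage(A, method="complete", metric="euclidean")
        return list(leaves_list(Z)), Z

    row_order, row_linkage = order_and_linkage(X)
    col_order, col_linkage = order_and_linkage(X.T)
    return {
        "row_order": row_order,
        "col_order": col_order,
        "row_linkage": row_linkage,
        "col_linkage": col_linkage,
    }
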