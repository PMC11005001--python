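"""Moderated differential testing, FDR control and set arithmetic.

Per feature, group means are fit by ordinary least squares within a plex
and the residual variance s_g^2 (d_g degrees of freedom) is shrunk toward
a prior (d0, s0^2) estimated across features by moment matching on
log s_g^2 (the empirical-Bayes scheme of variance-moderated t-tests):

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)
    t_mod  = log2FC / (s~_g * sqrt(1/n_t + 1/n_c)),  df = d0 + d_g

Significance is a Benjamini–Hochberg adjusted p below 0.05, applied per
contrast within each plex.  Significant phosphopeptides whose parent
protein also changed (in the matching comparison at either timepoint) are
excluded from downstream sets, so phospho-signals reflect stoichiometry
rather than expression; phosphopeptides with no protein record are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .design import Contrast, SampleDesign
from .errors import DesignError

ALPHA_SIG = 0.05


@dataclass
class ModerationParams:
    s0_sq: float
    d0: float  # may be +inf when all variances agree


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Moment-match a scaled inverse-chi-square prior to observed residual
    variances via the distribution of log s_g^2."""
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2)
    if ok.sum() < 2:
        return ModerationParams(float(np.nanmean(s2[ok])) if ok.any() else 0.0, np.inf)
    x = np.maximum(s2[ok], 0.0)
    med = np.median(x)
    if med == 0:
        med = 1.0
    x = np.maximum(x, 1e-5 * med)  # offset exact-zero variances
    z = np.log(x)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # all variances consistent with one value: infinite prior df and
        # the pooled (arithmetic mean) variance
        d0 = np.inf
        s0_sq = float(np.mean(x))
    return ModerationParams(s0_sq, d0)


def fit_moderated_test(
    X: np.ndarray,
    feature_ids: list[str],
    design: SampleDesign,
    contrast: Contrast,
    d0_override: float | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Moderated t-test for one contrast on a complete plex matrix.

    `X` columns must correspond to design.subset(plex=contrast.plex).
    Residual variance pools over all groups present in the plex (the
    group-means model), not just the two contrasted groups.  `d0_override`
    forces the prior degrees of freedom (0 gives the ordinary t-test,
    inf the fully pooled variance).
    """
    sub = design.subset(plex=contrast.plex)
    sub.validate_contrast(contrast)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(sub):
        raise DesignError(
            f"matrix has {X.shape[1]} columns but plex {contrast.plex!r} has "
            f"{len(sub)} samples"
        )
    labels = np.asarray(sub.group_labels())
    groups = sorted(set(labels))
    d_g = X.shape[1] - len(groups)
    if d_g <= 0:
        raise DesignError("zero residual degrees of freedom")

    means = {g: X[:, labels == g].mean(axis=1) for g in groups}
    rss = np.zeros(X.shape[0])
    for g in groups:
        cols = X[:, labels == g]
        rss += ((cols - means[g][:, None]) ** 2).sum(axis=1)
    s2 = rss / d_g

    params = (
        ModerationParams(float(np.mean(s2)), np.inf)
        if d0_override is not None and np.isinf(d0_override)
        else estimate_moderation(s2, d_g)
    )
    d0 = params.d0 if d0_override is None else d0_override
    if np.isinf(d0):
        s2_post = np.full_like(s2, params.s0_sq)
    else:
        s2_post = (d0 * params.s0_sq + d_g * s2) / (d0 + d_g)
    # total df capped at the pooled residual df across all features: the
    # prior cannot carry more information than the data it was fit on
    df_total = min(d0 + d_g, d_g * X.shape[0])

    n_t = (labels == contrast.treatment).sum()
    n_c = (labels == contrast.control).sum()
    leverage = 1.0 / n_t + 1.0 / n_c
    log2fc = means[contrast.treatment] - means[contrast.control]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / np.sqrt(s2_post * leverage)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.where(np.isfinite(t_mod), p, np.nan)
    adj = adjust_bh(np.nan_to_num(p, nan=1.0))

    res = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "contrast": contrast.label,
            "log2fc": log2fc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "adj_p": adj,
            "significant": adj < ALPHA_SIG,
        }
    )
    if genes is not None:
        res.insert(1, "gene", genes)
    res.attrs["moderation"] = ModerationParams(params.s0_sq, d0)
    return res


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# protein-level exclusion

def exclude_protein_driven(
    phospho_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    contrast_pairs: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Flag significant phosphopeptides whose gene's protein is significant
    in the matching comparison at either timepoint.

    `phospho_results` and `protein_results` need columns gene, contrast,
    significant.  `contrast_pairs` maps each phospho contrast label to the
    protein contrast labels counted as 'matching at either timepoint'
    (default: the P/M pair for P/M contrasts, the D/U pair for D/U).
    Features whose gene has no protein record are always kept.
    """
    if contrast_pairs is None:
        contrast_pairs = {
            "P/M(4h)": ("P/M(4h)", "P/M(24h)"),
            "P/M(24h)": ("P/M(4h)", "P/M(24h)"),
            "D/U(4h)": ("D/U(4h)", "D/U(24h)"),
            "D/U(24h)": ("D/U(4h)", "D/U(24h)"),
        }
    sig_prot = protein_results[protein_results["significant"]]
    sig_genes_by_contrast: dict[str, set] = {}
    for label, grp in sig_prot.groupby("contrast"):
        sig_genes_by_contrast[label] = set(grp["gene"])
    measured_genes = set(protein_results["gene"])

    out = phospho_results.copy()
    excluded = np.zeros(len(out), dtype=bool)
    for i, (gene, label, sig) in enumerate(
        zip(out["gene"], out["contrast"], out["significant"])
    ):
        if not sig or gene not in measured_genes:
            continue
        labels = contrast_pairs.get(label, (label,))
        excluded[i] = any(
            gene in sig_genes_by_contrast.get(pl, ()) for pl in labels
        )
    out["protein_excluded"] = excluded
    out["significant_filtered"] = out["significant"] & ~excluded
    return out


# ---------------------------------------------------------------------------
# set arithmetic and summaries

def persistence_and_overlap(ids_a, ids_b) -> dict:
    """|A|, |B|, |A∩B| and |A∪B| with the inclusion–exclusion identity
    enforced."""
    a, b = set(ids_a), set(ids_b)
    inter = len(a & b)
    union = len(a | b)
    assert union == len(a) + len(b) - inter
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": inter,
        "n_union": union,
    }


def union_from_counts(n_a: int, n_b: int, n_intersection: int) -> int:
    """Inclusion–exclusion from printed per-set counts."""
    if n_intersection > min(n_a, n_b):
        raise ValueError("intersection exceeds a set size")
    return n_a + n_b - n_intersection


def median_protein_summary(results: pd.DataFrame) -> pd.Series:
    """Per-gene median of significant log2 fold changes (heatmap values).
    Genes with no significant feature are absent."""
    sig_col = (
        "significant_filtered"
        if "significant_filtered" in results.columns
        else "significant"
    )
    sig = results[results[sig_col]]
    return sig.groupby("gene")["log2fc"].median()
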