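"""Normalization, imputation, surrogate-variable correction and QC.

Operates on a features × samples log2 intensity matrix for a single TMT
plex.  The stage order is: group-missingness filter → quantile
normalization → k-nearest-neighbour imputation → surrogate variable
estimation and removal → Mahalanobis outlier screen on the first two
principal components (one re-run without flagged samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics.pairwise import nan_euclidean_distances

from .design import Contrast, SampleDesign
from .errors import DesignError


# ---------------------------------------------------------------------------
# quantile normalization

def quantile_normalize(X: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) of a log2 matrix.

    Complete data: every column's sorted values become the across-column
    mean of order statistics.  Missing entries are excluded from rank
    pooling and stay missing; observed entries map onto the reference
    distribution by interpolated rank, so columns with different numbers
    of observations share one reference.
    """
    X = np.asarray(X, dtype=float)
    n_feat, n_samp = X.shape
    if n_samp < 2:
        warnings.warn("quantile normalization needs >=2 samples; returning input")
        return X.copy()

    grid = np.linspace(0.0, 1.0, n_feat)
    ref = np.zeros(n_feat)
    n_used = 0
    for j in range(n_samp):
        col = X[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if obs.size == 0:
            continue
        if obs.size == 1:
            ref += obs[0]
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, obs.size), obs)
        n_used += 1
    if n_used == 0:
        return X.copy()
    ref /= n_used

    out = np.full_like(X, np.nan)
    for j in range(n_samp):
        col = X[:, j]
        mask = ~np.isnan(col)
        m = mask.sum()
        if m == 0:
            continue
        if m == 1:
            # single observation maps to the reference median
            out[mask, j] = np.interp(0.5, grid, ref)
            continue
        ranks = stats.rankdata(col[mask], method="average")  # 1..m, ties averaged
        q = (ranks - 1.0) / (m - 1.0)
        out[mask, j] = np.interp(q, grid, ref)
    return out


# ---------------------------------------------------------------------------
# missingness filter

def filter_missingness(
    X: np.ndarray,
    design: SampleDesign,
    contrasts: list[Contrast],
    max_group_frac: float = 0.25,
) -> np.ndarray:
    """Boolean keep-mask: a feature is kept iff, in every group required by
    the requested contrasts, its missing fraction is <= max_group_frac."""
    X = np.asarray(X, dtype=float)
    needed: list[tuple[str, str]] = []
    for c in contrasts:
        for g in (c.treatment, c.control):
            if (c.plex, g) not in needed:
                needed.append((c.plex, g))
    keep = np.ones(X.shape[0], dtype=bool)
    for plex, grp in needed:
        idx = design.indices(plex=plex, group=grp)
        if idx.size == 0:
            raise DesignError(f"no samples for group {grp!r} in plex {plex!r}")
        frac = np.isnan(X[:, idx]).mean(axis=1)
        keep &= frac <= max_group_frac + 1e-12
    return keep


# ---------------------------------------------------------------------------
# kNN imputation

def knn_impute(X: np.ndarray, k: int = 10) -> np.ndarray:
    """Row-wise k-nearest-neighbour imputation (Troyanskaya-style).

    Each missing entry is replaced by the unweighted mean, over the k
    nearest feature rows by Euclidean distance on co-observed samples, of
    those rows' values at the missing sample.  Neighbours must be observed
    at that sample; with fewer than k candidates all are used, and with
    none the feature's own row mean is imputed.  Observed entries are
    never altered.
    """
    X = np.asarray(X, dtype=float)
    out = X.copy()
    miss_rows = np.where(np.isnan(X).any(axis=1))[0]
    if miss_rows.size == 0:
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN pair distances
        D = nan_euclidean_distances(X[miss_rows], X)
    observed = ~np.isnan(X)
    for r, i in enumerate(miss_rows):
        d = D[r].copy()
        d[i] = np.inf  # not its own neighbour
        for j in np.where(np.isnan(X[i]))[0]:
            cand = np.where(observed[:, j] & np.isfinite(d))[0]
            if cand.size == 0:
                row = X[i][~np.isnan(X[i])]
                out[i, j] = row.mean() if row.size else 0.0
                continue
            kk = min(k, cand.size)
            nearest = cand[np.argpartition(d[cand], kk - 1)[:kk]]
            out[i, j] = X[nearest, j].mean()
    return out


# ---------------------------------------------------------------------------
# surrogate variable analysis

def _model_matrix(design: SampleDesign, plex: str | None = None) -> np.ndarray:
    """Group-means model matrix (one-hot over groups) for samples of a plex."""
    labels = design.group_labels(plex)
    groups = sorted(set(labels))
    M = np.zeros((len(labels), len(groups)))
    for i, lab in enumerate(labels):
        M[i, groups.index(lab)] = 1.0
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise DesignError("design matrix is rank-deficient")
    return M


def _residuals(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    H = M @ np.linalg.pinv(M)
    return X - X @ H.T


def num_surrogates(
    X: np.ndarray,
    M: np.ndarray,
    n_perm: int = 25,
    alpha: float = 0.10,
    seed: int = 0,
) -> int:
    """Permutation (Buja–Eyuboglu) significance of residual eigenvalues.

    Residual rows are independently permuted to build a null for each
    component's variance-explained fraction; components are accepted while
    their permutation p-value is <= alpha, stopping at the first failure.
    """
    R = _residuals(X, M)
    sv = np.linalg.svd(R, compute_uv=False)
    tot = (sv**2).sum()
    if tot <= 0:
        return 0
    stat = sv**2 / tot
    rng = np.random.default_rng(seed)
    max_k = len(sv)
    null = np.empty((n_perm, max_k))
    for b in range(n_perm):
        Rp = rng.permuted(R, axis=1)
        Rp = _residuals(Rp, M)
        svp = np.linalg.svd(Rp, compute_uv=False)
        null[b] = svp**2 / (svp**2).sum()
    n_sv = 0
    for kcomp in range(max_k):
        p = (1 + (null[:, kcomp] >= stat[kcomp]).sum()) / (n_perm + 1)
        if p <= alpha:
            n_sv += 1
        else:
            break
    return n_sv


def estimate_surrogate_variables(
    X: np.ndarray,
    design: SampleDesign,
    plex: str | None = None,
    n_sv: int | None = None,
    n_perm: int = 25,
    alpha: float = 0.10,
    seed: int = 0,
) -> np.ndarray:
    """Two-step residual-SVD surrogate estimation.

    Step 1: right singular vectors of the residual matrix propose candidate
    surrogates; being built from residuals they are orthogonal to the
    primary design, so a technical factor fully aligned with the design is
    never proposed (it is unidentifiable and must not be absorbed).
    Step 2: each candidate is re-estimated from the raw (row-centered)
    sub-matrix of the features most associated with it.  Re-estimation on
    raw data lets a *partially* design-aligned factor be recovered in
    full, so that the joint regression in :func:`remove_surrogates` can
    de-bias the design coefficients.  Returns a (samples × n_sv) matrix
    (possibly 0 columns).
    """
    M = _model_matrix(design, plex)
    X = np.asarray(X, dtype=float)
    if n_sv is None:
        n_sv = num_surrogates(X, M, n_perm=n_perm, alpha=alpha, seed=seed)
    if n_sv == 0:
        return np.empty((X.shape[1], 0))
    R = _residuals(X, M)
    _, _, Vt = np.linalg.svd(R, full_matrices=False)
    svs = []
    for kcomp in range(min(n_sv, Vt.shape[0])):
        v = Vt[kcomp]
        # association of each feature's residual profile with the eigen-sample
        denom = np.linalg.norm(R, axis=1) * np.linalg.norm(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(R @ v) / np.where(denom > 0, denom, np.inf)
        cutoff = np.quantile(r[np.isfinite(r)], 0.90) if np.isfinite(r).any() else 0
        sub = X[r >= cutoff]
        if sub.shape[0] >= 2:
            sub = sub - sub.mean(axis=1, keepdims=True)
            _, _, Vt_sub = np.linalg.svd(sub, full_matrices=False)
            # pick the sub-matrix singular vector best aligned with the
            # residual eigen-sample
            align = np.abs(Vt_sub @ v)
            z = Vt_sub[int(np.argmax(align))]
        else:
            z = v
        nz = np.linalg.norm(z)
        if nz > 1e-12:
            svs.append(z / nz)
    if not svs:
        return np.empty((X.shape[1], 0))
    return np.column_stack(svs)


def remove_surrogates(
    X: np.ndarray, design: SampleDesign, svs: np.ndarray, plex: str | None = None
) -> np.ndarray:
    """Regress surrogate components out of the data, protecting the primary
    design: the joint fit on [design | surrogates] is computed and only the
    surrogate part is subtracted."""
    if svs.size == 0:
        return np.asarray(X, dtype=float).copy()
    M = _model_matrix(design, plex)
    D = np.column_stack([M, svs])
    B = X @ np.linalg.pinv(D).T  # features × (p + q) coefficients
    return X - B[:, M.shape[1]:] @ svs.T


# ---------------------------------------------------------------------------
# outlier samples

def detect_outlier_samples(
    X: np.ndarray, n_pcs: int = 2, alpha: float = 1e-4
) -> np.ndarray:
    """Indices of samples whose squared Mahalanobis distance in the first
    n_pcs principal components exceeds the chi-square(n_pcs) quantile at
    1 - alpha.

    Each sample's distance uses the leave-one-out mean and covariance of
    the remaining scores: with ~11 samples a covariance that includes the
    candidate caps the classical distance at (n-1)^2/n, below the 1-1e-4
    chi-square quantile, so an in-sample estimate could never flag anything
    (the masking effect).  A singular covariance yields no flags."""
    X = np.asarray(X, dtype=float)
    n_samp = X.shape[1]
    if n_samp < n_pcs + 2:
        raise DesignError(f"need at least {n_pcs + 2} samples for outlier screen")
    A = X.T - X.mean(axis=1)  # samples × features, feature-centered
    U, S, _ = np.linalg.svd(A, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    thresh = stats.chi2.ppf(1.0 - alpha, df=n_pcs)
    flagged = []
    for i in range(n_samp):
        others = np.delete(scores, i, axis=0)
        mu = others.mean(axis=0)
        cov = np.cov(others, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        if np.linalg.matrix_rank(cov) < n_pcs or np.linalg.det(cov) <= 1e-300:
            warnings.warn("singular PC-space covariance; no outliers flagged")
            return np.array([], dtype=int)
        diff = scores[i] - mu
        d2 = float(diff @ np.linalg.solve(cov, diff))
        if d2 > thresh:
            flagged.append(i)
    return np.asarray(flagged, dtype=int)


# ---------------------------------------------------------------------------
# orchestration for one plex

@dataclass
class PreprocessResult:
    matrix: np.ndarray              # complete, corrected (features × samples)
    feature_ids: list[str]
    design: SampleDesign            # samples actually used (outliers removed)
    surrogates: np.ndarray
    removed_samples: list[str] = field(default_factory=list)
    n_sv: int = 0


def preprocess_plex(
    X: np.ndarray,
    feature_ids: list[str],
    design: SampleDesign,
    plex: str,
    max_group_frac: float = 0.25,
    impute_k: int = 10,
    sva_mode: str = "regress",
    n_sv: int | None = None,
    outlier_alpha: float = 1e-4,
    outlier_n_pcs: int = 2,
    seed: int = 0,
    _rerun: bool = False,
) -> PreprocessResult:
    """Full preprocessing for the samples of one plex.

    One outlier-triggered re-run is performed: if the Mahalanobis screen
    flags samples, they are dropped and the chain re-executes once from
    the missingness filter.
    """
    sub = design.subset(plex=plex)
    contrasts = sub.contrasts_for_plex(plex)
    keep = filter_missingness(X, sub, contrasts, max_group_frac)
    Xf = X[keep]
    ids = [fid for fid, k in zip(feature_ids, keep) if k]
    Xn = quantile_normalize(Xf)
    Xi = knn_impute(Xn, k=impute_k)
    svs = estimate_surrogate_variables(Xi, sub, plex=plex, n_sv=n_sv, seed=seed)
    Xc = remove_surrogates(Xi, sub, svs, plex=plex) if sva_mode == "regress" else Xi
    flagged = detect_outlier_samples(Xc, n_pcs=outlier_n_pcs, alpha=outlier_alpha)
    if flagged.size > 0 and not _rerun:
        removed = [sub.sample_ids[i] for i in flagged]
        design2 = sub.subset(exclude=set(removed))
        col_keep = [i for i, sid in enumerate(sub.sample_ids) if sid not in removed]
        res = preprocess_plex(
            X[:, col_keep], feature_ids, design2, plex,
            max_group_frac=max_group_frac, impute_k=impute_k, sva_mode=sva_mode,
            n_sv=n_sv, outlier_alpha=outlier_alpha, outlier_n_pcs=outlier_n_pcs,
            seed=seed, _rerun=True,
        )
        res.removed_samples = removed
        return res
    return PreprocessResult(
        matrix=Xc, feature_ids=ids, design=sub, surrogates=svs,
        removed_samples=[], n_sv=svs.shape[1],
    )
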