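"""Kinase-activity inference from substrate motifs (swing statistic).

A position weight matrix (PWM) is built for each kinase from the 15-mer
sequence windows of its curated substrates.  Every detected phosphopeptide
window of the compatible residue class (Ser/Thr vs Tyr acceptor) is scored
against every PWM as a log2 likelihood ratio to a background composition,
and calibrated into an empirical match p-value against scores of windows
sampled from all detected phosphopeptides.  Matches at p <= 0.05 become
edges of a bipartite kinase-substrate network.

Per kinase, the swing statistic contrasts the proportions of its modeled
substrates that increase vs decrease significantly (raw differential
p <= 0.05), weighted by network degree and by the number of substrate
sequences behind the PWM:

    swing_raw = (p_pos - p_neg) * ln(n_edges + 1) * ln(n_seqs + 1)

Swing values are z-transformed across kinases; significance comes from a
degree-preserving permutation that reassigns each kinase's edges to random
substrates of the network, with one p-value per tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
WINDOW_LEN = 15
CENTER = WINDOW_LEN // 2

#: residue classes; kinases with dual specificity are modeled once per class
SER_THR = "ST"
TYR = "Y"


def encode_windows(windows: list[str]) -> np.ndarray:
    """Integer-encode 15-mers; '_' (and any non-standard letter) -> -1."""
    out = np.full((len(windows), WINDOW_LEN), -1, dtype=np.int64)
    for i, w in enumerate(windows):
        if len(w) != WINDOW_LEN:
            raise FormatError(f"window {w!r} is not {WINDOW_LEN} residues")
        for j, ch in enumerate(w):
            out[i, j] = AA_INDEX.get(ch, -1)
    return out


def window_residue_class(window: str) -> str | None:
    c = window[CENTER]
    if c in SER_THR:
        return SER_THR
    if c == TYR:
        return TYR
    return None


@dataclass
class KinasePWM:
    kinase: str
    residue_class: str
    freq: np.ndarray        # 20 x 15 probabilities, columns sum to 1
    background: np.ndarray  # 20 probabilities
    n_seqs: int

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.freq / self.background[:, None])


def build_pwm(
    substrate_windows: list[str],
    kinase: str,
    residue_class: str = SER_THR,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> KinasePWM:
    """freq[a, j] = (count_{a,j} + pseudocount) / (n_seqs + 20*pseudocount);
    '_' contributes to no count.  Duplicated windows count each time."""
    enc = encode_windows(substrate_windows)
    n_seqs = enc.shape[0]
    if n_seqs == 0:
        raise FormatError(f"kinase {kinase}: no substrate windows")
    counts = np.zeros((20, WINDOW_LEN))
    for j in range(WINDOW_LEN):
        col = enc[:, j]
        col = col[col >= 0]
        np.add.at(counts[:, j], col, 1.0)
    freq = (counts + pseudocount) / (n_seqs + 20.0 * pseudocount)
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    return KinasePWM(kinase, residue_class, freq, np.asarray(background, float), n_seqs)


def score_window(pwm: KinasePWM, window: str) -> float:
    """Sum over positions of log2(freq/background); padded positions add 0.
    Returns NaN when the center residue is incompatible with the PWM class."""
    if window_residue_class(window) != pwm.residue_class:
        return float("nan")
    return float(score_encoded(pwm, encode_windows([window]))[0])


def score_encoded(pwm: KinasePWM, enc: np.ndarray) -> np.ndarray:
    """Vectorized scoring of pre-encoded windows (no class gate)."""
    lo = pwm.log_odds  # 20 x 15
    padded = np.vstack([lo, np.zeros((1, WINDOW_LEN))])  # index -1 -> 0
    return padded[enc, np.arange(WINDOW_LEN)].sum(axis=1)


def empirical_match_pvalues(
    scores: np.ndarray, background_scores: np.ndarray
) -> np.ndarray:
    """Add-one empirical p: (1 + #{bg >= s}) / (n_bg + 1)."""
    bg = np.sort(background_scores)
    n = bg.size
    ge = n - np.searchsorted(bg, scores, side="left")
    return (1.0 + ge) / (n + 1.0)


def match_pvalue(
    pwm: KinasePWM,
    window: str,
    background_windows: list[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical match p-value of one window against a seeded background
    sample of detected windows (with replacement iff the pool is smaller
    than n_draws)."""
    rng = np.random.default_rng(seed)
    bg_scores = _background_scores(pwm, background_windows, n_draws, rng)
    s = score_window(pwm, window)
    if np.isnan(s):
        return float("nan")
    return float(empirical_match_pvalues(np.array([s]), bg_scores)[0])


def _background_scores(pwm, background_windows, n_draws, rng) -> np.ndarray:
    pool = encode_windows(background_windows)
    replace = pool.shape[0] < n_draws
    idx = rng.choice(pool.shape[0], size=n_draws, replace=replace)
    return score_encoded(pwm, pool[idx])


# ---------------------------------------------------------------------------
# network construction

def build_network(
    pwms: list[KinasePWM],
    feature_ids: list[str],
    feature_windows: list[str],
    edge_p_threshold: float = 0.05,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every feature's first-site window against every compatible PWM
    and keep matches at p <= edge_p_threshold as kinase-substrate edges.

    Background pools are the detected windows of the matching residue
    class; one seeded sample per kinase.  Columns: kinase, feature_id,
    match_score, match_p.
    """
    classes = np.array(
        [window_residue_class(w) or "none" for w in feature_windows]
    )
    enc_all = encode_windows(feature_windows)
    ids = np.asarray(feature_ids)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(pwms))
    rows = []
    for pwm, cs in zip(pwms, child_seeds):
        mask = classes == pwm.residue_class
        if not mask.any():
            continue
        rng = np.random.default_rng(cs)
        pool = enc_all[mask]
        replace = pool.shape[0] < n_draws
        idx = rng.choice(pool.shape[0], size=n_draws, replace=replace)
        bg_scores = score_encoded(pwm, pool[idx])
        scores = score_encoded(pwm, enc_all[mask])
        pvals = empirical_match_pvalues(scores, bg_scores)
        hit = pvals <= edge_p_threshold
        for fid, s, p in zip(ids[mask][hit], scores[hit], pvals[hit]):
            rows.append((pwm.kinase, fid, float(s), float(p)))
    return pd.DataFrame(rows, columns=["kinase", "feature_id", "match_score", "match_p"])


# ---------------------------------------------------------------------------
# swing statistic

def compute_swing(
    network: pd.DataFrame,
    diff_results: pd.DataFrame,
    pwms: list[KinasePWM],
    fc_p_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Swing statistic, z-transform and degree-preserving permutation
    significance for each kinase of the network.

    Substrate significance uses the raw differential p (p <= threshold)
    with the sign of the log2 fold change.  The permutation null keeps
    each kinase's edge count and resamples its substrate endpoints without
    replacement from the network's substrate pool; permuted swings are
    z-transformed within each permutation and the observed z is compared
    to the null per tail.
    """
    if network.empty:
        return pd.DataFrame(
            columns=["kinase", "n_edges", "n_pos", "n_neg", "p_pos_frac",
                     "p_neg_frac", "swing_raw", "z", "perm_p_pos",
                     "perm_p_neg", "n_perm"]
        )
    n_seqs = {p.kinase: p.n_seqs for p in pwms}
    dr = diff_results.set_index("feature_id")
    substrates = network["feature_id"].unique()
    lfc = dr["log2fc"].reindex(substrates).to_numpy()
    praw = dr["p"].reindex(substrates).to_numpy()
    sig = praw <= fc_p_threshold
    is_pos = sig & (lfc > 0)
    is_neg = sig & (lfc < 0)
    sub_index = {s: i for i, s in enumerate(substrates)}

    kinases, degrees, npos, nneg, weights = [], [], [], [], []
    for kin, grp in network.groupby("kinase", sort=True):
        idx = np.array([sub_index[s] for s in grp["feature_id"]])
        m = idx.size
        if m == 0:
            continue
        kinases.append(kin)
        degrees.append(m)
        npos.append(int(is_pos[idx].sum()))
        nneg.append(int(is_neg[idx].sum()))
        weights.append(np.log(m + 1.0) * np.log(n_seqs.get(kin, 1) + 1.0))
    degrees = np.asarray(degrees)
    npos_a = np.asarray(npos, dtype=float)
    nneg_a = np.asarray(nneg, dtype=float)
    weights = np.asarray(weights)
    ppos = npos_a / degrees
    pneg = nneg_a / degrees
    swing_raw = (ppos - pneg) * weights

    sd = swing_raw.std(ddof=1) if len(kinases) > 1 else 0.0
    if sd <= 0:
        raise ValueError("swing SD across kinases is zero; z undefined")
    z = (swing_raw - swing_raw.mean()) / sd

    # permutation null: multivariate hypergeometric draw of (pos, neg, rest)
    # is equivalent to sampling substrates without replacement
    rng = np.random.default_rng(seed)
    pool = np.array([int(is_pos.sum()), int(is_neg.sum()),
                     int(len(substrates) - is_pos.sum() - is_neg.sum())])
    n_kin = len(kinases)
    perm_z_ge = np.zeros(n_kin)
    perm_z_le = np.zeros(n_kin)
    for _ in range(n_perm):
        draws = np.array(
            [rng.multivariate_hypergeometric(pool, int(m)) for m in degrees]
        )
        ps = (draws[:, 0] - draws[:, 1]) / degrees * weights
        psd = ps.std(ddof=1)
        if psd <= 0:
            pz = np.zeros(n_kin)
        else:
            pz = (ps - ps.mean()) / psd
        perm_z_ge += pz >= z
        perm_z_le += pz <= z
    perm_p_pos = (1.0 + perm_z_ge) / (n_perm + 1.0)
    perm_p_neg = (1.0 + perm_z_le) / (n_perm + 1.0)

    return pd.DataFrame(
        {
            "kinase": kinases,
            "n_edges": degrees,
            "n_pos": npos,
            "n_neg": nneg,
            "p_pos_frac": ppos,
            "p_neg_frac": pneg,
            "swing_raw": swing_raw,
            "z": z,
            "perm_p_pos": perm_p_pos,
            "perm_p_neg": perm_p_neg,
            "n_perm": n_perm,
        }
    )


# ---------------------------------------------------------------------------
# known-substrate validation

CORE_FLANK = 4


def window_core(window: str) -> str:
    """±4-residue core of a 15-mer window (positions 3..11 inclusive)."""
    return window[CENTER - CORE_FLANK: CENTER + CORE_FLANK + 1]


def load_kinase_substrate_db(path) -> pd.DataFrame:
    """Tab-separated flat file with columns KINASE_GENE, SUB_GENE, SUB_POS,
    SITE_WINDOW (PhosphoSitePlus-style ±7 window)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"KINASE_GENE", "SUB_GENE", "SUB_POS", "SITE_WINDOW"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"kinase-substrate file lacks columns {sorted(missing)}")
    return df


def known_substrate_average(
    diff_results: pd.DataFrame,
    features: pd.DataFrame,
    ks_db: pd.DataFrame,
    min_substrates: int = 4,
) -> pd.Series:
    """Per-kinase mean of significant substrate log2 fold changes.

    Substrates match on identical gene name and identical ±4 window core
    (multi-phosphopeptides via the first site's window); duplicate
    (gene, window) database pairs are counted once; kinases with fewer
    than `min_substrates` matched significant substrates are dropped.

    `features` needs columns feature_id, gene, window.
    """
    db = ks_db.copy()
    db["core"] = [window_core(w) for w in db["SITE_WINDOW"]]
    db = db.drop_duplicates(subset=["KINASE_GENE", "SUB_GENE", "core"])

    feats = features.copy()
    feats["core"] = [window_core(w) for w in feats["window"]]
    sig_col = (
        "significant_filtered"
        if "significant_filtered" in diff_results.columns
        else "significant"
    )
    sig = diff_results[diff_results[sig_col]][["feature_id", "log2fc"]]
    feats = feats.merge(sig, on="feature_id", how="inner")

    merged = db.merge(
        feats, left_on=["SUB_GENE", "core"], right_on=["gene", "core"], how="inner"
    )
    # a feature contributes once per kinase even if several db rows match it
    merged = merged.drop_duplicates(subset=["KINASE_GENE", "feature_id"])
    counts = merged.groupby("KINASE_GENE")["log2fc"].agg(["mean", "count"])
    keep = counts[counts["count"] >= min_substrates]
    return keep["mean"].rename("mean_sig_log2fc")
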