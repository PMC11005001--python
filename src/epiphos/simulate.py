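"""Synthetic two-plex TMT experiment with planted ground truth.

Emulates the processed-table structure of the study design: two 11-channel
plexes (3 untreated + 4 mock + 4 pilocarpine each, at 4 h and 24 h),
log2-normal reporter intensities, 20-30% missing values imposed
preferentially at low intensity (TMT phospho data are left-censored; an
MCAR mode exists for imputation unit tests), one orthogonal batch vector
per plex, localization probabilities with a configurable failing fraction,
duplicate peptide forms, kinase-motif-coherent substrate windows, and
protein-level confounds that shift a gene's protein feature together with
all of its phosphopeptides.

Everything planted (feature effects, kinase activations, protein changes,
batch vectors) is recorded in a GroundTruth mapping serialized with each
generated dataset, so every pipeline stage can be scored against the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SampleDesign
from .ingest import make_feature_id, window_from_sequence

AA = "ACDEFGHIKLMNPQRSTVWY"
FUNCTIONS = (
    "translation", "apoptosis", "cell growth", "transcription",
    "cell motility", "cell differentiation",
)
SLOT_SPACING = 24  # residues between site slots within a protein
FIRST_SLOT = 12    # 1-based center of the first slot (>= 8 avoids padding)


@dataclass
class PlantedEffect:
    features: list[int]
    log2fc: float
    plex: str = "4h"
    group: str = "pilocarpine"


@dataclass
class KinaseActivation:
    kinase: int           # kinase index (0-based)
    log2fc: float
    n_substrates: int
    plex: str = "4h"


@dataclass
class ProteinChange:
    protein: int          # protein index (0-based)
    log2fc: float
    plex: str = "24h"


@dataclass
class SimConfig:
    n_features: int = 5000
    n_proteins: int = 1200
    n_kinases: int = 30
    baseline_mean: float = 20.0
    baseline_sd: float = 1.5
    within_sd: float = 0.5          # within-group log2 SD
    missing_rate: float = 0.25
    mcar: bool = False
    missing_steepness: float = 1.5  # logistic slope on standardized intensity
    n_batch: int = 1
    batch_magnitude: float = 0.5
    batch_frac: float = 0.4
    multiplicity2_frac: float = 0.15
    duplicate_frac: float = 0.10
    loc_fail_frac: float = 0.10
    tyr_frac: float = 0.08
    n_db_substrates: int = 30
    motif_noise: float = 0.2
    protein_missing_rate: float = 0.05
    protein_within_sd: float = 0.3
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    planted_kinases: list[KinaseActivation] = field(default_factory=list)
    planted_proteins: list[ProteinChange] = field(default_factory=list)


def default_config() -> SimConfig:
    """Study-condition defaults with planted truth exercising every stage:
    up/down effects at 4 h with a persistent subset at 24 h, one activated
    and one deactivated kinase, and protein-level confounds at 24 h."""
    return SimConfig(
        planted_effects=[
            PlantedEffect(list(range(0, 250)), +1.0, "4h"),
            PlantedEffect(list(range(250, 450)), -1.0, "4h"),
            PlantedEffect(list(range(0, 120)), +1.0, "24h"),
            PlantedEffect(list(range(450, 550)), +0.8, "24h"),
        ],
        planted_kinases=[
            KinaseActivation(0, +1.0, 40, "4h"),
            KinaseActivation(1, -1.0, 40, "24h"),
        ],
        planted_proteins=(
            [ProteinChange(p, +0.8, "24h") for p in range(700, 715)]
            + [ProteinChange(p, -0.8, "24h") for p in range(715, 730)]
        ),
    )


# ---------------------------------------------------------------------------
# kinase motifs and flat files

def _kinase_names(config: SimConfig) -> list[str]:
    return [f"KIN{i + 1:02d}" for i in range(config.n_kinases)]


def kinase_motifs(config: SimConfig, seed: int) -> dict[str, tuple[str, str]]:
    """kinase -> (consensus 15-mer, residue class); deterministic in seed.
    Every tenth kinase is Tyr-class, the rest Ser/Thr."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    motifs = {}
    for i, name in enumerate(_kinase_names(config)):
        cls = "Y" if (i + 1) % 10 == 0 else "ST"
        center = "Y" if cls == "Y" else str(rng.choice(["S", "T"]))
        flanks = rng.choice(list(AA), size=14)
        consensus = "".join(flanks[:7]) + center + "".join(flanks[7:])
        motifs[name] = (consensus, cls)
    return motifs


def _noisy_window(consensus: str, noise: float, rng) -> str:
    out = list(consensus)
    for j in range(len(out)):
        if j == 7:
            continue
        if rng.random() < noise:
            out[j] = str(rng.choice(list(AA)))
    return "".join(out)


def generate_kinase_db(config: SimConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kinase-substrate and regulatory-site flat files (as DataFrames).

    Each kinase's curated substrates are noisy draws from its consensus;
    regulatory sites get random windows, functions and directions."""
    motifs = kinase_motifs(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    rows = []
    for name, (consensus, _cls) in motifs.items():
        for k in range(config.n_db_substrates):
            win = _noisy_window(consensus, config.motif_noise, rng)
            rows.append(
                (name, f"DBGENE{rng.integers(1, 5000):05d}",
                 int(rng.integers(10, 900)), win)
            )
    ks = pd.DataFrame(rows, columns=["KINASE_GENE", "SUB_GENE", "SUB_POS", "SITE_WINDOW"])

    reg_rows = []
    for _ in range(200):
        center = str(rng.choice(["S", "T", "Y"], p=[0.6, 0.3, 0.1]))
        flanks = rng.choice(list(AA), size=14)
        win = "".join(flanks[:7]) + center + "".join(flanks[7:])
        reg_rows.append(
            (f"DBGENE{rng.integers(1, 5000):05d}", int(rng.integers(10, 900)),
             win, str(rng.choice(FUNCTIONS)),
             str(rng.choice(["induced", "inhibited"])))
        )
    reg = pd.DataFrame(
        reg_rows, columns=["GENE", "POS", "SITE_WINDOW", "FUNCTION", "DIRECTION"]
    )
    return ks, reg


# ---------------------------------------------------------------------------
# experiment generation

@dataclass
class SimulatedExperiment:
    phospho_table: pd.DataFrame
    protein_table: pd.DataFrame
    fasta: dict[str, str]
    design: SampleDesign
    ground_truth: dict

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "phospho": out / "phospho_sites.tsv",
            "protein": out / "protein_groups.tsv",
            "fasta": out / "proteome.fasta",
            "design": out / "design.tsv",
            "ground_truth": out / "ground_truth.json",
        }
        self.phospho_table.to_csv(paths["phospho"], sep="\t", index=False)
        self.protein_table.to_csv(paths["protein"], sep="\t", index=False)
        with open(paths["fasta"], "w") as fh:
            for acc in sorted(self.fasta):
                fh.write(f">{acc}\n{self.fasta[acc]}\n")
        self.design.to_tsv(paths["design"])
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        return paths


def _batch_vector(design: SampleDesign, plex: str, rng) -> np.ndarray:
    """Within-group-centered ±1 vector, orthogonal to the group factor."""
    sub = design.subset(plex=plex)
    v = np.zeros(len(sub))
    for grp in set(s.group for s in sub.samples):
        idx = sub.indices(group=grp)
        signs = np.ones(idx.size)
        signs[1::2] = -1.0
        v[idx] = signs - signs.mean()
    return v


def generate_experiment(config: SimConfig, seed: int) -> SimulatedExperiment:
    """Full synthetic dataset: phosphosite table, protein table, FASTA,
    design and ground truth, deterministic in (config, seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    design = SampleDesign.default()
    n_feat, n_prot = config.n_features, config.n_proteins
    for eff in config.planted_effects:
        if any(f < 0 or f >= n_feat for f in eff.features):
            raise ValueError("planted feature index out of range")
    for act in config.planted_kinases:
        if not 0 <= act.kinase < config.n_kinases:
            raise ValueError("planted kinase index out of range")
    for pc in config.planted_proteins:
        if not 0 <= pc.protein < n_prot:
            raise ValueError("planted protein index out of range")
    motifs = kinase_motifs(config, seed)
    kin_names = _kinase_names(config)

    # --- assign features to proteins and site slots -----------------------
    prot_of = np.arange(n_feat) % n_prot
    slot_of = np.arange(n_feat) // n_prot
    genes = [f"GENE{p + 1:04d}" for p in range(n_prot)]
    accessions = [f"SYN|P{p + 1:05d}|{genes[p]}" for p in range(n_prot)]

    # index sets for special feature roles (kept disjoint from planted
    # effect/substrate indices, which default_config puts below 1000)
    planted_idx: set[int] = set()
    for eff in config.planted_effects:
        planted_idx.update(eff.features)
    substrate_ids: dict[int, list[int]] = {}
    cursor = 600
    for act in config.planted_kinases:
        substrate_ids[act.kinase] = list(range(cursor, cursor + act.n_substrates))
        cursor += act.n_substrates
    reserved = set(planted_idx)
    for ids in substrate_ids.values():
        reserved.update(ids)
    prot_change_feats: set[int] = set()
    for pc in config.planted_proteins:
        prot_change_feats.update(np.where(prot_of == pc.protein)[0].tolist())
    reserved |= prot_change_feats

    free = np.array(sorted(set(range(n_feat)) - reserved))
    rng.shuffle(free)
    n_fail = int(round(config.loc_fail_frac * n_feat))
    n_tyr = int(round(config.tyr_frac * n_feat))
    n_mult = int(round(config.multiplicity2_frac * n_feat))
    loc_fail = set(free[:n_fail].tolist())
    tyr_set = set(free[n_fail:n_fail + n_tyr].tolist())
    mult_set = set(free[n_fail + n_tyr:n_fail + n_tyr + n_mult].tolist())

    # --- windows ----------------------------------------------------------
    windows1 = []
    for f in range(n_feat):
        owner_kin = next((k for k, ids in substrate_ids.items() if f in ids), None)
        if owner_kin is not None:
            # substrate windows are noisy draws from the kinase's consensus
            consensus, _cls = motifs[kin_names[owner_kin]]
            win = _noisy_window(consensus, config.motif_noise, rng)
        else:
            center = "Y" if f in tyr_set else str(rng.choice(["S", "T"], p=[0.7, 0.3]))
            flanks = rng.choice(list(AA), size=14)
            win = "".join(flanks[:7]) + center + "".join(flanks[7:])
        windows1.append(win)

    positions1 = FIRST_SLOT + SLOT_SPACING * slot_of  # 1-based centers
    positions2 = positions1 + 3                        # secondary site of 2-phospho

    # --- protein sequences with windows spliced in ------------------------
    max_slot = np.zeros(n_prot, dtype=int)
    for f in range(n_feat):
        max_slot[prot_of[f]] = max(max_slot[prot_of[f]], slot_of[f])
    seqs = []
    for p in range(n_prot):
        length = FIRST_SLOT + SLOT_SPACING * max_slot[p] + 16
        seqs.append(list(rng.choice(list(AA), size=length)))
    for f in range(n_feat):
        p, pos = prot_of[f], positions1[f]
        seqs[p][pos - 8: pos + 7] = list(windows1[f])
        if f in mult_set:
            seqs[p][positions2[f] - 1] = "S"
    fasta = {accessions[p]: "".join(seqs[p]) for p in range(n_prot)}

    # recompute windows from the final sequence (splices may overlap-free by
    # slot spacing, but the secondary-site write can touch a window tail)
    windows1 = [
        window_from_sequence(fasta[accessions[prot_of[f]]], int(positions1[f]))
        for f in range(n_feat)
    ]
    windows2 = {
        f: window_from_sequence(fasta[accessions[prot_of[f]]], int(positions2[f]))
        for f in mult_set
    }
    residues1 = [windows1[f][7] for f in range(n_feat)]

    # --- log2 intensity matrix -------------------------------------------
    n_samp = len(design)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_feat)
    X = baseline[:, None] + rng.normal(0.0, config.within_sd, size=(n_feat, n_samp))

    effect_of: dict[tuple[int, str], float] = {}  # (feature, plex) -> log2fc

    def add_effect(feats, log2fc, plex, group="pilocarpine"):
        cols = design.indices(plex=plex, group=group)
        for f in feats:
            X[f, cols] += log2fc
            key = (int(f), plex)
            effect_of[key] = effect_of.get(key, 0.0) + log2fc

    for eff in config.planted_effects:
        add_effect(eff.features, eff.log2fc, eff.plex, eff.group)
    for act in config.planted_kinases:
        add_effect(substrate_ids[act.kinase], act.log2fc, act.plex)
    for pc in config.planted_proteins:
        feats = np.where(prot_of == pc.protein)[0]
        add_effect(feats, pc.log2fc, pc.plex)

    batch_vectors = {}
    if config.n_batch > 0 and config.batch_magnitude != 0:
        affected = rng.random(n_feat) < config.batch_frac
        loadings = (
            config.batch_magnitude
            * rng.choice([-1.0, 1.0], size=n_feat)
            * affected
        )
        for plex in design.plexes:
            v = _batch_vector(design, plex, rng)
            cols = design.indices(plex=plex)
            X[:, cols] += loadings[:, None] * v[None, :]
            batch_vectors[plex] = v.tolist()
        batch_loadings = loadings
    else:
        batch_loadings = np.zeros(n_feat)

    # --- missingness ------------------------------------------------------
    if config.missing_rate > 0:
        if config.mcar:
            pmiss = np.full_like(X, config.missing_rate)
        else:
            z = (X - X.mean()) / X.std()
            b = config.missing_steepness
            # calibrate the logistic intercept so the mean rate matches
            lo, hi = -20.0, 20.0
            for _ in range(60):
                a = 0.5 * (lo + hi)
                rate = _expit(a - b * z).mean()
                if rate > config.missing_rate:
                    hi = a
                else:
                    lo = a
            pmiss = _expit(0.5 * (lo + hi) - b * z)
        miss_mask = rng.random(X.shape) < pmiss
    else:
        miss_mask = np.zeros(X.shape, dtype=bool)

    # --- localization probabilities --------------------------------------
    groups = sorted({s.group for s in design.samples})

    def probs_for(f: int) -> dict[str, list[float]]:
        n_sites = 2 if f in mult_set else 1
        fail = f in loc_fail
        out = {}
        best_group = int(rng.integers(0, len(groups)))
        for gi, g in enumerate(groups):
            ps = []
            if n_sites == 1:
                if fail:
                    ps.append(round(float(rng.uniform(0.30, 0.70)), 4))
                else:
                    lo_ = 0.76 if gi == best_group else 0.50
                    ps.append(round(float(rng.uniform(lo_, 1.0)), 4))
            else:
                # primary always > 0.5; secondary carries the evidence
                ps.append(round(float(rng.uniform(0.55, 1.0)), 4))
                if fail:
                    ps.append(round(float(rng.uniform(0.30, 0.70)), 4))
                else:
                    lo_ = 0.76 if gi == best_group else 0.40
                    ps.append(round(float(rng.uniform(lo_, 1.0)), 4))
            out[g] = ps
        return out

    # --- assemble the phosphosite table -----------------------------------
    dup_set = set(
        free[n_fail + n_tyr + n_mult:
             n_fail + n_tyr + n_mult + int(round(config.duplicate_frac * n_feat))]
        .tolist()
    )
    sample_ids = design.sample_ids
    rows = []
    feature_ids = []
    for f in range(n_feat):
        gene = genes[prot_of[f]]
        if f in mult_set:
            positions = [int(positions1[f]), int(positions2[f])]
            residues = [residues1[f], windows2[f][7]]
            wins = [windows1[f], windows2[f]]
            mult = 2
        else:
            positions = [int(positions1[f])]
            residues = [residues1[f]]
            wins = [windows1[f]]
            mult = 1
        feature_ids.append(make_feature_id(gene, positions, residues, mult))
        probs = probs_for(f)
        variants = [(2, 0.0)] if f not in dup_set else [(2, +0.05), (3, -0.05)]
        for charge, delta in variants:
            raw = np.where(miss_mask[f], 0.0, 2.0 ** (X[f] + delta))
            row = {
                "gene": gene,
                "protein": accessions[prot_of[f]],
                "positions": ";".join(str(p) for p in positions),
                "residues": ";".join(residues),
                "multiplicity": mult,
                "charge": charge,
                "windows": ";".join(wins),
                "reverse": "",
                "contaminant": "",
            }
            for g in groups:
                row[f"loc_prob_{g}"] = ";".join(f"{p:.4f}" for p in probs[g])
            for j, sid in enumerate(sample_ids):
                row[f"intensity_{sid}"] = f"{raw[j]:.4f}"
            rows.append(row)
    phospho_table = pd.DataFrame(rows)

    # --- protein table -----------------------------------------------------
    prot_base = rng.normal(config.baseline_mean, 1.0, size=n_prot)
    P = prot_base[:, None] + rng.normal(
        0.0, config.protein_within_sd, size=(n_prot, n_samp)
    )
    for pc in config.planted_proteins:
        cols = design.indices(plex=pc.plex, group="pilocarpine")
        P[pc.protein, cols] += pc.log2fc
    pmiss_mask = rng.random(P.shape) < config.protein_missing_rate
    prot_rows = []
    for p in range(n_prot):
        raw = np.where(pmiss_mask[p], 0.0, 2.0 ** P[p])
        row = {
            "protein_group_id": f"PG{p + 1:05d}",
            "genes": genes[p],
            "n_unique_peptides": int(rng.integers(1, 20)),
            "reverse": "",
            "contaminant": "",
        }
        for j, sid in enumerate(sample_ids):
            row[f"intensity_{sid}"] = f"{raw[j]:.4f}"
        prot_rows.append(row)
    protein_table = pd.DataFrame(prot_rows)

    # --- ground truth -------------------------------------------------------
    ground_truth = {
        "seed": seed,
        "generator_version": "0.1.0",
        "n_features": n_feat,
        "planted_effects": [
            {
                "feature_ids": [feature_ids[f] for f in eff.features],
                "log2fc": eff.log2fc,
                "plex": eff.plex,
                "group": eff.group,
            }
            for eff in config.planted_effects
        ],
        "planted_kinases": [
            {
                "kinase": kin_names[act.kinase],
                "log2fc": act.log2fc,
                "plex": act.plex,
                "n_substrates": act.n_substrates,
                "feature_ids": [feature_ids[f] for f in substrate_ids[act.kinase]],
            }
            for act in config.planted_kinases
        ],
        "planted_proteins": [
            {"gene": genes[pc.protein], "log2fc": pc.log2fc, "plex": pc.plex}
            for pc in config.planted_proteins
        ],
        "total_effect_by_feature_plex": {
            f"{feature_ids[f]}|{plex}": fc for (f, plex), fc in effect_of.items()
        },
        "batch_vectors": batch_vectors,
        "batch_loading_sd": float(np.std(batch_loadings)),
        "loc_fail_feature_ids": sorted(feature_ids[f] for f in loc_fail),
        "duplicate_feature_ids": sorted(feature_ids[f] for f in dup_set),
    }
    return SimulatedExperiment(phospho_table, protein_table, fasta, design, ground_truth)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# small matrices for module-level calibration and power studies

def simulate_two_group_matrix(
    n_features: int,
    n_per_group: int,
    effect_features: int = 0,
    log2fc: float = 0.0,
    sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Complete two-group matrix (control columns first): the first
    `effect_features` rows carry `log2fc` in the treatment group.  Returns
    (matrix, truth mask, feature ids)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(20.0, 1.0, size=(n_features, 1)) + rng.normal(
        0.0, sd, size=(n_features, 2 * n_per_group)
    )
    truth = np.zeros(n_features, dtype=bool)
    truth[:effect_features] = True
    X[truth, n_per_group:] += log2fc
    ids = [f"F{i:05d}" for i in range(n_features)]
    return X, truth, ids
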