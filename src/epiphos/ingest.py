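"""Parsing, re-annotation and collapsing of phosphosite-level search output.

The phosphosite table is a tab-separated export with one row per detected
phosphopeptide form (a peptide with a specific set of phosphorylated sites,
multiplicity and charge).  Rows carry the protein accession, gene symbol,
1-based site positions within the protein, site residues (S/T/Y), per-group
localization probabilities, the 15-residue sequence windows centered on each
site, and one reporter-ion intensity column per design sample.

Processing order mirrors the study's post-search pipeline: re-annotate site
windows against the search FASTA, apply the localization retention rule,
log2-transform (zero intensity is missing), then collapse duplicate peptide
forms to unique phosphopeptide features by the per-sample median.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

from .design import SampleDesign
from .errors import AccessionError, AnnotationConflictError, FormatError, DesignError

WINDOW_LEN = 15
WINDOW_FLANK = 7
PHOSPHO_RESIDUES = {"S", "T", "Y"}

#: Localization retention thresholds: a primary (class-1) site needs
#: probability > 0.5 on multi-phosphopeptides, with supporting evidence of
#: another site > 0.75 in at least one experimental group; singly
#: phosphorylated peptides need > 0.75 on their site.
PRIMARY_PROB_MULTI = 0.5
SECONDARY_PROB = 0.75
SINGLE_PROB = 0.75


@dataclass
class PhosphoSiteRecord:
    """One row of the phosphosite table (a peptide form, pre-collapsing)."""

    protein_accession: str
    gene: str
    positions: tuple[int, ...]
    residues: tuple[str, ...]
    multiplicity: int
    localization_probs: dict[str, tuple[float, ...]]  # group -> per-site max prob
    windows: tuple[str, ...]
    charge: int
    intensities: np.ndarray  # per design sample; NaN = missing

    def __post_init__(self):
        if not (len(self.positions) == len(self.residues) == len(self.windows)):
            raise FormatError(
                f"{self.gene}: positions/residues/windows length mismatch"
            )


@dataclass
class PhosphoFeature:
    """A unique phosphopeptide: (gene, site set, multiplicity) with one
    log2 intensity per design sample."""

    feature_id: str
    gene: str
    positions: tuple[int, ...]
    residues: tuple[str, ...]
    windows: tuple[str, ...]
    log2_intensity: np.ndarray

    @property
    def primary_window(self) -> str:
        """Window of the first phosphorylation site (used for all sequence
        matching of multi-phosphopeptides)."""
        return self.windows[0]


@dataclass
class ProteinFeature:
    protein_group_id: str
    genes: tuple[str, ...]
    log2_intensity: np.ndarray
    n_unique_peptides: int = 1

    @property
    def gene(self) -> str:
        return self.genes[0]


# ---------------------------------------------------------------------------
# parsing

_PHOSPHO_REQUIRED = ["gene", "protein", "positions", "residues", "multiplicity",
                     "charge", "windows"]


def _split(cell, cast=str):
    return tuple(cast(x) for x in str(cell).split(";"))


def parse_phospho_table(path, design: SampleDesign) -> list[PhosphoSiteRecord]:
    """Read the phosphosite table; zero/absent intensity becomes missing and
    reverse/contaminant rows are dropped."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _PHOSPHO_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"phosphosite table lacks mandatory column '{col}'")
    groups = sorted({s.group for s in design.samples})
    prob_cols = {g: f"loc_prob_{g}" for g in groups}
    for col in prob_cols.values():
        if col not in df.columns:
            raise FormatError(f"phosphosite table lacks mandatory column '{col}'")
    int_cols = [f"intensity_{sid}" for sid in design.sample_ids]
    missing_int = [c for c in int_cols if c not in df.columns]
    if missing_int:
        raise DesignError(
            f"intensity columns absent for design samples: {missing_int[:3]}"
            + ("..." if len(missing_int) > 3 else "")
        )

    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        if row.get("reverse", "") == "+" or row.get("contaminant", "") == "+":
            continue
        intens = np.array(
            [float(row[c]) if row[c] not in ("", "NA", "NaN") else np.nan
             for c in int_cols],
            dtype=float,
        )
        intens[intens == 0.0] = np.nan  # zero reporter intensity == missing
        positions = _split(row["positions"], int)
        probs = {
            g: _split(row[prob_cols[g]], float) for g in groups
        }
        for g, p in probs.items():
            if len(p) != len(positions):
                raise FormatError(
                    f"localization probabilities for group '{g}' do not match "
                    f"site count in row for {row['gene']}"
                )
        records.append(
            PhosphoSiteRecord(
                protein_accession=row["protein"],
                gene=row["gene"],
                positions=positions,
                residues=_split(row["residues"]),
                multiplicity=int(row["multiplicity"]),
                localization_probs=probs,
                windows=_split(row["windows"]),
                charge=int(row["charge"]),
                intensities=intens,
            )
        )
    return records


def parse_protein_table(path, design: SampleDesign) -> list[ProteinFeature]:
    """Read the protein-group table, log2-transform and deduplicate to one
    feature per representative gene (first listed gene wins; ties resolved
    by unique-peptide count)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein_group_id", "genes", "n_unique_peptides"):
        if col not in df.columns:
            raise FormatError(f"protein table lacks mandatory column '{col}'")
    int_cols = [f"intensity_{sid}" for sid in design.sample_ids]
    missing_int = [c for c in int_cols if c not in df.columns]
    if missing_int:
        raise DesignError(f"protein table lacks intensity columns: {missing_int[:3]}")

    feats: dict[str, ProteinFeature] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        if row.get("reverse", "") == "+" or row.get("contaminant", "") == "+":
            continue
        genes = _split(row["genes"])
        if not genes or not genes[0]:
            raise FormatError(f"protein group {row['protein_group_id']} has no gene")
        intens = np.array(
            [float(row[c]) if row[c] not in ("", "NA", "NaN") else np.nan
             for c in int_cols],
            dtype=float,
        )
        intens[intens == 0.0] = np.nan
        feat = ProteinFeature(
            protein_group_id=row["protein_group_id"],
            genes=genes,
            log2_intensity=np.log2(intens),
            n_unique_peptides=int(row["n_unique_peptides"]),
        )
        prev = feats.get(feat.gene)
        if prev is None or feat.n_unique_peptides > prev.n_unique_peptides:
            feats[feat.gene] = feat
    return list(feats.values())


# ---------------------------------------------------------------------------
# re-annotation

def load_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def window_from_sequence(seq: str, pos: int) -> str:
    """±7 window around 1-based position `pos`, '_'-padded at termini."""
    i = pos - 1
    left = seq[max(0, i - WINDOW_FLANK): i]
    right = seq[i + 1: i + 1 + WINDOW_FLANK]
    return ("_" * (WINDOW_FLANK - len(left)) + left + seq[i] + right
            + "_" * (WINDOW_FLANK - len(right)))


def remap_windows(records: list[PhosphoSiteRecord],
                  fasta: dict[str, str] | str) -> list[PhosphoSiteRecord]:
    """Recompute every site window from the FASTA, verifying site residues."""
    if not isinstance(fasta, dict):
        fasta = load_fasta(fasta)
    out = []
    for rec in records:
        seq = fasta.get(rec.protein_accession)
        if seq is None:
            raise AccessionError(
                f"accession {rec.protein_accession!r} not in FASTA"
            )
        windows = []
        for pos, res in zip(rec.positions, rec.residues):
            if pos < 1 or pos > len(seq):
                raise AnnotationConflictError(
                    f"{rec.gene} position {pos} outside protein of length {len(seq)}"
                )
            if seq[pos - 1] != res:
                raise AnnotationConflictError(
                    f"{rec.gene} {res}{pos}: FASTA has {seq[pos - 1]!r} at "
                    f"position {pos} of {rec.protein_accession}"
                )
            windows.append(window_from_sequence(seq, pos))
        out.append(replace(rec, windows=tuple(windows)))
    return out


# ---------------------------------------------------------------------------
# localization filtering

def _max_over_groups(rec: PhosphoSiteRecord, site_idx: int) -> float:
    return max(probs[site_idx] for probs in rec.localization_probs.values())


def passes_localization(rec: PhosphoSiteRecord) -> bool:
    """Retention rule.  The primary site is the first listed site.

    Singly phosphorylated: primary probability > 0.75 in at least one group.
    Multi-phosphorylated: primary > 0.5 AND evidence of another site > 0.75
    in at least one group.
    """
    primary = _max_over_groups(rec, 0)
    if rec.multiplicity <= 1:
        return primary > SINGLE_PROB
    if primary <= PRIMARY_PROB_MULTI:
        return False
    others = [_max_over_groups(rec, i) for i in range(1, len(rec.positions))]
    return any(p > SECONDARY_PROB for p in others)


def filter_multiphospho(records: list[PhosphoSiteRecord]) -> list[PhosphoSiteRecord]:
    return [r for r in records if passes_localization(r)]


# ---------------------------------------------------------------------------
# collapsing

def log2_transform(records: list[PhosphoSiteRecord]) -> list[PhosphoSiteRecord]:
    return [replace(r, intensities=np.log2(r.intensities)) for r in records]


def _feature_key(rec: PhosphoSiteRecord):
    return (rec.gene, tuple(sorted(rec.positions)), rec.multiplicity)


def make_feature_id(gene: str, positions, residues, multiplicity: int) -> str:
    order = np.argsort(positions, kind="stable")
    sites = "+".join(f"{residues[i]}{positions[i]}" for i in order)
    return f"{gene}_{sites}_{multiplicity}"


def collapse_duplicates(records: list[PhosphoSiteRecord]) -> list[PhosphoFeature]:
    """Merge peptide forms sharing (gene, site set, multiplicity) across
    charge/modification variants; per-sample value is the median over
    non-missing duplicates (intensities must already be log2)."""
    groups: dict[tuple, list[PhosphoSiteRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        key = _feature_key(rec)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    features = []
    for key in order:
        recs = groups[key]
        first = recs[0]
        stacked = np.vstack([r.intensities for r in recs])
        all_nan = np.isnan(stacked).all(axis=0)
        med = np.full(stacked.shape[1], np.nan)
        if not all_nan.all():
            med[~all_nan] = np.nanmedian(stacked[:, ~all_nan], axis=0)
        features.append(
            PhosphoFeature(
                feature_id=make_feature_id(
                    first.gene, first.positions, first.residues, first.multiplicity
                ),
                gene=first.gene,
                positions=first.positions,
                residues=first.residues,
                windows=first.windows,
                log2_intensity=med,
            )
        )
    return features


def features_to_frame(features: list[PhosphoFeature],
                      design: SampleDesign) -> pd.DataFrame:
    """Tabular view: one row per feature, one column per sample plus metadata."""
    meta = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "gene": [f.gene for f in features],
            "sites": [";".join(f"{r}{p}" for r, p in zip(f.residues, f.positions))
                      for f in features],
            "windows": [";".join(f.windows) for f in features],
        }
    )
    values = pd.DataFrame(
        np.vstack([f.log2_intensity for f in features])
        if features else np.empty((0, len(design))),
        columns=design.sample_ids,
    )
    return pd.concat([meta, values], axis=1)


def intensity_matrix(features, design: SampleDesign, plex: str | None = None):
    """(features × samples) matrix and matching feature ids for one plex."""
    idx = design.indices(plex=plex)
    X = (np.vstack([f.log2_intensity for f in features])[:, idx]
         if features else np.empty((0, len(idx))))
    return X, [f.feature_id for f in features]
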