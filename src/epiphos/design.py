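"""Sample layout and contrast definitions for the two-plex TMT experiment.

Each TMT plex multiplexes 11 reporter channels: three untreated controls
(pooled tissue taken before any injection), four mock-injected and four
pilocarpine-injected biological replicates, with one plex dissected 4 h and
one 24 h after treatment.  Plexes are always analyzed separately; contrasts
never cross plexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError

GROUPS = ("untreated", "mock", "pilocarpine")
PLEXES = ("4h", "24h")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    plex: str
    group: str
    timepoint: float  # hours post treatment; 0 for untreated controls
    replicate: int


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison within one plex.

    log2 fold changes are treatment minus control (pilocarpine - mock for
    P/M; mock-injected-plus-diazepam minus untreated for D/U).
    """

    label: str
    plex: str
    treatment: str
    control: str


#: The four comparisons of the study design.
STANDARD_CONTRASTS = (
    Contrast("P/M(4h)", "4h", "pilocarpine", "mock"),
    Contrast("P/M(24h)", "24h", "pilocarpine", "mock"),
    Contrast("D/U(4h)", "4h", "mock", "untreated"),
    Contrast("D/U(24h)", "24h", "mock", "untreated"),
)


class SampleDesign:
    """Ordered collection of samples; column order of every intensity matrix."""

    def __init__(self, samples: list[Sample]):
        if not samples:
            raise DesignError("design has no samples")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate sample ids in design")
        for s in samples:
            if s.group not in GROUPS:
                raise DesignError(f"unknown group {s.group!r}")
        self.samples = list(samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleDesign) and self.samples == other.samples

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def plexes(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.plex not in seen:
                seen.append(s.plex)
        return seen

    def indices(self, plex: str | None = None, group: str | None = None) -> np.ndarray:
        """Positions of samples matching the given plex and/or group."""
        idx = [
            i
            for i, s in enumerate(self.samples)
            if (plex is None or s.plex == plex) and (group is None or s.group == group)
        ]
        return np.asarray(idx, dtype=int)

    def subset(self, plex: str | None = None, exclude: set[str] | None = None) -> "SampleDesign":
        exclude = exclude or set()
        kept = [
            s
            for s in self.samples
            if (plex is None or s.plex == plex) and s.sample_id not in exclude
        ]
        return SampleDesign(kept)

    def group_labels(self, plex: str | None = None) -> list[str]:
        return [s.group for s in self.samples if plex is None or s.plex == plex]

    def contrasts_for_plex(self, plex: str) -> list[Contrast]:
        return [c for c in STANDARD_CONTRASTS if c.plex == plex]

    def validate_contrast(self, contrast: Contrast) -> None:
        for grp in (contrast.treatment, contrast.control):
            if len(self.indices(plex=contrast.plex, group=grp)) < 2:
                raise DesignError(
                    f"contrast {contrast.label}: group {grp!r} in plex "
                    f"{contrast.plex!r} has fewer than 2 samples"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "plex": [s.plex for s in self.samples],
                "group": [s.group for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        required = {"sample_id", "plex", "group", "timepoint", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        samples = [
            Sample(
                str(r.sample_id),
                str(r.plex),
                str(r.group),
                float(r.timepoint),
                int(r.replicate),
            )
            for r in df.itertuples()
        ]
        return cls(samples)

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def default(cls) -> "SampleDesign":
        """Two 11-channel plexes: 3 untreated + 4 mock + 4 pilocarpine each."""
        samples = []
        for plex in PLEXES:
            tp = float(plex.rstrip("h"))
            for r in range(1, 4):
                samples.append(Sample(f"Untreated_{plex}_{r}", plex, "untreated", 0.0, r))
            for r in range(1, 5):
                samples.append(Sample(f"Mock_{plex}_{r}", plex, "mock", tp, r))
            for r in range(1, 5):
                samples.append(Sample(f"Pilo_{plex}_{r}", plex, "pilocarpine", tp, r))
        return cls(samples)
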