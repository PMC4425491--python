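"""Core in-memory containers for SNP-array cohort copy-number analysis.

The coordinate backbone is a :class:`SnpManifest` (ordered probes with local
GC context); all per-sample signal lives in samples x probes matrices inside
:class:`CohortTracks`. Downstream modules consume only these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

# Germline genotype codes (int8 in matrices).
GT_AA = 0
GT_AB = 1
GT_BB = 2
GT_NOCALL = -1
GT_LABELS = {GT_AA: "AA", GT_AB: "AB", GT_BB: "BB", GT_NOCALL: "NoCall"}
GT_CODES = {v: k for k, v in GT_LABELS.items()}

# The six histopathological malignancy parameters consumed by group contrasts.
HISTO_PARAMS = (
    "solid_growth",
    "myoepithelial_cells",
    "nuclear_pleomorphism",
    "mitotic_index",
    "invasive_growth",
    "necrosis",
)

MALIGNANCY_GROUPS = ("hyperplasia", "benign", "malignant")


def natural_chrom_key(chrom: str):
    """Sort key: numeric chromosomes in natural order, X (then others) last."""
    c = str(chrom)
    for pre in ("chr", "CFA", "cfa"):
        if c.startswith(pre):
            c = c[len(pre):]
            break
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


@dataclass
class SnpManifest:
    """Ordered genomic positions and GC context for every probe.

    ``df`` has columns ``probe_id, chrom, pos, gc_fraction`` sorted by
    (chrom, pos) with chromosome order natural-sorted and X last. ``pos`` is
    1-based; ``gc_fraction`` is in [0, 1] (NaN allowed for missing).
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = ["probe_id", "chrom", "pos", "gc_fraction"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_probes(self) -> int:
        return len(self.df)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.df["probe_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def gc_fraction(self) -> np.ndarray:
        return self.df["gc_fraction"].to_numpy(dtype=float)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in manifest (sorted) order."""
        seen = []
        for c in self.df["chrom"]:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index slice of one chromosome's probes."""
        idx = np.flatnonzero(self.df["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in manifest")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def iter_chrom_slices(self):
        for c in self.chromosomes:
            yield c, self.chrom_slice(c)


@dataclass
class CohortTracks:
    """Samples x probes LRR/BAF matrices for tumour and matched germline."""

    manifest: SnpManifest
    samples: list
    tumour_lrr: np.ndarray
    tumour_baf: np.ndarray
    germline_lrr: np.ndarray
    germline_baf: np.ndarray
    germline_genotype: np.ndarray  # int8, GT_* codes

    def __post_init__(self):
        n_s, n_p = len(self.samples), self.manifest.n_probes
        for name in ("tumour_lrr", "tumour_baf", "germline_lrr",
                     "germline_baf", "germline_genotype"):
            m = getattr(self, name)
            if m.shape != (n_s, n_p):
                raise ValueError(
                    f"{name} shape {m.shape} != ({n_s}, {n_p})")
        for name in ("tumour_baf", "germline_baf"):
            b = getattr(self, name)
            finite = b[np.isfinite(b)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)


@dataclass
class SampleMetadata:
    """Per-tumour metadata: dog of origin, malignancy grouping, histo scores."""

    df: pd.DataFrame

    def __post_init__(self):
        required = ["sample_id", "dog_id", "malignancy_group", "diagnosis_group"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def require_covers(self, samples) -> None:
        have = set(self.df["sample_id"])
        lacking = [s for s in samples if s not in have]
        if lacking:
            raise ValueError(f"metadata missing rows for samples: {lacking[:10]}")

    def group_members(self, column: str, levels) -> list:
        if column not in self.df.columns:
            raise KeyError(f"metadata has no column {column!r}")
        levels = set(levels)
        mask = self.df[column].isin(levels)
        return self.df.loc[mask, "sample_id"].tolist()


@dataclass
class Segment:
    """One constant-value segment of a per-sample profile.

    Probe indices are inclusive positions in the manifest; ``mean_mbaf`` is
    NaN for single-track (LRR-only) segmentation or segments without
    germline-heterozygous probes.
    """

    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    n_probes: int
    mean_lrr: float
    mean_mbaf: float = float("nan")
    n_het: int = 0


@dataclass
class AscatProfile:
    """Fitted allele-specific copy-number profile for one tumour.

    rho is the aberrant cell fraction, psi the tumour ploidy (probe-weighted
    mean total copy number of the fitted profile), goodness in [0, 1].
    ``segments`` pairs each Segment with integer allele counts nA >= nB >= 0.
    """

    sample_id: str
    rho: float
    psi: float
    goodness: float
    segments: list  # list of (Segment, nA, nB)
    psi_grid: float = float("nan")  # grid ploidy parameter at the optimum

    def total_copies_per_probe(self, n_probes: int) -> np.ndarray:
        out = np.full(n_probes, np.nan)
        for seg, na, nb in self.segments:
            out[seg.start_idx:seg.end_idx + 1] = na + nb
        return out


@dataclass
class FrequencyTrack:
    """Per-probe cohort aberration frequencies for one sample group."""

    group: str
    n_samples: int
    gain_freq: np.ndarray
    loss_freq: np.ndarray
    loh_freq: Optional[np.ndarray] = None


@dataclass
class RecurrentRegion:
    chrom: str
    start_bp: int
    end_bp: int
    direction: str  # gain | loss | LOH
    peak_freq: float
    n_samples_affected: int
    start_idx: int = -1
    end_idx: int = -1
    genes: list = field(default_factory=list)
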