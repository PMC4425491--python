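"""Frequency-difference contrasts between histopathological subgroups.

For each contrast, the per-probe aberration frequency of subgroup A is
subtracted from that of subgroup B (the myoepithelial-cell contrast is
reversed: absence of myoepithelial cells is the malignancy-associated
level); probe runs with a difference >= 20 percentage points are reported
as regions, per direction (gain/loss) and chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calls import _runs_to_regions, cohort_frequencies
from .datatypes import SnpManifest


@dataclass
class ContrastSpec:
    name: str
    column: str
    levels_a: frozenset
    levels_b: frozenset
    threshold: float = 0.20
    note: str = ""

    def __post_init__(self):
        if set(self.levels_a) & set(self.levels_b):
            raise ValueError(f"{self.name}: overlapping subgroup levels")


def builtin_contrasts() -> list:
    """The six histo-parameter contrasts plus the two malignancy contrasts.

    Binary parameters split no (0) vs yes (>=1). Nuclear pleomorphism and
    mitotic index compare score 0 against scores 2-3; the intermediate
    score 1 belongs to neither level. The myoepithelial contrast is
    oriented so that the reported difference is frequency(no) minus
    frequency(yes).
    """
    yes = frozenset({1, 2, 3})
    no = frozenset({0})
    high = frozenset({2, 3})
    return [
        ContrastSpec("solid_growth", "solid_growth", no, yes),
        ContrastSpec("myoepithelial_cells", "myoepithelial_cells",
                     yes, no, note="reversed orientation: no - yes"),
        ContrastSpec("nuclear_pleomorphism", "nuclear_pleomorphism",
                     no, high, note="score 1 excluded"),
        ContrastSpec("mitotic_index", "mitotic_index", no, high,
                     note="score 1 excluded"),
        ContrastSpec("invasive_growth", "invasive_growth", no, yes),
        ContrastSpec("necrosis", "necrosis", no, yes),
        ContrastSpec("hyperplasia_vs_malignant", "malignancy_group",
                     frozenset({"hyperplasia"}), frozenset({"malignant"})),
        ContrastSpec("benign_vs_malignant", "malignancy_group",
                     frozenset({"benign"}), frozenset({"malignant"})),
    ]


def contrast_frequencies(calltracks, metadata, spec: ContrastSpec,
                         manifest: SnpManifest,
                         directions=("gain", "loss")) -> dict:
    """Per-probe frequency difference (B - A) and qualifying regions.

    Returns {"delta_gain": array, "delta_loss": array, "regions": list}.
    """
    if spec.column not in metadata.df.columns:
        raise KeyError(f"metadata has no column {spec.column!r}")
    have = {t.sample_id for t in calltracks}
    members_a = [s for s in metadata.group_members(spec.column, spec.levels_a)
                 if s in have]
    members_b = [s for s in metadata.group_members(spec.column, spec.levels_b)
                 if s in have]
    if not members_a or not members_b:
        raise ValueError(
            f"{spec.name}: empty subgroup (levels_a={sorted(spec.levels_a)} "
            f"n={len(members_a)}, levels_b={sorted(spec.levels_b)} "
            f"n={len(members_b)})")
    freqs = cohort_frequencies(calltracks,
                               groups={"a": members_a, "b": members_b})
    out = {"spec": spec, "n_a": len(members_a), "n_b": len(members_b),
           "regions": []}
    for direction in directions:
        fa = getattr(freqs["a"], f"{direction}_freq")
        fb = getattr(freqs["b"], f"{direction}_freq")
        delta = fb - fa
        out[f"delta_{direction}"] = delta
        mask = delta >= spec.threshold - 1e-12
        regions = _runs_to_regions(mask, delta, manifest, direction,
                                   n_samples=len(members_b))
        for r in regions:
            r.n_samples_affected = 0
        out["regions"].extend(regions)
    return out


def run_contrasts(calltracks, metadata, manifest: SnpManifest,
                  specs=None) -> pd.DataFrame:
    """All contrasts; one row per qualifying region, Fig-7-style summary."""
    specs = specs or builtin_contrasts()
    rows = []
    for spec in specs:
        res = contrast_frequencies(calltracks, metadata, spec, manifest)
        for r in res["regions"]:
            rows.append({
                "contrast": spec.name, "chrom": r.chrom, "start": r.start_bp,
                "end": r.end_bp, "direction": r.direction,
                "peak_delta": r.peak_freq,
                "n_a": res["n_a"], "n_b": res["n_b"],
            })
    return pd.DataFrame(rows, columns=["contrast", "chrom", "start", "end",
                                       "direction", "peak_delta", "n_a",
                                       "n_b"])


def chromosome_summary(contrast_table: pd.DataFrame) -> pd.DataFrame:
    """Contrast x chromosome matrix of directions with qualifying regions."""
    if contrast_table.empty:
        return pd.DataFrame()
    agg = (contrast_table.groupby(["contrast", "chrom"])["direction"]
           .apply(lambda s: "/".join(sorted(set(s)))).unstack(fill_value=""))
    return agg
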