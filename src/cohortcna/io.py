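"""Readers and writers for the on-disk cohort formats.

Conventions: TSV with header row and ``NA`` for missing; coordinates are
1-based inclusive in manifests/region TSVs and 0-based half-open in BED;
matrix files have probe rows (first column ``probe_id``) and sample columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    GT_CODES,
    GT_LABELS,
    GT_NOCALL,
    CohortTracks,
    SampleMetadata,
    SnpManifest,
    natural_chrom_key,
)

BAF_CLAMP_EPS = 1e-3  # values in [-eps, 1+eps] are clamped with a warning


def read_manifest(path) -> SnpManifest:
    """Read a probe manifest TSV (probe_id, chrom, pos, gc_fraction)."""
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str},
                     na_values=["NA"])
    for col in ("probe_id", "chrom", "pos", "gc_fraction"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} missing column {col!r}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        bad = df.loc[pos.isna(), "probe_id"].head(5).tolist()
        raise ValueError(f"non-numeric pos for probes {bad}")
    df["pos"] = pos.astype(np.int64)
    dup = df["probe_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate probe_id: {df.loc[dup, 'probe_id'].iloc[0]!r}")
    key = df["chrom"].map(natural_chrom_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df["pos"].iloc[i]))
    if order != list(range(len(df))):
        warnings.warn("manifest rows were not sorted by (chrom, pos); sorting")
        df = df.iloc[order].reset_index(drop=True)
    dup_pos = df.duplicated(subset=["chrom", "pos"])
    if dup_pos.any():
        i = int(np.flatnonzero(dup_pos.to_numpy())[0])
        raise ValueError(
            f"duplicate (chrom, pos) at {df['chrom'].iloc[i]}:{df['pos'].iloc[i]}")
    return SnpManifest(df[["probe_id", "chrom", "pos", "gc_fraction"]])


def write_manifest(manifest: SnpManifest, path) -> None:
    manifest.df.to_csv(path, sep="\t", index=False, na_rep="NA",
                       float_format="%.6f")


def _read_matrix(path, manifest: SnpManifest, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str}, na_values=["NA"])
    if "probe_id" not in df.columns:
        raise ValueError(f"{name} matrix {path} missing probe_id column")
    df = df.set_index("probe_id")
    want = manifest.probe_ids
    have = df.index.to_numpy()
    if len(have) != len(want) or set(have) != set(want):
        offenders = sorted(set(want).symmetric_difference(have))[:10]
        raise ValueError(
            f"{name} matrix probe set does not match manifest; "
            f"first offenders: {offenders}")
    return df.loc[want]


def read_tracks(manifest: SnpManifest, tumour_lrr, tumour_baf,
                germline_lrr, germline_baf, germline_genotype) -> CohortTracks:
    """Read the five cohort matrices, aligned to the manifest order."""
    mats = {}
    samples = None
    for name, path in [("tumour_lrr", tumour_lrr), ("tumour_baf", tumour_baf),
                       ("germline_lrr", germline_lrr),
                       ("germline_baf", germline_baf)]:
        df = _read_matrix(path, manifest, name)
        if samples is None:
            samples = list(df.columns)
        elif list(df.columns) != samples:
            raise ValueError(f"{name} sample columns differ from tumour_lrr")
        mats[name] = df.to_numpy(dtype=float).T  # samples x probes
    for name in ("tumour_baf", "germline_baf"):
        b = mats[name]
        out_of_range = np.isfinite(b) & ((b < 0) | (b > 1))
        if out_of_range.any():
            worst = np.nanmax(np.abs(b - 0.5)) - 0.5
            if worst > BAF_CLAMP_EPS:
                raise ValueError(f"{name} value outside [-{BAF_CLAMP_EPS}, "
                                 f"1+{BAF_CLAMP_EPS}]")
            warnings.warn(f"{name}: clamping {int(out_of_range.sum())} "
                          "BAF values into [0, 1]")
            mats[name] = np.clip(b, 0.0, 1.0)
    gdf = _read_matrix(germline_genotype, manifest, "germline_genotype")
    if list(gdf.columns) != samples:
        raise ValueError("germline_genotype sample columns differ")
    gt = np.full((len(samples), manifest.n_probes), GT_NOCALL, dtype=np.int8)
    raw = gdf.to_numpy().T
    for label, code in GT_CODES.items():
        gt[raw == label] = code
    return CohortTracks(manifest=manifest, samples=samples,
                        germline_genotype=gt, **mats)


def write_tracks(tracks: CohortTracks, tumour_lrr, tumour_baf, germline_lrr,
                 germline_baf, germline_genotype) -> None:
    ids = tracks.manifest.probe_ids
    for name, path in [("tumour_lrr", tumour_lrr), ("tumour_baf", tumour_baf),
                       ("germline_lrr", germline_lrr),
                       ("germline_baf", germline_baf)]:
        m = getattr(tracks, name)
        df = pd.DataFrame(m.T, columns=tracks.samples)
        df.insert(0, "probe_id", ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA",
                  float_format="%.6f")
    labels = np.vectorize(GT_LABELS.get)(tracks.germline_genotype.T)
    gdf = pd.DataFrame(labels, columns=tracks.samples)
    gdf.insert(0, "probe_id", ids)
    gdf.to_csv(path_or_buf=germline_genotype, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dog_id": str},
                     na_values=["NA"])
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_region_table(regions: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write regions (chrom, start, end 1-based inclusive, + payload).

    ``format='bed'`` converts exactly to 0-based half-open; extra columns
    follow the three coordinate fields.
    """
    for col in ("chrom", "start", "end"):
        if col not in regions.columns:
            raise ValueError(f"regions missing column {col!r}")
    if len(regions) and (regions["start"] > regions["end"]).any():
        raise ValueError("region with start > end")
    payload = [c for c in regions.columns if c not in ("chrom", "start", "end")]
    out = regions[["chrom", "start", "end", *payload]].copy()
    if format == "bed":
        out["start"] = out["start"].astype(np.int64) - 1
        out.to_csv(path, sep="\t", index=False, header=False)
    elif format == "tsv":
        out.to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown region format {format!r}")


def read_region_table(path, format: str = "tsv") -> pd.DataFrame:
    """Inverse of :func:`write_region_table`; returns 1-based inclusive."""
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"malformed BED {path}: fewer than 3 columns")
        cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
        if df.shape[1] >= 4:
            cols[3] = "name"
        df.columns = cols
        try:
            df["start"] = df["start"].astype(np.int64) + 1
            df["end"] = df["end"].astype(np.int64)
        except (ValueError, TypeError) as e:
            raise ValueError(f"malformed BED {path}: {e}") from None
        return df
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return df


def read_gene_bed(path) -> pd.DataFrame:
    """Read a gene interval BED (chrom, start, end, name) with line checks."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer BED coordinates") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            genes.append((parts[0], start, end, name))
    return pd.DataFrame(genes, columns=["chrom", "start", "end", "name"])


def write_bedgraph(manifest: SnpManifest, values: np.ndarray, path,
                   track_name: str = "") -> None:
    """Per-probe values as bedGraph intervals (probe pos, half-open)."""
    with open(path, "w") as fh:
        if track_name:
            fh.write(f"track type=bedGraph name=\"{track_name}\"\n")
        chrom = manifest.chrom
        pos = manifest.pos
        for i in range(manifest.n_probes):
            v = values[i]
            if np.isnan(v):
                continue
            fh.write(f"{chrom[i]}\t{pos[i] - 1}\t{pos[i]}\t{v:.6g}\n")


def segments_to_frame(segments) -> pd.DataFrame:
    rows = [{
        "chrom": s.chrom, "start": s.start_bp, "end": s.end_bp,
        "n_probes": s.n_probes, "mean_lrr": s.mean_lrr,
        "mean_mbaf": s.mean_mbaf, "n_het": s.n_het,
    } for s in segments]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes",
                                       "mean_lrr", "mean_mbaf", "n_het"])
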