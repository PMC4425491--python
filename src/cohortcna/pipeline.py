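"""End-to-end orchestration with YAML config, logging and deterministic seeds.

Stage order follows the analysis design: tumour LRR preprocessing (GC
correction, optional quantile normalization, winsorization) -> single-track
PCF -> threshold calls / recurrence; ASPCF -> ASCAT -> ploidy-relative calls,
LOH and frequencies; permutation significance; histopathology contrasts;
optional gene annotation. Reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ascat, calls, contrast, io, preprocess, segmentation, significance
from .datatypes import SampleMetadata
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger("cohortcna")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "cohortcna_run",
    "simulate": None,        # dict of SimConfig overrides, or None for file input
    "inputs": None,          # dict of file paths (manifest, matrices, metadata)
    "gene_bed": None,
    "preprocess": {"gc_window_bp": 1_000_000, "winsor_k": 2.5,
                   "winsor_window": 25, "apply_quantile": False},
    "segmentation": {"gamma_pcf": 80.0, "kmin": 10, "aspcf_penalty": 0.80},
    "ascat": {"gamma_platform": 0.40, "min_goodness": 0.80},
    "calls": {"gain_threshold": 0.05, "loss_threshold": -0.05,
              "recurrence_fraction": 0.20, "recurrence_count": 20},
    "significance": {"n_perm": 1000, "alpha": 0.05,
                     "direction": "two_sided_abs"},
    "contrast": {"threshold": 0.20},
}


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (user or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict) \
                and key not in ("simulate", "inputs"):
            for k2, v2 in val.items():
                if k2 not in cfg[key]:
                    raise ValueError(f"unknown config key {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(user)


def split_by_dog(metadata: SampleMetadata, seed: int = 0):
    """Two analysis sets with one tumour per dog each (singles in both).

    Multi-tumour dogs have their tumours distributed across the two sets
    (seeded random for pairs; triples put two in one set and one in the
    other); single-tumour dogs appear in both. The third returned set is
    all samples.
    """
    rng = np.random.default_rng(seed)
    set_a, set_b = [], []
    all_ids = metadata.df["sample_id"].tolist()
    for _, grp in metadata.df.groupby("dog_id", sort=True):
        ids = grp["sample_id"].tolist()
        if len(ids) == 1:
            set_a.extend(ids)
            set_b.extend(ids)
        else:
            ids = list(ids)
            rng.shuffle(ids)
            half = (len(ids) + 1) // 2
            set_a.extend(sorted(ids[:half]))
            set_b.extend(sorted(ids[half:]))
    order = {s: i for i, s in enumerate(all_ids)}
    set_a.sort(key=order.get)
    set_b.sort(key=order.get)
    return set_a, set_b, all_ids


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: dict, outdir=None) -> Path:
    """Execute all stages; returns the run directory.

    Writes segment/profile/region TSVs, frequency bedGraphs, a significant
    -region BED and a JSON manifest of parameters, seed and output
    checksums.
    """
    cfg = _merge_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    if cfg["simulate"] is not None:
        sim_kw = dict(cfg["simulate"])
        sim_kw.setdefault("seed", seed)
        sim = SimConfig(**sim_kw)
        log.info("simulating cohort (seed=%d)", sim.seed)
        tracks, metadata, truths = simulate_cohort(sim)
    elif cfg["inputs"]:
        paths = cfg["inputs"]
        manifest = io.read_manifest(paths["manifest"])
        tracks = io.read_tracks(manifest, paths["tumour_lrr"],
                                paths["tumour_baf"], paths["germline_lrr"],
                                paths["germline_baf"],
                                paths["germline_genotype"])
        metadata = io.read_metadata(paths["metadata"])
    else:
        raise ValueError("config needs either a simulate block or inputs")
    metadata.require_covers(tracks.samples)
    manifest = tracks.manifest
    n_probes = manifest.n_probes

    pp = cfg["preprocess"]
    pparams = preprocess.PreprocessParams(
        gc_window_bp=pp["gc_window_bp"], winsor_k=pp["winsor_k"],
        winsor_window=pp["winsor_window"])
    scale = preprocess.germline_lrr_scale(tracks.germline_lrr)
    log.info("preprocessing tumour LRR (quantile=%s, scale=%.3f)",
             pp["apply_quantile"], scale)
    lrr_pp = preprocess.preprocess_tumour_lrr(
        tracks.tumour_lrr, manifest, pparams,
        apply_quantile=pp["apply_quantile"], scale=scale)

    sp = cfg["segmentation"]
    sparams = segmentation.SegParams(gamma_pcf=sp["gamma_pcf"],
                                     kmin=sp["kmin"],
                                     aspcf_penalty=sp["aspcf_penalty"])
    log.info("PCF segmentation (gamma=%g, kmin=%d)", sparams.gamma_pcf,
             sparams.kmin)
    seg_matrix = np.empty_like(lrr_pp)
    pcf_calls = []
    for i, sid in enumerate(tracks.samples):
        segs = segmentation.segment_sample_lrr(lrr_pp[i], manifest, sparams)
        seg_matrix[i] = segmentation.segments_to_track(segs, n_probes)
        pcf_calls.append(calls.call_threshold(segs, n_probes, sid))
    np.savetxt(out / "segmented_lrr.tsv",
               seg_matrix, delimiter="\t", fmt="%.6f")

    log.info("ASPCF + ASCAT (penalty=%g, gamma_platform=%g)",
             sparams.aspcf_penalty, cfg["ascat"]["gamma_platform"])
    aparams = ascat.AscatParams(
        gamma_platform=cfg["ascat"]["gamma_platform"],
        min_goodness=cfg["ascat"]["min_goodness"])
    profiles = {}
    for i, sid in enumerate(tracks.samples):
        segs = segmentation.segment_sample_aspcf(
            lrr_pp[i], tracks.tumour_baf[i], tracks.germline_genotype[i],
            manifest, sparams)
        prof = ascat.fit_purity_ploidy(segs, aparams, sample_id=sid)
        if prof is not None:
            profiles[sid] = prof
    log.info("profiles obtained for %d of %d tumours", len(profiles),
             len(tracks.samples))

    summary = pd.DataFrame([{
        "sample_id": p.sample_id, "rho": p.rho, "psi": p.psi,
        "goodness": p.goodness, "ploidy_class": ascat.classify_ploidy(p.psi),
    } for p in profiles.values()])
    summary.to_csv(out / "ascat_summary.tsv", sep="\t", index=False,
                   float_format="%.4f")

    ascat_calls = [calls.call_ascat(p, n_probes) for p in profiles.values()]
    groups = {g: metadata.group_members("malignancy_group", [g])
              for g in metadata.df["malignancy_group"].unique()}
    freqs = calls.cohort_frequencies(ascat_calls, groups)
    for label, ft in freqs.items():
        for direction in ("gain", "loss", "loh"):
            io.write_bedgraph(manifest, getattr(ft, f"{direction}_freq"),
                              out / f"freq_{label}_{direction}.bedgraph",
                              track_name=f"{label}_{direction}")
    regions = calls.recurrent_regions(
        freqs["all"], manifest, mode="count",
        min_count=cfg["calls"]["recurrence_count"])
    region_df = calls.regions_to_frame(regions)
    gene_bed = None
    if cfg["gene_bed"]:
        gene_bed = io.read_gene_bed(cfg["gene_bed"])
        calls.annotate_regions(regions, gene_bed)
        region_df = calls.regions_to_frame(regions)
    io.write_region_table(region_df, out / "recurrent_regions.tsv", "tsv")

    sg = cfg["significance"]
    log.info("permutation significance (n_perm=%d)", sg["n_perm"])
    perm = significance.PermParams(n_perm=sg["n_perm"], alpha=sg["alpha"],
                                   seed=seed + 1, direction=sg["direction"])
    sig = significance.significance_test(seg_matrix, perm)
    sig_regions = significance.significant_regions(sig, manifest)
    if sig_regions:
        io.write_region_table(calls.regions_to_frame(sig_regions),
                              out / "significant_regions.bed", "bed")
    else:
        (out / "significant_regions.bed").write_text("")
    pd.DataFrame({"probe_id": manifest.probe_ids, "G": sig.G,
                  "p": sig.p_value, "q": sig.q_value,
                  "significant": sig.significant.astype(int)}).to_csv(
        out / "significance.tsv", sep="\t", index=False, float_format="%.6g")

    log.info("group contrasts")
    ctab = contrast.run_contrasts(ascat_calls, metadata, manifest)
    ctab.to_csv(out / "contrasts.tsv", sep="\t", index=False,
                float_format="%.4f")

    manifest_info = {
        "seed": seed,
        "config": cfg,
        "n_samples": len(tracks.samples),
        "n_profiles": len(profiles),
        "outputs": {p.name: _checksum(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "run_manifest.json"},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest_info, indent=2, default=str))
    log.info("run complete: %s", out)
    return out
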