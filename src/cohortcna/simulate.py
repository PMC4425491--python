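"""Synthetic SNP-array tumour cohorts with known allele-specific truth.

The generator emulates a mammary-tumour cohort profiled on a ~170K canine
SNP array: matched germline/tumour LRR and BAF tracks, mixed diploid and
aneuploid tumours, purities between 24% and 100%, GC-correlated LRR waves,
group-structured recurrent aberrations (an oncogene-like amplicon enriched
in the malignant group, a tumour-suppressor-like homozygous deletion,
telomeric losses, a cnLOH region) and private per-tumour events. Observed
signals are drawn from the allele-specific forward model plus truncated
Gaussian noise, so every pipeline stage can be validated against the truth
profiles.

The default configuration is desk-scale (3 groups of 12/55/46 samples on
4 chromosomes x 5,000 probes); ``SimConfig.full_scale()`` gives the
39-chromosome, ~170K-probe layout of the real platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ascat import HOMDEL_LRR_SENTINEL
from .calls import CallTrack, STATE_GAIN, STATE_LOSS, STATE_NEUTRAL
from .datatypes import (
    GT_AA,
    GT_AB,
    GT_BB,
    HISTO_PARAMS,
    CohortTracks,
    SampleMetadata,
    SnpManifest,
)

MB = 1_000_000


@dataclass
class EventDesign:
    """One recurrent aberration: region, type, per-group carrier frequency."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    kind: str  # gain | loss | cnLOH | homdel
    group_freq: dict  # group label -> Bernoulli carrier probability


@dataclass
class TruthProfile:
    sample_id: str
    rho_true: float
    nA: np.ndarray  # per-probe
    nB: np.ndarray

    @property
    def psi_true(self) -> float:
        return float((self.nA + self.nB).mean())

    def segments(self, manifest: SnpManifest) -> list:
        """Maximal constant-(nA, nB) runs as (chrom, start, end, nA, nB)."""
        out = []
        total = self.nA * 100 + self.nB
        for chrom, sl in manifest.iter_chrom_slices():
            t = total[sl]
            pos = manifest.pos[sl]
            brk = np.flatnonzero(np.diff(t) != 0) + 1
            starts = np.concatenate(([0], brk))
            ends = np.concatenate((brk - 1, [t.size - 1]))
            for a, b in zip(starts, ends):
                out.append((chrom, int(pos[a]), int(pos[b]),
                            int(self.nA[sl][a]), int(self.nB[sl][a])))
        return out


def default_events() -> list:
    """Recurrent-event design shaped like the cohort's reported anchors."""
    return [
        EventDesign("oncogene_amp", "chr1", 60 * MB, 80 * MB, "gain",
                    {"hyperplasia": 0.167, "benign": 0.091,
                     "malignant": 0.304}),
        EventDesign("tsg_homdel", "chr3", 40 * MB, 41 * MB, "homdel",
                    {"hyperplasia": 0.0, "benign": 0.02, "malignant": 0.09}),
        EventDesign("telomeric_loss_a", "chr2", 85 * MB, 100 * MB, "loss",
                    {"hyperplasia": 0.08, "benign": 0.13, "malignant": 0.30}),
        EventDesign("telomeric_loss_b", "chr4", 50 * MB, 60 * MB, "loss",
                    {"hyperplasia": 0.20, "benign": 0.20, "malignant": 0.20}),
        EventDesign("cnloh_region", "chr3", 1, 20 * MB, "cnLOH",
                    {"hyperplasia": 0.10, "benign": 0.15, "malignant": 0.25}),
    ]


@dataclass
class SimConfig:
    n_per_group: dict = field(default_factory=lambda: {
        "hyperplasia": 12, "benign": 55, "malignant": 46})
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 120 * MB, "chr2": 100 * MB, "chr3": 80 * MB,
        "chr4": 60 * MB})
    probes_per_chrom: dict = field(default_factory=lambda: {
        "chr1": 5000, "chr2": 5000, "chr3": 5000, "chr4": 5000})
    het_fraction: float = 0.33
    lrr_noise_sd: float = 0.15
    baf_noise_sd: float = 0.03
    gc_wave_amplitude: float = 0.08
    events: list = field(default_factory=default_events)
    # ploidy-state mixture over baseline (nA, nB): diploid, tetraploid,
    # triploid-like, hypodiploid, highly polyploid
    ploidy_mixture: dict = field(default_factory=lambda: {
        "diploid": 0.74, "tetraploid": 0.09, "triploid": 0.13,
        "hypodiploid": 0.02, "highly_polyploid": 0.02})
    rho_range: tuple = (0.24, 1.00)
    private_event_rate: float = 1.5  # extra Poisson events per tumour
    min_private_events: int = 1      # every tumour carries >= this many
    # Force germline-het probes at truth-segment boundaries. Breakpoints of
    # BAF-only events are observable only on the het-probe grid, so the
    # zero-noise configuration uses this to make every boundary identifiable
    # at probe resolution; it is off for noisy (realistic) cohorts.
    het_at_event_boundaries: bool = False
    seed: int = 0

    def __post_init__(self):
        for ev in self.events:
            if ev.chrom not in self.chrom_lengths:
                raise ValueError(f"event {ev.name}: unknown chromosome "
                                 f"{ev.chrom}")
            if not (1 <= ev.start_bp <= ev.end_bp
                    <= self.chrom_lengths[ev.chrom]):
                raise ValueError(f"event {ev.name}: region outside "
                                 f"chromosome bounds")
            for f in ev.group_freq.values():
                if not (0 <= f <= 1):
                    raise ValueError(f"event {ev.name}: frequency outside "
                                     "[0, 1]")

    @classmethod
    def zero_noise(cls, **kw) -> "SimConfig":
        kw.setdefault("het_at_event_boundaries", True)
        return cls(lrr_noise_sd=0.0, baf_noise_sd=0.0,
                   gc_wave_amplitude=0.0, **kw)

    @classmethod
    def full_scale(cls, **kw) -> "SimConfig":
        """38 autosomes + X, ~170K probes (not exercised by default tests)."""
        lengths = {f"chr{i}": int((125 - 2.4 * i) * MB) for i in range(1, 39)}
        lengths["chrX"] = 124 * MB
        total = sum(lengths.values())
        probes = {c: max(500, int(170_000 * l / total))
                  for c, l in lengths.items()}
        return cls(chrom_lengths=lengths, probes_per_chrom=probes, **kw)


_BASELINES = {
    "diploid": (1, 1),
    "tetraploid": (2, 2),
    "triploid": (2, 1),
    "hypodiploid": (1, 1),        # plus extensive losses, applied below
    "highly_polyploid": (3, 2),
}


def build_manifest(config: SimConfig, rng: np.random.Generator) -> SnpManifest:
    """Evenly spaced probes with a slowly varying sinusoidal GC landscape."""
    rows = []
    for chrom, length in config.chrom_lengths.items():
        n = config.probes_per_chrom[chrom]
        pos = np.linspace(length / (2 * n), length - length / (2 * n), n)
        pos = np.unique(np.round(pos).astype(np.int64))
        phase = rng.uniform(0, 2 * np.pi)
        gc = (0.45 + 0.08 * np.sin(2 * np.pi * pos / (25 * MB) + phase)
              + rng.normal(0, 0.01, size=pos.size))
        gc = np.clip(gc, 0.30, 0.60)
        for i, (p, g) in enumerate(zip(pos, gc)):
            rows.append((f"{chrom}_p{i:05d}", chrom, int(p), float(g)))
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos",
                                     "gc_fraction"])
    return SnpManifest(df)


def _region_probe_mask(manifest, chrom, start_bp, end_bp):
    m = ((manifest.chrom == chrom) & (manifest.pos >= start_bp)
         & (manifest.pos <= end_bp))
    return m


def _apply_event(nA, nB, mask, kind):
    if kind == "gain":
        nA[mask] += 1
    elif kind == "loss":
        has_b = mask & (nB > 0)
        only_a = mask & (nB == 0) & (nA > 0)
        nB[has_b] -= 1
        nA[only_a] -= 1
    elif kind == "cnLOH":
        tot = nA[mask] + nB[mask]
        nA[mask] = tot
        nB[mask] = 0
    elif kind == "homdel":
        nA[mask] = 0
        nB[mask] = 0
    else:
        raise ValueError(f"unknown event kind {kind!r}")


def _private_events(manifest, config, rng, nA, nB):
    n_events = config.min_private_events + rng.poisson(config.private_event_rate)
    chroms = list(config.chrom_lengths)
    for _ in range(n_events):
        chrom = chroms[rng.integers(len(chroms))]
        length = config.chrom_lengths[chrom]
        if rng.random() < 0.2:  # whole chromosome
            start, end = 1, length
        else:
            span = rng.uniform(5 * MB, 30 * MB)
            start = rng.uniform(0, max(length - span, 1))
            end = start + span
        kind = rng.choice(["gain", "loss", "cnLOH"], p=[0.4, 0.4, 0.2])
        mask = _region_probe_mask(manifest, chrom, start, end)
        _apply_event(nA, nB, mask, kind)


def _sample_truth(manifest, config, rng, group) -> tuple:
    n_probes = manifest.n_probes
    states = list(config.ploidy_mixture)
    probs = np.array([config.ploidy_mixture[s] for s in states])
    state = states[rng.choice(len(states), p=probs / probs.sum())]
    na0, nb0 = _BASELINES[state]
    nA = np.full(n_probes, na0, dtype=np.int16)
    nB = np.full(n_probes, nb0, dtype=np.int16)
    if state == "hypodiploid":
        # lose one copy over roughly half the genome
        for chrom in list(config.chrom_lengths)[::2]:
            mask = manifest.chrom == chrom
            nB[mask] = 0
    if state in ("tetraploid", "highly_polyploid"):
        # genome-doubled tumours carry the signatures of their history:
        # LOH regions acquired before doubling ((nA+nB)/2, 0) and at least
        # one post-doubling single-copy event (odd total)
        chroms = list(config.chrom_lengths)
        for _ in range(2):
            chrom = chroms[rng.integers(len(chroms))]
            length = config.chrom_lengths[chrom]
            span = rng.uniform(10 * MB, 30 * MB)
            start = rng.uniform(0, max(length - span, 1))
            mask = _region_probe_mask(manifest, chrom, start, start + span)
            tot = nA[mask] + nB[mask]
            nA[mask] = tot // 2
            nB[mask] = 0
        chrom = chroms[rng.integers(len(chroms))]
        length = config.chrom_lengths[chrom]
        span = rng.uniform(10 * MB, 30 * MB)
        start = rng.uniform(0, max(length - span, 1))
        mask = _region_probe_mask(manifest, chrom, start, start + span)
        _apply_event(nA, nB, mask, "gain" if rng.random() < 0.5 else "loss")
    for ev in config.events:
        if rng.random() < ev.group_freq.get(group, 0.0):
            mask = _region_probe_mask(manifest, ev.chrom, ev.start_bp,
                                      ev.end_bp)
            _apply_event(nA, nB, mask, ev.kind)
    _private_events(manifest, config, rng, nA, nB)
    rho = round(float(rng.uniform(*config.rho_range)), 2)
    return rho, nA, nB


_HISTO_HIGH_PROB = {  # probability of the malignancy-associated level
    "hyperplasia": {"solid_growth": 0.05, "myoepithelial_cells": 0.8,
                    "nuclear_pleomorphism": 0.05, "mitotic_index": 0.05,
                    "invasive_growth": 0.0, "necrosis": 0.1},
    "benign": {"solid_growth": 0.2, "myoepithelial_cells": 0.7,
               "nuclear_pleomorphism": 0.2, "mitotic_index": 0.15,
               "invasive_growth": 0.05, "necrosis": 0.2},
    "malignant": {"solid_growth": 0.6, "myoepithelial_cells": 0.35,
                  "nuclear_pleomorphism": 0.7, "mitotic_index": 0.5,
                  "invasive_growth": 0.6, "necrosis": 0.5},
}

_DIAGNOSIS = {"hyperplasia": "non_neoplastic", "benign": "benign_neoplasia",
              "malignant": "malignant_epithelial"}


def _metadata_row(sid, dog_id, group, rng):
    row = {"sample_id": sid, "dog_id": dog_id, "malignancy_group": group,
           "diagnosis_group": _DIAGNOSIS[group]}
    probs = _HISTO_HIGH_PROB[group]
    for param in HISTO_PARAMS:
        p = probs[param]
        if param in ("nuclear_pleomorphism", "mitotic_index", "necrosis"):
            if rng.random() < p:
                row[param] = int(rng.choice([2, 3]))
            else:
                row[param] = int(rng.choice([0, 1], p=[0.8, 0.2]))
        elif param == "myoepithelial_cells":
            row[param] = int(rng.random() < p)  # p = presence probability
        else:
            row[param] = int(rng.random() < p)
    return row


def _observed_baf(genotype, nA, nB, rho):
    """Expected BAF per probe given germline genotype and tumour state.

    Germline B-allele copies: AA -> 0 of 2, AB -> 1 of 2, BB -> 2 of 2;
    tumour B copies: 0, nB and nA+nB respectively (no somatic point events).
    A homozygous deletion in a pure tumour leaves no DNA; arrays then report
    noise around the midpoint, emulated as 0.5.
    """
    total = (nA + nB).astype(float)
    g_b = np.select([genotype == GT_AA, genotype == GT_AB, genotype == GT_BB],
                    [0.0, 1.0, 2.0], default=np.nan)
    t_b = np.select([genotype == GT_AA, genotype == GT_AB, genotype == GT_BB],
                    [0.0, nB.astype(float), total], default=np.nan)
    denom = 2 * (1 - rho) + rho * total
    b = ((1 - rho) * g_b + rho * t_b) / np.where(denom == 0, np.nan, denom)
    b = np.where(denom == 0, 0.5, b)
    return b


def simulate_cohort(config: SimConfig | None = None):
    """Generate (CohortTracks, SampleMetadata, [TruthProfile]) from a seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    manifest = build_manifest(config, rng)
    n_probes = manifest.n_probes

    sample_ids = []
    groups = []
    for group, n in config.n_per_group.items():
        for i in range(n):
            sample_ids.append(f"{group[:3]}_{i:03d}")
            groups.append(group)
    n_samples = len(sample_ids)

    # dog structure: consecutive pairs share a dog until ~70% of samples,
    # the rest are single-tumour dogs
    dog_ids = []
    dog = 0
    i = 0
    while i < n_samples:
        take = 2 if (i + 1 < n_samples and dog % 3 != 2) else 1
        for _ in range(take):
            if i < n_samples:
                dog_ids.append(f"dog{dog:03d}")
                i += 1
        dog += 1

    gt = np.empty((n_samples, n_probes), dtype=np.int8)
    t_lrr = np.empty((n_samples, n_probes))
    t_baf = np.empty((n_samples, n_probes))
    g_lrr = np.empty((n_samples, n_probes))
    g_baf = np.empty((n_samples, n_probes))
    truths = []
    meta_rows = []

    gc = manifest.gc_fraction
    gc_std = (gc - gc.mean()) / max(gc.std(), 1e-9)
    wave = config.gc_wave_amplitude * gc_std

    for s, (sid, group) in enumerate(zip(sample_ids, groups)):
        geno = rng.choice([GT_AA, GT_AB, GT_BB], size=n_probes,
                          p=[(1 - config.het_fraction) / 2,
                             config.het_fraction,
                             (1 - config.het_fraction) / 2]).astype(np.int8)
        rho, nA, nB = _sample_truth(manifest, config, rng, group)
        if config.het_at_event_boundaries:
            enc = nA.astype(np.int32) * 64 + nB
            for _, sl in manifest.iter_chrom_slices():
                chg = np.flatnonzero(np.diff(enc[sl])) + sl.start
                geno[chg] = GT_AB
                geno[chg + 1] = GT_AB
        gt[s] = geno
        truths.append(TruthProfile(sample_id=sid, rho_true=rho, nA=nA, nB=nB))
        psi = truths[-1].psi_true

        total = (nA + nB).astype(float)
        num = 2 * (1 - rho) + rho * total
        den = 2 * (1 - rho) + rho * psi
        with np.errstate(divide="ignore"):
            r_true = 0.40 * np.log2(num / den)
        r_true = np.where(num == 0, HOMDEL_LRR_SENTINEL, r_true)
        b_true = _observed_baf(geno, nA, nB, rho)

        t_lrr[s] = (r_true + wave
                    + rng.normal(0, config.lrr_noise_sd, n_probes))
        noise = rng.normal(0, config.baf_noise_sd, n_probes)
        b_obs = b_true + noise
        # reflect into [0, 1] (truncated-Gaussian array noise behaviour)
        b_obs = np.abs(b_obs)
        b_obs = 1 - np.abs(1 - b_obs)
        t_baf[s] = np.clip(b_obs, 0.0, 1.0)

        g_lrr[s] = rng.normal(0, config.lrr_noise_sd, n_probes)
        gb_true = np.select([geno == GT_AA, geno == GT_AB, geno == GT_BB],
                            [0.0, 0.5, 1.0])
        gb = gb_true + rng.normal(0, config.baf_noise_sd, n_probes)
        gb = np.abs(gb)
        gb = 1 - np.abs(1 - gb)
        g_baf[s] = np.clip(gb, 0.0, 1.0)

        meta_rows.append(_metadata_row(sid, dog_ids[s], group, rng))

    tracks = CohortTracks(manifest=manifest, samples=sample_ids,
                          tumour_lrr=t_lrr, tumour_baf=t_baf,
                          germline_lrr=g_lrr, germline_baf=g_baf,
                          germline_genotype=gt)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    return tracks, metadata, truths


def simulate_lrr_cohort(n_samples: int = 40, n_chrom: int = 2,
                        probes_per_chrom: int = 1000,
                        spike_probes: tuple | None = None,
                        spike_freq: float = 0.3, effect: float = 0.3,
                        noise_sd: float = 0.15, seed: int = 0):
    """Plain LRR cohort for the recurrence-significance test.

    Returns (matrix, manifest, spike_mask, carriers): a samples x probes
    LRR matrix of Gaussian noise, with an optional gain of ``effect`` added
    over the probe index range ``spike_probes`` in a Bernoulli
    (``spike_freq``) subset of samples. ``spike_probes=None`` gives a pure
    null cohort.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_probes = n_chrom * probes_per_chrom
    for c in range(1, n_chrom + 1):
        pos = (np.arange(probes_per_chrom) + 1) * 100_000
        for i, p in enumerate(pos):
            rows.append((f"chr{c}_p{i:05d}", f"chr{c}", int(p), 0.45))
    manifest = SnpManifest(pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gc_fraction"]))
    m = rng.normal(0.0, noise_sd, size=(n_samples, n_probes))
    spike_mask = np.zeros(n_probes, dtype=bool)
    carriers = np.zeros(n_samples, dtype=bool)
    if spike_probes is not None:
        a, b = spike_probes
        spike_mask[a:b] = True
        carriers = rng.random(n_samples) < spike_freq
        m[np.ix_(carriers, spike_mask)] += effect
    return m, manifest, spike_mask, carriers


def segment_matrix(m: np.ndarray, manifest: SnpManifest,
                   gamma: float = 80.0, kmin: int = 10) -> np.ndarray:
    """PCF-segment every sample of an LRR matrix; segment means per probe."""
    from .segmentation import SegParams, segment_sample_lrr, segments_to_track
    params = SegParams(gamma_pcf=gamma, kmin=kmin)
    out = np.empty_like(m)
    for i in range(m.shape[0]):
        segs = segment_sample_lrr(m[i], manifest, params)
        out[i] = segments_to_track(segs, manifest.n_probes)
    return out


def truth_identifiable(truth: TruthProfile, max_loh_frac: float = 0.6,
                       max_homdel_frac: float = 0.05) -> bool:
    """Whether a truth profile is recoverable from (LRR, BAF) at all.

    The admixture model admits exact alternative interpretations for some
    profiles: an all-even profile halves onto a lower ploidy (the classic
    whole-genome-duplication ambiguity), an all-odd profile maps onto
    (n+1)/2 + 1/2-shifted copies at doubled purity, and a profile whose
    implied genome lies outside the fitter's plausibility priors (LOH or
    homozygous-deletion fraction) cannot be selected. Such samples are
    degenerate for parameter-recovery purposes; no estimator can resolve
    them from the signal alone.
    """
    nA, nB = truth.nA, truth.nB
    if np.all(nA % 2 == 0) and np.all(nB % 2 == 0):
        return False
    if np.all(nA % 2 == 1) and np.all(nB % 2 == 1):
        return False
    loh = float(np.mean(nB == 0))
    homdel = float(np.mean((nA == 0) & (nB == 0)))
    if loh > max_loh_frac or homdel > max_homdel_frac:
        return False
    return True


def resolvable_probes(truth: TruthProfile, germline_genotype: np.ndarray,
                      manifest: SnpManifest, kmin: int = 10,
                      margin: int = 45) -> np.ndarray:
    """Mask of probes whose truth state is recoverable at ``kmin`` resolution.

    Truth runs with fewer than ``kmin`` germline-het probes are below the
    joint segmentation's minimum segment size (they occur at chromosome
    ends and where simulated events overlap); they, and a ``margin`` of
    neighbouring probes whose segment boundary they can displace, are
    excluded from exactness comparisons.
    """
    n = manifest.n_probes
    is_het = np.asarray(germline_genotype) == 1
    ok = np.zeros(n, dtype=bool)
    enc = truth.nA.astype(np.int32) * 64 + truth.nB
    for _, sl in manifest.iter_chrom_slices():
        t = enc[sl]
        brk = np.flatnonzero(np.diff(t)) + 1
        starts = np.concatenate(([0], brk))
        ends = np.concatenate((brk, [t.size]))
        het = is_het[sl]
        for a, b_ in zip(starts, ends):
            if het[a:b_].sum() >= kmin:
                ok[sl.start + a:sl.start + b_] = True
        for a, b_ in zip(starts, ends):
            if het[a:b_].sum() < kmin:
                lo = max(sl.start, sl.start + a - margin)
                hi = min(sl.stop, sl.start + b_ + margin)
                ok[lo:hi] = False
    return ok


def truth_calls(truth: TruthProfile, germline_genotype: np.ndarray,
                manifest: SnpManifest) -> CallTrack:
    """Oracle call track from a truth profile, using the ASCAT call rules.

    Gain/loss are relative to the rounded true ploidy; LOH requires nB = 0
    within a truth segment containing at least one germline-het probe.
    """
    ref = int(np.floor(truth.psi_true + 0.5))
    total = truth.nA + truth.nB
    state = np.where(total > ref, STATE_GAIN,
                     np.where(total < ref, STATE_LOSS,
                              STATE_NEUTRAL)).astype(np.int8)
    loh = np.zeros(total.size, dtype=bool)
    cnloh = np.zeros(total.size, dtype=bool)
    homdel = total == 0
    is_het = germline_genotype == GT_AB
    # segment-wise LOH: constant-(nA,nB) runs with >= 1 het probe
    for chrom, s_bp, e_bp, na, nb in truth.segments(manifest):
        if nb != 0:
            continue
        mask = _region_probe_mask(manifest, chrom, s_bp, e_bp)
        if is_het[mask].any():
            loh |= mask
            cnloh |= mask & (total == ref)
    return CallTrack(sample_id=truth.sample_id, state=state, loh=loh,
                     cnloh=cnloh, homdel=homdel)
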