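"""Aberration calling, cohort frequencies, recurrence and gene annotation.

Two calling modes:

* threshold mode — PCF segment means above 0.05 are gains, below -0.05
  losses (strict inequalities; the band is neutral);
* ASCAT mode — per-segment total copy number compared with the rounded
  tumour ploidy (half-up), with LOH / copy-neutral LOH / homozygous-deletion
  flags layered on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FrequencyTrack, RecurrentRegion, SnpManifest

GAIN_THRESHOLD = 0.05
LOSS_THRESHOLD = -0.05

STATE_LOSS = -1
STATE_NEUTRAL = 0
STATE_GAIN = 1


@dataclass
class CallTrack:
    """Per-probe aberration states for one sample.

    ``state`` holds gain/neutral/loss (+1/0/-1); ``loh``, ``cnloh`` and
    ``homdel`` are boolean flags (ASCAT mode only). The invariants
    homdel => loss and cnloh => loh hold by construction.
    """

    sample_id: str
    state: np.ndarray
    loh: np.ndarray = field(default=None)
    cnloh: np.ndarray = field(default=None)
    homdel: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.state.size
        for name in ("loh", "cnloh", "homdel"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n, dtype=bool))


def call_threshold(segments, n_probes: int, sample_id: str = "") -> CallTrack:
    """Gain/loss/neutral from PCF segment means at the +/-0.05 thresholds."""
    state = np.zeros(n_probes, dtype=np.int8)
    for s in segments:
        if s.mean_lrr > GAIN_THRESHOLD:
            state[s.start_idx:s.end_idx + 1] = STATE_GAIN
        elif s.mean_lrr < LOSS_THRESHOLD:
            state[s.start_idx:s.end_idx + 1] = STATE_LOSS
    return CallTrack(sample_id=sample_id, state=state)


def call_ascat(profile, n_probes: int) -> CallTrack:
    """States relative to the rounded tumour ploidy, with LOH flags.

    gain: total > round(psi); loss: total < round(psi); LOH: nB = 0 in a
    segment containing at least one germline-het probe; cnLOH: LOH at
    neutral total; homdel: total = 0.
    """
    ref = int(np.floor(profile.psi + 0.5))  # half-up
    state = np.zeros(n_probes, dtype=np.int8)
    loh = np.zeros(n_probes, dtype=bool)
    cnloh = np.zeros(n_probes, dtype=bool)
    homdel = np.zeros(n_probes, dtype=bool)
    for seg, na, nb in profile.segments:
        sl = slice(seg.start_idx, seg.end_idx + 1)
        total = na + nb
        if total > ref:
            state[sl] = STATE_GAIN
        elif total < ref:
            state[sl] = STATE_LOSS
        if nb == 0 and seg.n_het > 0:
            loh[sl] = True
            if total == ref:
                cnloh[sl] = True
        if total == 0:
            homdel[sl] = True
    return CallTrack(sample_id=profile.sample_id, state=state, loh=loh,
                     cnloh=cnloh, homdel=homdel)


def cohort_frequencies(calltracks, groups: dict | None = None) -> dict:
    """Per-probe gain/loss/LOH frequencies, overall and per group.

    ``groups`` maps group label -> list of sample ids; the overall track is
    always computed under the key ``"all"``. Frequencies are exact
    count / n_samples.
    """
    tracks = {t.sample_id: t for t in calltracks}
    if not tracks:
        raise ValueError("no call tracks supplied")
    n_probes = next(iter(tracks.values())).state.size
    wanted = {"all": list(tracks)}
    if groups:
        for label, members in groups.items():
            missing = [s for s in members if s not in tracks]
            members = [s for s in members if s in tracks]
            if not members:
                raise ValueError(f"group {label!r} has no samples with calls "
                                 f"(missing: {missing[:5]})")
            wanted[label] = members
    out = {}
    for label, members in wanted.items():
        gain = np.zeros(n_probes)
        loss = np.zeros(n_probes)
        loh = np.zeros(n_probes)
        for sid in members:
            t = tracks[sid]
            gain += t.state == STATE_GAIN
            loss += t.state == STATE_LOSS
            loh += t.loh
        n = len(members)
        out[label] = FrequencyTrack(group=label, n_samples=n,
                                    gain_freq=gain / n, loss_freq=loss / n,
                                    loh_freq=loh / n)
    return out


def _runs_to_regions(mask: np.ndarray, freq: np.ndarray,
                     manifest: SnpManifest, direction: str,
                     n_samples: int) -> list:
    regions = []
    for chrom, sl in manifest.iter_chrom_slices():
        m = mask[sl]
        if not m.any():
            continue
        # maximal runs of qualifying probes
        padded = np.concatenate(([False], m, [False]))
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        pos = manifest.pos[sl]
        for a, b in zip(starts, ends):
            peak = float(freq[sl][a:b + 1].max())
            regions.append(RecurrentRegion(
                chrom=chrom, start_bp=int(pos[a]), end_bp=int(pos[b]),
                direction=direction, peak_freq=peak,
                n_samples_affected=int(round(peak * n_samples)),
                start_idx=sl.start + int(a), end_idx=sl.start + int(b)))
    return regions


def recurrent_regions(freq_track: FrequencyTrack, manifest: SnpManifest,
                      mode: str = "fraction", threshold: float = 0.20,
                      min_count: int = 20,
                      directions=("gain", "loss", "LOH")) -> list:
    """Maximal probe runs meeting the recurrence rule, merged per direction.

    ``mode='fraction'``: probes with frequency >= threshold (default 20%);
    ``mode='count'``: probes carried by >= min_count samples (default 20).
    Both comparisons are inclusive.
    """
    n = freq_track.n_samples
    out = []
    for direction in directions:
        freq = {"gain": freq_track.gain_freq, "loss": freq_track.loss_freq,
                "LOH": freq_track.loh_freq}[direction]
        if freq is None:
            continue
        count = freq * n
        if mode == "fraction":
            mask = freq >= threshold - 1e-12
        elif mode == "count":
            mask = count >= min_count - 1e-9
        else:
            raise ValueError(f"unknown recurrence mode {mode!r}")
        out.extend(_runs_to_regions(mask, freq, manifest, direction, n))
    return out


def annotate_regions(regions, gene_bed: pd.DataFrame) -> list:
    """Attach overlapping genes (>= 1 bp, half-open arithmetic) to regions.

    Regions carry 1-based inclusive bp coordinates; gene intervals are BED
    half-open. Gene lists are sorted by gene start.
    """
    for region in regions:
        r_start0 = region.start_bp - 1  # half-open
        r_end0 = region.end_bp
        hits = gene_bed[(gene_bed["chrom"] == region.chrom)
                        & (gene_bed["start"] < r_end0)
                        & (gene_bed["end"] > r_start0)]
        region.genes = hits.sort_values("start")["name"].tolist()
    return regions


def gene_hit_counts(calltracks, gene_bed: pd.DataFrame,
                    manifest: SnpManifest, states=("loss",)) -> pd.Series:
    """Per-gene number of samples with any probe in a requested state.

    ``states`` may contain ``gain``, ``loss``, ``loh``, ``cnloh``,
    ``homdel``. Genes without any overlapping probe report NaN (missing),
    never 0.
    """
    chrom = manifest.chrom
    pos = manifest.pos
    counts = {}
    for _, gene in gene_bed.iterrows():
        on_chrom = chrom == gene["chrom"]
        in_gene = on_chrom & (pos >= gene["start"] + 1) & (pos <= gene["end"])
        if not in_gene.any():
            counts[gene["name"]] = np.nan
            continue
        idx = np.flatnonzero(in_gene)
        n_hit = 0
        for t in calltracks:
            hit = False
            for st in states:
                if st == "gain":
                    hit = hit or bool((t.state[idx] == STATE_GAIN).any())
                elif st == "loss":
                    hit = hit or bool((t.state[idx] == STATE_LOSS).any())
                else:
                    hit = hit or bool(getattr(t, st)[idx].any())
            n_hit += hit
        counts[gene["name"]] = n_hit
    return pd.Series(counts, name="+".join(states))


def regions_to_frame(regions) -> pd.DataFrame:
    rows = [{
        "chrom": r.chrom, "start": r.start_bp, "end": r.end_bp,
        "direction": r.direction, "peak_freq": r.peak_freq,
        "n_samples_affected": r.n_samples_affected,
        "genes": ",".join(r.genes) if r.genes else "",
    } for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction",
                                       "peak_freq", "n_samples_affected",
                                       "genes"])
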