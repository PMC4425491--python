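"""Penalized piecewise-constant-fit segmentation (PCF and joint ASPCF).

``pcf`` computes the exact minimizer of

    sum_i (y_i - m(i))^2  +  gamma * (number of breakpoints)

over all segmentations whose segments each contain at least ``kmin`` probes,
by dynamic programming (O(n^2), vectorized inner loop). ``aspcf`` runs the
allele-specific variant: LRR and mirrored BAF share breakpoints, each track's
squared error standardized by its robust (derivative-MAD) variance, with
breakpoints constrained to the germline-heterozygous probe grid.

Penalties are applied to variance-standardized data so that the conventional
penalty values (gamma = 80 for single-track LRR, 0.80 for ASPCF) transfer
across platforms with different noise levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import GT_AB, Segment, SnpManifest

MAD_SCALE = 1.4826
_SD_FLOOR = 1e-4  # keeps standardization defined on noise-free input


@dataclass
class SegParams:
    gamma_pcf: float = 80.0
    kmin: int = 10
    aspcf_penalty: float = 0.80
    coarsen: int = 1  # >1: candidate breakpoints every `coarsen` probes

    def __post_init__(self):
        if self.gamma_pcf <= 0 or self.aspcf_penalty <= 0:
            raise ValueError("penalties must be positive")
        if self.kmin < 1:
            raise ValueError("kmin must be >= 1")


def robust_sd(y: np.ndarray) -> float:
    """Noise sd estimate from first differences, robust to level shifts."""
    v = y[np.isfinite(y)]
    if v.size < 2:
        return _SD_FLOOR
    d = np.diff(v)
    sd = np.median(np.abs(d)) * MAD_SCALE / np.sqrt(2.0)
    return max(float(sd), _SD_FLOOR)


def _pcf_breaks(cost_fn, n: int, gamma: float, kmin: int):
    """Shared exact-DP engine.

    ``cost_fn(iarr, j)`` returns the segment cost for units iarr..j (vector
    over candidate starts). Ties break toward fewer segments, then the
    leftmost (smallest) start of the final segment.
    Returns a list of (start, end) unit index pairs.
    """
    G = np.full(n, np.inf)
    NS = np.zeros(n, dtype=np.int64)
    PREV = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        if j + 1 < kmin:
            continue
        if j + 1 >= 2 * kmin:
            iarr = np.concatenate(([0], np.arange(kmin, j - kmin + 2)))
        else:
            iarr = np.array([0], dtype=np.int64)
        prev_cost = np.where(iarr == 0, -gamma, G[iarr - 1])
        cand = prev_cost + gamma + cost_fn(iarr, j)
        m = cand.min()
        ties = np.flatnonzero(cand == m)
        if ties.size > 1:
            prev_ns = np.where(iarr[ties] == 0, 0, NS[iarr[ties] - 1])
            k = ties[int(np.argmin(prev_ns))]
        else:
            k = int(ties[0])
        G[j] = cand[k]
        PREV[j] = iarr[k]
        NS[j] = (0 if iarr[k] == 0 else NS[iarr[k] - 1]) + 1
    bounds = []
    j = n - 1
    while j >= 0:
        i = int(PREV[j])
        bounds.append((i, j))
        j = i - 1
    bounds.reverse()
    return bounds


def pcf_breaks(y: np.ndarray, gamma: float, kmin: int):
    """Exact PCF on a finite vector; returns [(start, end, mean), ...]."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n == 0:
        return []
    if not np.isfinite(y).all():
        raise ValueError("pcf input must be finite (drop missing first)")
    if n < kmin:
        warnings.warn("fewer probes than kmin; returning a single segment")
        return [(0, n - 1, float(y.mean()))]
    S = np.concatenate(([0.0], np.cumsum(y)))
    S2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def cost(iarr, j):
        lens = j - iarr + 1
        seg_sum = S[j + 1] - S[iarr]
        return (S2[j + 1] - S2[iarr]) - seg_sum * seg_sum / lens

    bounds = _pcf_breaks(cost, n, gamma, kmin)
    return [(i, j, float((S[j + 1] - S[i]) / (j - i + 1))) for i, j in bounds]


def _coarsen_refine(y, gamma, kmin, step):
    """Approximate PCF for very long tracks: solve on `step`-probe blocks,
    then refine each breakpoint locally with the exact objective."""
    n = y.size
    edges = np.arange(0, n, step)
    means = np.add.reduceat(y, edges) / np.diff(np.append(edges, n))
    weights = np.diff(np.append(edges, n))
    # weighted PCF on block means, penalty unchanged (cost uses block SSE)
    S = np.concatenate(([0.0], np.cumsum(means * weights)))
    W = np.concatenate(([0.0], np.cumsum(weights)))
    S2 = np.concatenate(([0.0], np.cumsum(means * means * weights)))

    def cost(iarr, j):
        w = W[j + 1] - W[iarr]
        s = S[j + 1] - S[iarr]
        return (S2[j + 1] - S2[iarr]) - s * s / w

    kmin_blocks = max(1, kmin // step)
    bounds = _pcf_breaks(cost, len(edges), gamma, kmin_blocks)
    breaks = [int(edges[i]) for i, _ in bounds[1:]]
    # local refinement of each break position on the raw data
    refined = []
    prev = 0
    for b in breaks:
        lo, hi = max(prev + kmin, b - step), min(n - kmin, b + step)
        best, best_cost = b, np.inf
        for c in range(lo, hi + 1):
            left = y[prev:c]
            right = y[c:min(n, c + 2 * step)]
            cc = left.var() * left.size + right.var() * right.size
            if cc < best_cost:
                best, best_cost = c, cc
        refined.append(best)
        prev = best
    out = []
    starts = [0] + refined
    ends = [b - 1 for b in refined] + [n - 1]
    for i, j in zip(starts, ends):
        out.append((i, j, float(y[i:j + 1].mean())))
    return out


def pcf(y: np.ndarray, manifest: SnpManifest, chrom: str,
        gamma: float = 80.0, kmin: int = 10, standardize: bool = True,
        coarsen: int = 1) -> list:
    """Segment one chromosome of one sample's (winsorized) LRR track.

    Missing probes are dropped for the fit and re-attached to the flanking
    segment on output so segments tile the chromosome. With
    ``standardize=True`` (default) the data are divided by their robust sd
    before applying ``gamma``, then segment means are reported on the
    original scale.
    """
    sl = manifest.chrom_slice(chrom)
    pos = manifest.pos[sl]
    y = np.asarray(y, dtype=float)
    if y.size != sl.stop - sl.start:
        raise ValueError("track length does not match chromosome probes")
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError(f"no finite values on {chrom}")
    idx_map = np.flatnonzero(ok)
    v = y[ok]
    sd = robust_sd(v) if standardize else 1.0
    if coarsen > 1 and v.size > 4 * coarsen * kmin:
        segs = _coarsen_refine(v / sd, gamma, kmin, coarsen)
    else:
        segs = pcf_breaks(v / sd, gamma, kmin)
    out = []
    n_all = y.size
    for si, (i, j, _) in enumerate(segs):
        gi = int(idx_map[i])
        gj = int(idx_map[j])
        # carry missing flanks into the first/last segment of the chromosome
        start = 0 if si == 0 else gi
        end = n_all - 1 if si == len(segs) - 1 else _next_start(idx_map, segs, si, n_all) - 1
        mean = float(v[i:j + 1].mean())
        out.append(Segment(
            chrom=chrom, start_idx=sl.start + start, end_idx=sl.start + end,
            start_bp=int(pos[start]), end_bp=int(pos[end]),
            n_probes=end - start + 1, mean_lrr=mean))
    return out


def _next_start(idx_map, segs, si, n_all):
    nxt = segs[si + 1][0]
    return int(idx_map[nxt])


def folded_mean_correct(d_mean: float, d_sq_mean: float) -> float:
    """Recover a segment's BAF band offset from its folded (mirrored) moments.

    Mirroring |b - 0.5| + 0.5 folds probe noise upward when the true band
    sits near 0.5: a balanced segment's mirrored mean is biased to
    0.5 + sd * sqrt(2/pi) instead of 0.5, which after the 1/rho inversion
    systematically distorts low-purity fits. With x = b - 0.5 ~ N(delta,
    sigma) the mirrored data give E[|x|] = delta(1 - 2 Phi(-delta/sigma))
    + 2 sigma phi(delta/sigma) and E[x^2] = delta^2 + sigma^2 exactly, so
    (delta, sigma) are identified from the segment's first two mirrored
    moments alone. Returns the debiased offset delta >= 0 (identity at
    zero noise).
    """
    from scipy.stats import norm

    if not np.isfinite(d_mean) or d_mean <= 0:
        return max(d_mean, 0.0) if np.isfinite(d_mean) else d_mean
    s2 = max(d_sq_mean, d_mean * d_mean)

    def folded_mean(delta):
        sig = np.sqrt(max(s2 - delta * delta, 1e-16))
        z = delta / sig
        return delta * (1 - 2 * norm.cdf(-z)) + 2 * sig * norm.pdf(z)

    if d_mean <= folded_mean(0.0):
        return 0.0
    lo, hi = 0.0, np.sqrt(s2)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if folded_mean(mid) < d_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mirror_baf(baf: np.ndarray, germline_genotype: np.ndarray) -> np.ndarray:
    """Mirrored BAF |b - 0.5| + 0.5 at germline-heterozygous probes.

    Homozygous, NoCall and missing-BAF probes are NaN-masked; mirroring
    removes the arbitrary A/B labelling so a balanced locus sits at 0.5.
    """
    b = np.asarray(baf, dtype=float)
    out = np.abs(b - 0.5) + 0.5
    mask = (np.asarray(germline_genotype) != GT_AB) | ~np.isfinite(b)
    out = np.where(mask, np.nan, out)
    return out


def aspcf(lrr: np.ndarray, mbaf: np.ndarray, manifest: SnpManifest,
          chrom: str, penalty: float = 0.80, kmin: int = 10) -> list:
    """Joint LRR + mirrored-BAF segmentation with shared breakpoints.

    Candidate breakpoints lie on the het-probe grid (probes with finite
    mBAF); each candidate segment's cost is the LRR SSE over all member
    probes plus the mBAF SSE over het probes, each divided by the track's
    robust variance, plus ``penalty`` per breakpoint. ``kmin`` counts het
    probes. Chromosomes without het probes yield one LRR-only segment
    flagged with ``n_het=0``.
    """
    sl = manifest.chrom_slice(chrom)
    pos = manifest.pos[sl]
    n_all = sl.stop - sl.start
    lrr = np.asarray(lrr, dtype=float)
    mbaf = np.asarray(mbaf, dtype=float)
    if lrr.size != n_all or mbaf.size != n_all:
        raise ValueError("track length does not match chromosome probes")
    het = np.flatnonzero(np.isfinite(mbaf))
    if het.size == 0:
        ok = np.isfinite(lrr)
        mean = float(lrr[ok].mean()) if ok.any() else float("nan")
        warnings.warn(f"no heterozygous probes on {chrom}; allele-specific "
                      "inference skipped")
        return [Segment(chrom=chrom, start_idx=sl.start, end_idx=sl.stop - 1,
                        start_bp=int(pos[0]), end_bp=int(pos[-1]),
                        n_probes=n_all, mean_lrr=mean, n_het=0)]
    # blocks: het probe t owns probes [het[t], het[t+1]-1]; first block
    # extends to the chromosome start, the last to the chromosome end.
    n_b = het.size
    block_start = np.empty(n_b, dtype=np.int64)
    block_start[0] = 0
    block_start[1:] = het[1:]
    # probes before het[1] but >= het[0]... assign [het[t], het[t+1]-1] to t;
    # leading probes [0, het[0]-1] join block 0.
    block_end = np.empty(n_b, dtype=np.int64)
    block_end[:-1] = het[1:] - 1
    block_end[-1] = n_all - 1

    lrr_fin = np.where(np.isfinite(lrr), lrr, 0.0)
    lrr_cnt = np.isfinite(lrr).astype(float)
    cL1 = np.concatenate(([0.0], np.cumsum(lrr_fin)))
    cL2 = np.concatenate(([0.0], np.cumsum(lrr_fin * lrr_fin)))
    cLn = np.concatenate(([0.0], np.cumsum(lrr_cnt)))

    def block_sums(arr_cum, t):
        return arr_cum[block_end[t] + 1] - arr_cum[block_start[t]]

    # cumulative sums over blocks
    BL1 = np.concatenate(([0.0], np.cumsum([block_sums(cL1, t) for t in range(n_b)])))
    BL2 = np.concatenate(([0.0], np.cumsum([block_sums(cL2, t) for t in range(n_b)])))
    BLn = np.concatenate(([0.0], np.cumsum([block_sums(cLn, t) for t in range(n_b)])))
    m = mbaf[het]
    BM1 = np.concatenate(([0.0], np.cumsum(m)))
    BM2 = np.concatenate(([0.0], np.cumsum(m * m)))

    sd_l = robust_sd(lrr)
    var_l = sd_l ** 2
    var_m = robust_sd(m) ** 2
    # The conventional ASPCF penalty is quoted on the raw squared-error
    # scale of the LRR track; the joint cost is variance-standardized, so
    # the penalty is mapped onto that scale via the LRR noise variance.
    # On (near) noise-free input the variance sits at its numerical floor;
    # the penalty then stays on the raw scale, which is negligible against
    # the floor-standardized cost of any true step, so every real
    # breakpoint is taken while exactly-flat stretches are never split.
    penalty_std = penalty if sd_l <= _SD_FLOOR else penalty / var_l

    def cost(iarr, j):
        nl = np.maximum(BLn[j + 1] - BLn[iarr], 1.0)
        s1 = BL1[j + 1] - BL1[iarr]
        sse_l = (BL2[j + 1] - BL2[iarr]) - s1 * s1 / nl
        nm = j - iarr + 1.0
        t1 = BM1[j + 1] - BM1[iarr]
        sse_m = (BM2[j + 1] - BM2[iarr]) - t1 * t1 / nm
        return sse_l / var_l + sse_m / var_m

    if n_b < kmin:
        bounds = [(0, n_b - 1)]
    else:
        bounds = _pcf_breaks(cost, n_b, penalty_std, kmin)
    out = []
    for i, j in bounds:
        gi, gj = int(block_start[i]), int(block_end[j])
        nl = BLn[j + 1] - BLn[i]
        mean_lrr = float((BL1[j + 1] - BL1[i]) / nl) if nl > 0 else float("nan")
        n_h = j - i + 1
        d_mean = float((BM1[j + 1] - BM1[i]) / n_h) - 0.5
        d_sq = float((BM2[j + 1] - BM2[i]) / n_h) \
            - 2 * 0.5 * (d_mean + 0.5) + 0.25
        mean_mbaf = 0.5 + folded_mean_correct(d_mean, d_sq)
        out.append(Segment(
            chrom=chrom, start_idx=sl.start + gi, end_idx=sl.start + gj,
            start_bp=int(pos[gi]), end_bp=int(pos[gj]),
            n_probes=gj - gi + 1, mean_lrr=mean_lrr,
            mean_mbaf=mean_mbaf, n_het=j - i + 1))
    return out


def segment_sample_lrr(lrr: np.ndarray, manifest: SnpManifest,
                       params: SegParams | None = None) -> list:
    """Single-track PCF over all chromosomes of one sample."""
    params = params or SegParams()
    segs = []
    for chrom, sl in manifest.iter_chrom_slices():
        segs.extend(pcf(lrr[sl], manifest, chrom, gamma=params.gamma_pcf,
                        kmin=params.kmin, coarsen=params.coarsen))
    return segs


def segment_sample_aspcf(lrr: np.ndarray, baf: np.ndarray,
                         germline_genotype: np.ndarray,
                         manifest: SnpManifest,
                         params: SegParams | None = None) -> list:
    """Joint ASPCF over all chromosomes of one sample."""
    params = params or SegParams()
    mbaf = mirror_baf(baf, germline_genotype)
    segs = []
    for chrom, sl in manifest.iter_chrom_slices():
        segs.extend(aspcf(lrr[sl], mbaf[sl], manifest, chrom,
                          penalty=params.aspcf_penalty, kmin=params.kmin))
    return segs


def segments_to_track(segments, n_probes: int,
                      attr: str = "mean_lrr") -> np.ndarray:
    """Broadcast segment values back to a per-probe vector."""
    out = np.full(n_probes, np.nan)
    for s in segments:
        out[s.start_idx:s.end_idx + 1] = getattr(s, attr)
    return out
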