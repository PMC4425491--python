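"""Allele-specific copy number: forward model, inversion, purity/ploidy fit.

The model links a segment's allele-specific copy numbers (nA, nB), the
aberrant cell fraction rho and the tumour ploidy psi to the expected SNP-array
signal at a germline-heterozygous locus:

    r = gamma_platform * log2( (2(1-rho) + rho*(nA+nB)) / (2(1-rho) + rho*psi) )
    b = (1 - rho + rho*nB) / (2(1-rho) + rho*(nA+nB))

gamma_platform is the platform compression factor (how much of a true copy
doubling the array's log ratio actually reports; 0.40 here). The admixture
with 2 copies of normal DNA per non-tumour cell shrinks both signals toward
the diploid baseline as rho decreases.

``fit_purity_ploidy`` inverts segment means on a (rho, psi) grid and scores
each candidate by the weighted squared distance of the continuous allele
copies from non-negative integers; the grid minimum, with a degeneracy guard
and deterministic tie-breaking (lower psi, then higher rho), yields the
profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AscatProfile

log = logging.getLogger(__name__)

HOMDEL_LRR_SENTINEL = -8.0  # -inf surrogate for total copy number 0 at rho=1


@dataclass
class AscatParams:
    gamma_platform: float = 0.40
    rho_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.10, 1.0001, 0.01), 2))
    psi_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1.0, 5.5001, 0.05), 2))
    min_goodness: float = 0.80
    # exact-path parsimony: candidates whose refined distance is within
    # ghost_rel x the best (plus a small absolute floor) count as
    # equivalent-fit solutions, among which the lowest fitted ploidy wins
    ghost_rel: float = 25.0
    ghost_abs_frac: float = 1e-6
    # feasibility threshold on the noise-debiased distance, in null sds;
    # generous because segment means carry systematic (breakpoint-placement)
    # error beyond propagated probe noise
    z_max: float = 50.0
    # plausibility vetoes on a candidate cell's implied genome: fraction of
    # het weight with nB = 0 (LOH) and with total 0 (homozygous deletion)
    max_loh_frac: float = 0.6
    max_homdel_frac: float = 0.05
    # cells where more than this weight fraction of propagated variances hit
    # the rounding-residual cap carry no allele-resolution information
    max_capped_frac: float = 0.1

    def __post_init__(self):
        if not (0 < self.gamma_platform <= 1):
            raise ValueError("gamma_platform must be in (0, 1]")
        if len(self.rho_grid) == 0 or len(self.psi_grid) == 0:
            raise ValueError("grids must be non-empty")
        if np.any(self.rho_grid <= 0) or np.any(self.rho_grid > 1):
            raise ValueError("rho grid must lie in (0, 1]")
        if np.any(self.psi_grid <= 0) or np.any(self.psi_grid > 8):
            raise ValueError("psi grid must lie in (0, 8]")


def predict_signal(nA, nB, rho, psi, gamma_platform: float = 0.40):
    """Expected (LRR, BAF) at a germline-heterozygous locus.

    Total copy number 0 with rho = 1 leaves no DNA: BAF is undefined (NaN)
    and LRR is returned as the documented -inf surrogate.
    """
    nA = np.asarray(nA, dtype=float)
    nB = np.asarray(nB, dtype=float)
    if np.any(rho <= 0) or np.any(np.asarray(rho) > 1):
        raise ValueError("rho must be in (0, 1]")
    if np.any(np.asarray(psi) <= 0):
        raise ValueError("psi must be positive")
    total = nA + nB
    num = 2 * (1 - rho) + rho * total
    den = 2 * (1 - rho) + rho * psi
    with np.errstate(divide="ignore", invalid="ignore"):
        r = gamma_platform * np.log2(num / den)
        b = (1 - rho + rho * nB) / num
    empty = num == 0
    r = np.where(empty, HOMDEL_LRR_SENTINEL, r)
    b = np.where(empty, np.nan, b)
    if r.ndim == 0:
        return float(r), float(b)
    return r, b


def invert_signal(r, b, rho, psi, gamma_platform: float = 0.40):
    """Continuous allele-specific copy numbers from observed (LRR, BAF).

    Exact inverse of :func:`predict_signal` on its domain; outputs may be
    negative (noise) and are rounded/clipped later by the grid fit.
    """
    if np.any(np.asarray(rho) <= 0):
        raise ValueError("rho must be positive (no tumour content at rho=0)")
    r = np.asarray(r, dtype=float)
    b = np.asarray(b, dtype=float)
    t = 2.0 ** (r / gamma_platform) * (2 * (1 - rho) + rho * psi)
    nB_raw = (rho - 1 + b * t) / rho
    nA_raw = (rho - 1 + (1 - b) * t) / rho
    if nA_raw.ndim == 0:
        return float(nA_raw), float(nB_raw)
    return nA_raw, nB_raw


def round_nonneg(x: np.ndarray) -> np.ndarray:
    """Nearest non-negative integer, half-up."""
    return np.maximum(np.floor(np.asarray(x, dtype=float) + 0.5), 0.0)


def classify_ploidy(psi: float) -> str:
    """Ploidy bin: closed intervals, diploid [1.8, 2.2], tetraploid [3.8, 4.2]."""
    if psi <= 0:
        raise ValueError("psi must be positive")
    if psi < 1.8:
        return "hypodiploid"
    if psi <= 2.2:
        return "diploid"
    if 3.8 <= psi <= 4.2:
        return "tetraploid"
    if psi > 4.2:
        return "highly_polyploid"
    return "aneuploid_other"


def fit_purity_ploidy(segments, params: AscatParams | None = None,
                      sample_id: str = "", lrr_sd: float = 0.0,
                      baf_sd: float = 0.0) -> AscatProfile | None:
    """Grid search for (rho, psi) and integer allele copies from ASPCF segments.

    Segments with germline-het probes drive the fit (weight = het count).
    At each grid point the segment means are inverted to continuous allele
    copies and scored by

        D(rho, psi) = sum_seg w_seg * [(nA_raw - [nA_raw]+)^2
                                        + (nB_raw - [nB_raw]+)^2]

    with [.]+ the nearest non-negative integer. The model has exact
    lower/higher-ploidy ghost solutions ((nA-1, nB-1) at rho/(1+rho) and
    (nA+1, nB+1) at rho/(1-rho)) whose distances are statistically
    indistinguishable from the truth, so among grid cells whose distance
    lies within a near-tie margin of the minimum the lowest ploidy is
    selected (then, within that ploidy, the best-fitting rho; exact ties go
    to higher rho). Grid cells whose entire profile rounds to a single
    (nA, nB) pair carry a fixed penalty (degenerate fits are uninformative
    about rho). Goodness is 1 - D_min / (95th percentile of D over the
    grid); profiles below ``min_goodness`` are rejected (returns None, as
    happens for a few real tumours).

    With measured per-probe noise levels (``lrr_sd``, ``baf_sd``) the
    selection additionally debiases D by its expected noise contribution:
    the inversion amplifies noise by 1/rho, so the raw distance is
    systematically cheapest at rho = 1 regardless of the data. Cells whose
    debiased distance exceeds ``z_max`` null standard deviations are
    infeasible; among feasible cells the lowest ploidy wins (then the best
    debiased fit, then higher rho). With the default zero noise the fit is
    an exact-match criterion appropriate for noise-free input.
    """
    params = params or AscatParams()
    het = [s for s in segments
           if s.n_het > 0 and np.isfinite(s.mean_mbaf) and np.isfinite(s.mean_lrr)]
    if not het:
        log.warning("sample %s: no heterozygous segments; no profile", sample_id)
        return None
    r = np.array([s.mean_lrr for s in het])
    b = np.array([s.mean_mbaf for s in het])  # mirrored, >= 0.5
    w = np.array([s.n_het for s in het], dtype=float)
    n_lrr = np.array([s.n_probes for s in het], dtype=float)
    rho_g = np.asarray(params.rho_grid, dtype=float)
    psi_g = np.asarray(params.psi_grid, dtype=float)
    g = params.gamma_platform
    ln2_g = np.log(2.0) / g
    var_cap = 1.0 / 12.0  # variance of a rounding residual, Uniform(-.5,.5)

    D = np.empty((psi_g.size, rho_g.size))
    E = np.zeros_like(D)   # expected noise contribution to D
    V = np.zeros_like(D)   # its variance
    degenerate = np.zeros_like(D, dtype=bool)
    loh_frac = np.zeros_like(D)
    homdel_frac = np.zeros_like(D)
    capped = np.zeros_like(D)
    pow_r = 2.0 ** (r / g)
    have_noise = lrr_sd > 0 or baf_sd > 0
    W = float(w.sum())
    for ri, rho in enumerate(rho_g):
        # vectorized over psi x segments
        t = pow_r[None, :] * (2 * (1 - rho) + rho * psi_g[:, None])
        n_maj = (rho - 1 + b[None, :] * t) / rho
        n_min = (rho - 1 + (1 - b[None, :]) * t) / rho
        NA = round_nonneg(n_maj)
        NB = round_nonneg(n_min)
        D[:, ri] = np.sum(w[None, :] * ((n_maj - NA) ** 2
                                        + (n_min - NB) ** 2), axis=1)
        degenerate[:, ri] = (np.all(NA == NA[:, :1], axis=1)
                             & np.all(NB == NB[:, :1], axis=1))
        loh_frac[:, ri] = np.sum(w[None, :] * (NB == 0), axis=1) / W
        homdel_frac[:, ri] = np.sum(w[None, :] * ((NA == 0) & (NB == 0)),
                                    axis=1) / W
        if have_noise:
            var_t = (t * ln2_g) ** 2 * lrr_sd ** 2 / n_lrr[None, :]
            var_b = baf_sd ** 2 / w[None, :]
            var_maj = np.minimum(((t / rho) ** 2 * var_b
                                  + (b[None, :] / rho) ** 2 * var_t), var_cap)
            var_min = np.minimum(((t / rho) ** 2 * var_b
                                  + ((1 - b[None, :]) / rho) ** 2 * var_t),
                                 var_cap)
            E[:, ri] = np.sum(w[None, :] * (var_maj + var_min), axis=1)
            V[:, ri] = np.sum(w[None, :] ** 2 * 2
                              * (var_maj ** 2 + var_min ** 2), axis=1)
            capped[:, ri] = np.sum(
                w[None, :] * ((var_maj >= var_cap) + (var_min >= var_cap)),
                axis=1) / (2 * W)
    D_pen = D + np.where(degenerate, 0.05 * W, 0.0)

    def cell_profile(pi, ri):
        rho, psi = rho_g[ri], psi_g[pi]
        t = pow_r * (2 * (1 - rho) + rho * psi)
        return (round_nonneg((rho - 1 + b * t) / rho),
                round_nonneg((rho - 1 + (1 - b) * t) / rho))

    def assign(rho, psi):
        t = pow_r * (2 * (1 - rho) + rho * psi)
        n_maj = (rho - 1 + b * t) / rho
        n_min = (rho - 1 + (1 - b) * t) / rho
        return round_nonneg(n_maj), round_nonneg(n_min)

    def dist_uv(u, v, NA, NB):
        # u = rho, v = 2(1-rho) + rho*psi (the model's mixture denominator);
        # the rho/psi distance valley runs along v = const, so coordinate
        # descent in (u, v) does not stall on a diagonal ridge
        t = pow_r * v
        n_maj = (u - 1 + b * t) / u
        n_min = (u - 1 + (1 - b) * t) / u
        return float(np.sum(w * ((n_maj - NA) ** 2 + (n_min - NB) ** 2)))

    def refine(pi, ri, wide=False):
        """Continuous (rho, psi) polish within the selected grid cell's basin.

        The grid quantizes psi in 0.05 steps and the distance optimum partly
        compensates a psi offset by shifting rho off the truth; after cell
        selection the pair is polished by multi-scale coordinate descent in
        (rho, denominator) space, re-deriving the integer assignment each
        round. ``wide`` loosens the rho box for the exact-match path, where
        the quantized column argmin can sit several grid steps from the
        basin centre.
        """
        rho0, psi0 = float(rho_g[ri]), float(psi_g[pi])
        step_r = rho_g[1] - rho_g[0] if rho_g.size > 1 else 0.01
        drho = step_r * (6 if wide else 2)
        dpsi = (psi_g[1] - psi_g[0]) * 1.5 if psi_g.size > 1 else 0.075
        u0 = rho0
        v0 = 2 * (1 - rho0) + rho0 * psi0
        dv = dpsi * rho0 + 2.5 * drho
        lo = (max(rho0 - drho, 1e-3), v0 - dv)
        hi = (min(rho0 + drho, 1.0), v0 + dv)
        uv = [u0, v0]
        for _ in range(3):
            psi_cur = (uv[1] - 2 * (1 - uv[0])) / uv[0]
            NA, NB = assign(uv[0], max(psi_cur, 1e-3))
            for scale in (1.0, 0.2, 0.04, 0.008):
                for _ in range(8):
                    moved = False
                    for k, step in ((0, 0.002 * scale), (1, 0.002 * scale)):
                        best_d = dist_uv(uv[0], uv[1], NA, NB)
                        for sgn in (+1, -1):
                            x2 = list(uv)
                            x2[k] = min(max(uv[k] + sgn * step, lo[k]), hi[k])
                            d2 = dist_uv(x2[0], x2[1], NA, NB)
                            while d2 < best_d - 1e-15:
                                best_d = d2
                                uv = list(x2)
                                moved = True
                                x2 = list(x2)
                                x2[k] = min(max(x2[k] + sgn * step, lo[k]),
                                            hi[k])
                                d2 = dist_uv(x2[0], x2[1], NA, NB)
                    if not moved:
                        break
        rho1 = uv[0]
        psi1 = (uv[1] - 2 * (1 - rho1)) / rho1
        NA, NB = assign(rho1, max(psi1, 1e-3))
        return rho1, psi1, dist_uv(rho1, uv[1], NA, NB)

    pi = ri = None
    if have_noise:
        excess = D_pen - E
        sd_null = np.sqrt(V) + 1e-12
        feasible = ((excess <= params.z_max * sd_null)
                    & (loh_frac <= params.max_loh_frac)
                    & (homdel_frac <= params.max_homdel_frac)
                    & (capped <= params.max_capped_frac))
        if feasible.any():
            pi = int(np.flatnonzero(feasible.any(axis=1))[0])  # lowest psi
            row = np.where(feasible[pi], excess[pi], np.inf)
            m = row.min()
            ri = int(np.flatnonzero(row == m)[-1])  # ties -> higher rho
            rho_hat, psi_hat, d_sel = refine(pi, ri)

    if pi is None:
        # exact-match path: refine each psi column's best cell and choose
        # by refined distance; among near-exact equivalents (ghost family,
        # which all refine to the same fit quality) prefer the lowest
        # ploidy, then the higher rho
        col_min = D_pen.min(axis=1)
        keep = col_min <= 200.0 * float(col_min.min()) + 1e-3 * W
        keep[np.argsort(col_min, kind="stable")[:8]] = True
        cand = []
        for pi2 in range(psi_g.size):
            if not keep[pi2]:
                continue
            row = D_pen[pi2]
            ri0 = int(np.flatnonzero(row == row.min())[-1])
            rho2, psi2, d2 = refine(pi2, ri0, wide=True)
            ri2 = ri0
            for ri_alt in (ri0 - 2, ri0 + 2):
                if 0 <= ri_alt < rho_g.size:
                    ralt, palt, dalt = refine(pi2, ri_alt, wide=True)
                    if dalt < d2 - 1e-15:
                        rho2, psi2, d2, ri2 = ralt, palt, dalt, ri_alt
            NA2, NB2 = assign(rho2, psi2)
            psi_fit2 = float(np.sum(w * (NA2 + NB2)) / W)
            loh2 = float(np.sum(w * (NB2 == 0)) / W)
            homdel2 = float(np.sum(w * ((NA2 == 0) & (NB2 == 0))) / W)
            plausible = (loh2 <= params.max_loh_frac
                         and homdel2 <= params.max_homdel_frac)
            cand.append((d2, psi_fit2, rho2, psi2, pi2, ri2, plausible))
        pool = [c for c in cand if c[6]] or cand
        d_best = min(c[0] for c in pool)
        bound = params.ghost_rel * d_best + params.ghost_abs_frac * W
        near = [c for c in pool if c[0] <= bound]
        # lowest fitted ploidy first; among equal profiles the better fit,
        # and only then (exact ties) the higher rho
        near.sort(key=lambda c: (round(c[1], 6), c[0], -c[2]))
        d_sel, _, rho_hat, psi_hat, pi, ri, _ = near[0]

    p95 = float(np.percentile(D_pen, 95))
    goodness = 1.0 - d_sel / max(p95, 1e-12)
    goodness = float(np.clip(goodness, 0.0, 1.0))
    if goodness < params.min_goodness:
        log.warning("sample %s: goodness %.3f below threshold; no profile",
                    sample_id, goodness)
        return None

    # assign integer copies to every segment at the chosen (rho, psi)
    out_segs = []
    tot_copies = 0.0
    tot_probes = 0.0
    for s in segments:
        if not np.isfinite(s.mean_lrr):
            continue
        t = 2.0 ** (s.mean_lrr / g) * (2 * (1 - rho_hat) + rho_hat * psi_hat)
        if s.n_het > 0 and np.isfinite(s.mean_mbaf):
            n_maj = (rho_hat - 1 + s.mean_mbaf * t) / rho_hat
            n_min = (rho_hat - 1 + (1 - s.mean_mbaf) * t) / rho_hat
            na = int(round_nonneg(n_maj))
            nb = int(round_nonneg(n_min))
        else:
            # no allelic information: split the total evenly, nA >= nB
            n_tot = (t - 2 * (1 - rho_hat)) / rho_hat
            tot = int(round_nonneg(n_tot))
            na, nb = tot - tot // 2, tot // 2
        if nb > na:
            na, nb = nb, na
        out_segs.append((s, na, nb))
        tot_copies += (na + nb) * s.n_probes
        tot_probes += s.n_probes
    psi_fit = tot_copies / tot_probes if tot_probes else float("nan")
    return AscatProfile(sample_id=sample_id, rho=float(round(rho_hat, 4)),
                        psi=float(psi_fit), goodness=goodness,
                        segments=out_segs, psi_grid=float(psi_hat))


def fit_sample(lrr: np.ndarray, baf: np.ndarray, germline_genotype,
               manifest, seg_params=None, params: AscatParams | None = None,
               sample_id: str = "") -> AscatProfile | None:
    """ASPCF-segment one sample and fit its profile with measured noise."""
    from .segmentation import mirror_baf, robust_sd, segment_sample_aspcf
    segs = segment_sample_aspcf(lrr, baf, germline_genotype, manifest,
                                seg_params)
    mbaf = mirror_baf(baf, germline_genotype)
    m = mbaf[np.isfinite(mbaf)]
    lrr_sd = robust_sd(lrr)
    baf_sd = robust_sd(m) if m.size else 0.0
    # robust_sd floors at 1e-4; treat that floor as "no measurable noise"
    if lrr_sd <= 2e-4 and baf_sd <= 2e-4:
        lrr_sd = baf_sd = 0.0
    return fit_purity_ploidy(segs, params, sample_id=sample_id,
                             lrr_sd=lrr_sd, baf_sd=baf_sd)


def fit_cohort(tracks, seg_params=None, params: AscatParams | None = None) -> dict:
    """Fit every tumour in a cohort; samples without a profile are omitted."""
    profiles = {}
    for i, sid in enumerate(tracks.samples):
        prof = fit_sample(tracks.tumour_lrr[i], tracks.tumour_baf[i],
                          tracks.germline_genotype[i], tracks.manifest,
                          seg_params, params, sample_id=sid)
        if prof is not None:
            profiles[sid] = prof
    return profiles
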