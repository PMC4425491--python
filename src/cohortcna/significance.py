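"""Permutation significance of recurrent aberrations, GISTIC-style.

The statistic at each genomic location is the sum of the segmented values
across samples. The null distribution is built by permuting, independently
within each sample, that sample's per-probe segmented values across genomic
locations, recomputing the location sums for each of ``n_perm`` replicates.
Pointwise empirical p-values (add-one corrected) are then FDR-adjusted by
Benjamini-Hochberg and significant probe runs are merged into regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calls import _runs_to_regions
from .datatypes import SnpManifest


@dataclass
class PermParams:
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    direction: str = "two_sided_abs"  # or "split_amp_del"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.direction not in ("two_sided_abs", "split_amp_del"):
            raise ValueError(f"unknown direction mode {self.direction!r}")


@dataclass
class SignificanceTrack:
    G: np.ndarray
    G_pos: np.ndarray
    G_neg: np.ndarray
    p_value: np.ndarray          # two-sided (or min of split one-sided)
    q_value: np.ndarray
    significant: np.ndarray
    p_pos: np.ndarray = None
    p_neg: np.ndarray = None
    significant_pos: np.ndarray = None  # split mode: per-direction BH
    significant_neg: np.ndarray = None
    alpha: float = 0.05


def location_sums(seg_matrix: np.ndarray):
    """G_j = sum over samples of the segmented value at probe j.

    Returns (G, G_pos, G_neg) with G = G_pos + G_neg (positive/negative
    part sums for the split amplification/deletion mode).
    """
    m = np.asarray(seg_matrix, dtype=float)
    G = m.sum(axis=0)
    G_pos = np.clip(m, 0, None).sum(axis=0)
    G_neg = np.clip(m, None, 0).sum(axis=0)
    return G, G_pos, G_neg


def permutation_null(seg_matrix: np.ndarray, params: PermParams,
                     rng: np.random.Generator | None = None):
    """Null location-sum tracks from within-sample probe permutations.

    Returns (null_G, null_pos, null_neg), each (n_perm, n_probes). The
    per-sample value multiset is preserved in every replicate; only genomic
    location is randomized.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    m = np.asarray(seg_matrix, dtype=float)
    n_perm = params.n_perm
    null_G = np.empty((n_perm, m.shape[1]))
    null_pos = np.empty_like(null_G)
    null_neg = np.empty_like(null_G)
    for r in range(n_perm):
        perm = rng.permuted(m, axis=1)
        null_G[r] = perm.sum(axis=0)
        null_pos[r] = np.clip(perm, 0, None).sum(axis=0)
        null_neg[r] = np.clip(perm, None, 0).sum(axis=0)
    return null_G, null_pos, null_neg


def empirical_pvalues(obs: np.ndarray, null: np.ndarray,
                      direction: str = "two_sided_abs") -> np.ndarray:
    """Pointwise p = (1 + #{null >= obs}) / (1 + n_perm).

    ``two_sided_abs`` compares |null| against |obs|; ``greater`` and
    ``less`` are the one-sided exceedances used by the split mode.
    """
    n_perm = null.shape[0]
    if direction == "two_sided_abs":
        exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    elif direction == "greater":
        exceed = (null >= obs[None, :]).sum(axis=0)
    elif direction == "less":
        exceed = (null <= obs[None, :]).sum(axis=0)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return (1.0 + exceed) / (1.0 + n_perm)


def benjamini_hochberg(pvals: np.ndarray, alpha: float = 0.05):
    """Standard BH step-up: q_i = min_{k>=i} p_(k) * m / k, reject q <= alpha."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q, q <= alpha


def significance_test(seg_matrix: np.ndarray,
                      params: PermParams | None = None,
                      rng: np.random.Generator | None = None) -> SignificanceTrack:
    """Full permutation test on a samples x probes segmented matrix."""
    params = params or PermParams()
    G, G_pos, G_neg = location_sums(seg_matrix)
    null_G, null_pos, null_neg = permutation_null(seg_matrix, params, rng)
    p_pos = empirical_pvalues(G_pos, null_pos, "greater")
    p_neg = empirical_pvalues(G_neg, null_neg, "less")
    if params.direction == "two_sided_abs":
        p = empirical_pvalues(G, null_G, "two_sided_abs")
        q, sig = benjamini_hochberg(p, params.alpha)
        return SignificanceTrack(G=G, G_pos=G_pos, G_neg=G_neg, p_value=p,
                                 q_value=q, significant=sig, p_pos=p_pos,
                                 p_neg=p_neg, alpha=params.alpha)
    # split mode: amplification and deletion analyzed (and FDR-adjusted)
    # separately, as their peak regions are reported separately
    q_pos, rej_pos = benjamini_hochberg(p_pos, params.alpha)
    q_neg, rej_neg = benjamini_hochberg(p_neg, params.alpha)
    p = np.minimum(p_pos, p_neg)
    q = np.minimum(q_pos, q_neg)
    return SignificanceTrack(G=G, G_pos=G_pos, G_neg=G_neg, p_value=p,
                             q_value=q, significant=rej_pos | rej_neg,
                             p_pos=p_pos, p_neg=p_neg,
                             significant_pos=rej_pos, significant_neg=rej_neg,
                             alpha=params.alpha)


def significant_regions(track: SignificanceTrack,
                        manifest: SnpManifest) -> list:
    """Maximal runs of significant probes, split by sign of G."""
    regions = []
    if track.significant_pos is not None:
        masks = (("gain", track.significant_pos),
                 ("loss", track.significant_neg))
    else:
        masks = (("gain", track.significant & (track.G > 0)),
                 ("loss", track.significant & (track.G < 0)))
    for direction, mask in masks:
        freq = np.abs(track.G)
        regions.extend(_runs_to_regions(mask, freq, manifest, direction,
                                        n_samples=1))
    for r in regions:
        r.n_samples_affected = 0  # statistic-based, not a carrier count
    return regions


def three_set_analysis(seg_matrix: np.ndarray, sample_ids, metadata,
                       params: PermParams | None = None,
                       seed: int | None = None) -> dict:
    """Run the test on the two split-pair sets and on all tumours.

    Tumours from one dog are possibly related, so multi-tumour dogs are
    split across two analysis sets (single tumours belong to both); the
    third set is everything. Returns {set label: SignificanceTrack}.
    """
    from .pipeline import split_by_dog
    params = params or PermParams()
    set_a, set_b, set_all = split_by_dog(
        metadata, seed=params.seed if seed is None else seed)
    idx = {sid: i for i, sid in enumerate(sample_ids)}
    out = {}
    for label, members in (("set_a", set_a), ("set_b", set_b),
                           ("all", set_all)):
        members = [s for s in members if s in idx]
        rows = [idx[s] for s in members]
        rng = np.random.default_rng(params.seed + 1)
        out[label] = significance_test(seg_matrix[rows], params, rng)
    return out
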