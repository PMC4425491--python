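"""LRR preprocessing: GC-wave correction, quantile normalization, winsorization.

Tumour LRR tracks on SNP arrays show a slow "wave" correlated with local GC
content plus occasional extreme outliers; both distort segmentation. The
pipeline order is GC correction first, then quantile normalization to a
Gaussian reference, then per-chromosome winsorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import SnpManifest

MAD_SCALE = 1.4826  # consistent sd estimate for Gaussian data


@dataclass
class PreprocessParams:
    gc_window_bp: float = 1_000_000.0
    winsor_k: float = 2.5
    winsor_window: int = 25
    reference_location: float = 0.0
    reference_scale: float = 1.0

    def __post_init__(self):
        if self.gc_window_bp <= 0 or self.winsor_k <= 0:
            raise ValueError("gc_window_bp and winsor_k must be positive")


def smoothed_gc(manifest: SnpManifest, window_bp: float) -> np.ndarray:
    """Running mean of gc_fraction over a window_bp span, per chromosome."""
    gc = manifest.gc_fraction
    pos = manifest.pos.astype(float)
    out = np.full_like(gc, np.nan, dtype=float)
    half = window_bp / 2.0
    for _, sl in manifest.iter_chrom_slices():
        g = gc[sl]
        p = pos[sl]
        ok = np.isfinite(g)
        if not ok.any():
            continue
        gp, pp = g[ok], p[ok]
        cs = np.concatenate(([0.0], np.cumsum(gp)))
        lo = np.searchsorted(pp, p - half, side="left")
        hi = np.searchsorted(pp, p + half, side="right")
        cnt = np.maximum(hi - lo, 1)
        out[sl] = (cs[hi] - cs[lo]) / cnt
    return out


def gc_correct(lrr: np.ndarray, manifest: SnpManifest,
               params: PreprocessParams | None = None) -> np.ndarray:
    """Remove the GC wave: residuals of LRR ~ smoothed GC, median-preserved.

    A least-squares line of LRR on window-smoothed local GC is subtracted and
    the result re-centred to the input's median, so corrected values stay on
    the log2-ratio scale. If GC has zero variance the input is returned
    unchanged with a warning.
    """
    params = params or PreprocessParams()
    gcs = smoothed_gc(manifest, params.gc_window_bp)
    y = np.asarray(lrr, dtype=float)
    ok = np.isfinite(y) & np.isfinite(gcs)
    if ok.sum() < 3 or np.nanstd(gcs[ok]) < 1e-9:  # constant up to roundoff
        warnings.warn("gc_correct: GC context constant or insufficient; "
                      "returning input unchanged")
        return y.copy()
    slope, intercept = np.polyfit(gcs[ok], y[ok], 1)
    out = y.copy()
    med = np.median(y[ok])
    out[ok] = y[ok] - (slope * gcs[ok] + intercept) + med
    return out


def quantile_normalize(values: np.ndarray, location: float = 0.0,
                       scale: float = 1.0) -> np.ndarray:
    """Map a track's order statistics onto Gaussian quantiles.

    The i-th smallest value becomes ``Phi^-1((i - 0.5)/n) * scale + location``;
    ranks (stable, ties by input order) are preserved exactly.
    """
    y = np.asarray(values, dtype=float)
    out = np.full_like(y, np.nan)
    ok = np.isfinite(y)
    n = int(ok.sum())
    if n == 0:
        return out
    v = y[ok]
    if np.ptp(v) == 0:
        warnings.warn("quantile_normalize: constant input mapped to location")
        out[ok] = location
        return out
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    targets = stats.norm.ppf((np.arange(n) + 0.5) / n) * scale + location
    out[ok] = targets[ranks]
    return out


def _running_median(y: np.ndarray, window: int) -> np.ndarray:
    # centred rolling median; shrinks at the ends
    import pandas as pd
    s = pd.Series(y)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def winsorize(track: np.ndarray, manifest: SnpManifest,
              params: PreprocessParams | None = None) -> np.ndarray:
    """Clamp outliers to running-median +/- k * (scaled MAD), per chromosome.

    The MAD (scaled by 1.4826) of deviations from the running median is a
    robust per-chromosome noise estimate; chromosomes shorter than the window
    fall back to a global median/MAD.
    """
    params = params or PreprocessParams()
    y = np.asarray(track, dtype=float)
    out = y.copy()
    k = params.winsor_k
    win = params.winsor_window
    for _, sl in manifest.iter_chrom_slices():
        v = y[sl]
        ok = np.isfinite(v)
        if ok.sum() < 2:
            continue
        if ok.sum() < win:
            centre = np.full(v.shape, np.median(v[ok]))
        else:
            centre = _running_median(v, win)
        resid = v - centre
        mad = np.nanmedian(np.abs(resid[ok])) * MAD_SCALE
        if not np.isfinite(mad):
            continue
        # mad == 0 (noise-free signal): any probe off its running median is
        # an outlier and collapses onto it
        lo, hi = centre - k * mad, centre + k * mad
        out[sl] = np.clip(v, lo, hi)
    return out


def missing_fraction(matrix: np.ndarray) -> np.ndarray:
    """Per-sample fraction of missing entries (QC gate input)."""
    return np.mean(~np.isfinite(matrix), axis=1)


def germline_lrr_scale(germline_lrr: np.ndarray) -> float:
    """Reference scale: median of per-sample germline LRR standard deviations."""
    sds = []
    for row in np.atleast_2d(germline_lrr):
        v = row[np.isfinite(row)]
        if v.size >= 2:
            sds.append(np.std(v))
    if not sds:
        return 1.0
    return float(np.median(sds))


def preprocess_tumour_lrr(tumour_lrr: np.ndarray, manifest: SnpManifest,
                          params: PreprocessParams | None = None,
                          apply_quantile: bool = True,
                          scale: float | None = None) -> np.ndarray:
    """GC-correct, optionally quantile-normalize, then winsorize each sample."""
    params = params or PreprocessParams()
    out = np.empty_like(tumour_lrr, dtype=float)
    for i in range(tumour_lrr.shape[0]):
        y = gc_correct(tumour_lrr[i], manifest, params)
        if apply_quantile:
            y = quantile_normalize(y, params.reference_location,
                                   scale if scale is not None
                                   else params.reference_scale)
        out[i] = winsorize(y, manifest, params)
    return out
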