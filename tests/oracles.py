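"""Independent brute-force references used by the test suite."""

import numpy as np


def pcf_oracle_cost(y, gamma, kmin):
    """Optimal penalized-SSE segmentation cost by segment-count DP.

    Tabulates C[b, j] = best SSE of y[0..j] split into exactly b segments
    (each >= kmin probes) over every admissible b, then minimizes
    C[b, n-1] + gamma * (b - 1). Exhaustive over the segment-count
    dimension and structurally unlike the production single-pass DP, which
    folds the penalty into the recursion.
    """
    y = np.asarray(y, float)
    n = y.size
    S = np.concatenate(([0.0], np.cumsum(y)))
    S2 = np.concatenate(([0.0], np.cumsum(y * y)))
    i_idx = np.arange(n)[:, None]
    j_idx = np.arange(n)[None, :]
    lens = j_idx - i_idx + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        seg_sum = S[j_idx + 1] - S[i_idx]
        sse = (S2[j_idx + 1] - S2[i_idx]) - seg_sum ** 2 / lens
    sse = np.where(lens >= kmin, sse, np.inf)  # SSE[i, j], rows = starts

    bmax = n // kmin
    C = sse[0]  # one segment starting at 0
    best_total = C[n - 1]
    for b in range(2, bmax + 1):
        prev = np.concatenate(([np.inf], C[:-1]))  # C[b-1][i-1]
        C = np.min(prev[:, None] + sse, axis=0)
        total = C[n - 1] + gamma * (b - 1)
        if total < best_total:
            best_total = total
    return float(best_total)
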