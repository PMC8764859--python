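"""Changepoint detection for copy-number profiles.

Shared by the SNP-array caller (windowed median LogR) and the NGS caller
(per-bin copy ratio).  The scan recursively finds the *interval* whose mean
differs most from its complement (a CUSUM-type two-changepoint scan, exact
for an interval-versus-rest two-mean model), which detects short interior
CNV segments that a classic one-split-at-a-time binary segmentation dilutes
away.  A candidate is accepted when its sum-of-squares gain exceeds
``penalty_factor * sigma^2 * log(n)`` per new changepoint, with sigma
estimated robustly from first differences (MAD), so a constant noisy signal
yields a single segment.
"""

from __future__ import annotations

import numpy as np

__all__ = ["binary_segmentation", "robust_sigma"]


def robust_sigma(x: np.ndarray) -> float:
    """Noise sd estimate from the MAD of first differences."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return 0.0
    d = np.diff(x)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _best_interval(lo: int, hi: int, min_size: int, cs: np.ndarray):
    """Interval in [lo, hi) with the largest mean contrast to its complement.

    Returns (gain, i, j, n_changepoints); gain is the SSE reduction of the
    two-mean (inside/outside) model.  Intervals touching a boundary cost one
    changepoint, interior intervals two.
    """
    n = hi - lo
    if n < 2 * min_size:
        return 0.0, None, None, 0
    total = cs[hi] - cs[lo]
    best = (0.0, None, None, 0)
    for i in range(lo, hi - min_size + 1):
        js = np.arange(i + min_size, hi + 1)
        if i == lo:
            js = js[js < hi]  # whole range is not a candidate
        if len(js) == 0:
            continue
        n_in = js - i
        n_out = n - n_in
        sum_in = cs[js] - cs[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrast = sum_in / n_in - (total - sum_in) / np.maximum(n_out, 1)
            gains = np.where(n_out > 0, n_in * n_out / n * contrast ** 2, 0.0)
        k = int(np.argmax(gains))
        if gains[k] > best[0]:
            j = int(js[k])
            ncp = int(i > lo) + int(j < hi)
            best = (float(gains[k]), i, j, max(ncp, 1))
    return best


def binary_segmentation(x: np.ndarray, min_size: int = 4,
                        sigma: float | None = None,
                        penalty_factor: float = 3.0) -> list[tuple[int, int]]:
    """Split a 1-D signal into mean-homogeneous segments.

    Returns sorted half-open index intervals covering [0, len(x)).  ``sigma``
    (noise sd) is estimated from the data when not given; with sigma 0
    (noiseless) any exact mean change is split out.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    if sigma is None:
        sigma = robust_sigma(x)
    penalty = penalty_factor * max(sigma, 1e-12) ** 2 * np.log(max(n, 2))
    cs = np.concatenate([[0.0], np.cumsum(x)])
    segments = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        gain, i, j, ncp = _best_interval(lo, hi, min_size, cs)
        if i is not None and gain > ncp * penalty:
            for piece in ((lo, i), (i, j), (j, hi)):
                if piece[1] > piece[0]:
                    stack.append(piece)
        else:
            segments.append((lo, hi))
    return sorted(segments)
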