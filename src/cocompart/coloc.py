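"""Pixel-level colocalization statistics: Pearson, Costes thresholds, Manders.

The autophagic-flux readout of the pipeline: R_total (Pearson correlation of
two channels over analysed voxels), automatic channel thresholds by the
Costes orthogonal-regression descent, and the Manders coefficients M1/M2
computed above those thresholds. Analysis is restricted to a mask (the cell)
when given, since background voxels inflate the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CostesThresholds:
    t1: float | None
    t2: float | None
    slope: float
    intercept: float
    #: False when the channels show no positive relation overall; the
    #: thresholds are then undefined and Manders coefficients unavailable.
    positive: bool


@dataclass(frozen=True)
class PixelColocResult:
    r_total: float
    thresholds: CostesThresholds
    m1: float | None
    m2: float | None
    n_voxels: int


def _masked(ch1, ch2, mask):
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("channel shapes differ")
    if mask is None:
        return ch1.ravel(), ch2.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ch1.shape:
        raise ValueError("mask shape differs from channels")
    return ch1[mask], ch2[mask]


def pearson(ch1, ch2, mask=None) -> float:
    """Pearson correlation (R_total) of two channels over masked voxels."""
    x, y = _masked(ch1, ch2, mask)
    if x.size < 2:
        raise ValueError("need >=2 voxels for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: a channel has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _orthogonal_regression(x, y):
    """Total-least-squares line y = a x + b through the masked scatter."""
    mx, my = x.mean(), y.mean()
    cov = np.cov(x, y)
    # major axis of the 2D covariance
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, -1]
    if vx == 0:
        return np.inf, np.nan
    a = vy / vx
    return float(a), float(my - a * mx)


def costes_thresholds(ch1, ch2, mask=None, step: float | None = None) -> CostesThresholds:
    """Automatic colocalization thresholds by the Costes descent.

    Fits an orthogonal regression ch2 ~ a*ch1 + b, then walks a threshold T
    down from max(ch1) in increments of ``step`` (default (max-min)/256);
    t1 is the largest T for which the Pearson correlation of the voxels
    *below* both thresholds (ch1 < T and ch2 < a*T + b) drops to <= 0, and
    t2 = a*t1 + b. If no such T exists the descent reaches the intensity
    floor and every voxel counts as colocalized (t1 = min(ch1)). A
    non-positive regression slope flags the result as "no positive
    colocalization" with undefined thresholds.
    """
    x, y = _masked(ch1, ch2, mask)
    if x.size < 2:
        raise ValueError("need >=2 voxels")
    a, b = _orthogonal_regression(x, y)
    if not np.isfinite(a) or a <= 0:
        return CostesThresholds(t1=None, t2=None, slope=a, intercept=b,
                                positive=False)
    lo, hi = float(x.min()), float(x.max())
    if step is None:
        step = (hi - lo) / 256.0
    if step <= 0:
        raise ValueError("channel 1 has zero range; no threshold step possible")
    t = hi
    t1 = lo
    while t > lo:
        below = (x < t) & (y < a * t + b)
        if below.sum() >= 2:
            xb, yb = x[below], y[below]
            if np.ptp(xb) > 0 and np.ptp(yb) > 0:
                r = np.corrcoef(xb, yb)[0, 1]
                if r <= 0:
                    t1 = t
                    break
        t -= step
    return CostesThresholds(t1=float(t1), t2=float(a * t1 + b), slope=a,
                            intercept=b, positive=True)


def manders(ch1, ch2, thresholds: CostesThresholds, mask=None) -> tuple[float, float]:
    """Manders coefficients above the Costes thresholds.

    M1 = fraction of above-threshold ch1 intensity lying in ch2-positive
    voxels; M2 symmetric. Both lie in [0, 1].
    """
    if not thresholds.positive or thresholds.t1 is None:
        raise ValueError("thresholds undefined: no positive colocalization")
    x, y = _masked(ch1, ch2, mask)
    t1, t2 = thresholds.t1, thresholds.t2
    x_pos, y_pos = x > t1, y > t2
    denom1 = x[x_pos].sum()
    denom2 = y[y_pos].sum()
    if denom1 <= 0 or denom2 <= 0:
        raise ValueError("no above-threshold intensity in a channel")
    m1 = float(x[x_pos & y_pos].sum() / denom1)
    m2 = float(y[x_pos & y_pos].sum() / denom2)
    return m1, m2


def coloc_stats(ch1, ch2, mask=None, step: float | None = None) -> PixelColocResult:
    """R_total, Costes thresholds and Manders coefficients in one call."""
    x, _ = _masked(ch1, ch2, mask)
    r = pearson(ch1, ch2, mask)
    th = costes_thresholds(ch1, ch2, mask, step=step)
    if th.positive:
        try:
            m1, m2 = manders(ch1, ch2, th, mask)
        except ValueError:
            # descent stopped at the intensity ceiling: no voxel clears the
            # thresholds, so the Manders coefficients are undefined
            m1 = m2 = None
    else:
        m1 = m2 = None
    return PixelColocResult(r_total=r, thresholds=th, m1=m1, m2=m2,
                            n_voxels=int(x.size))


def costes_randomization_p(
    ch1, ch2, mask=None, block_voxels: int = 5, n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """Optional block-shuffling significance of the observed correlation.

    Shuffles ch1 in blocks of ``block_voxels`` per axis and reports the
    fraction of shuffles whose Pearson correlation reaches the observed one.
    """
    rng = np.random.default_rng(seed)
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    r_obs = pearson(ch1, ch2, mask)
    # partition the grid into blocks and permute them
    shape = ch1.shape
    n_blocks = [max(1, s // block_voxels) for s in shape]
    count = 0
    for _ in range(n_shuffles):
        shifted = ch1
        for ax, nb in enumerate(n_blocks):
            split = np.array_split(shifted, nb, axis=ax)
            order = rng.permutation(len(split))
            shifted = np.concatenate([split[i] for i in order], axis=ax)
        r = pearson(shifted, ch2, mask)
        if r >= r_obs:
            count += 1
    return (count + 1) / (n_shuffles + 1)
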