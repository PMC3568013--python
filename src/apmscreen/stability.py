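"""Multiscale-bootstrap stability of the joint inclusion probability.

How many replicates does a purification series need before the
indicator-based screen becomes reliable?  The joint inclusion probability
of the indicators is re-estimated on bootstrap samples of k replicates
(k ranging over experimental scales from 2 up to the available K): within
each sample, indicators are re-selected at ``p_min`` and the estimate is
the fraction of bootstrapped replicates that contain all of them
simultaneously (the bootstrapped reproducible-replicate count over the
sample size).  The naive bootstrap estimate inflates at small k because
marginal frequencies over few replicates are coarsely quantized, so
selection at ``p_min`` keeps only marginals near 1.  A two-parameter multiscale correction in the
spirit of the approximately-unbiased bootstrap removes the leading bias:
per outer replicate, the scale-wise bootstrap means are transformed to
normal quantiles ``z(k) = Phi^-1(1 - BP(k))``, fitted by least squares as

    z(k) ~ v * tau(k) + c / tau(k),     tau(k) = sqrt(K / k)

(signed distance ``v``, curvature ``c``), and the corrected probability at
scale k is ``1 - Phi(v / s - c * s)`` with ``s = sqrt(k / K)`` — for
``c = 0`` the correction is the identity.  Averaging over outer replicates
yields the curve and its standard error; the change-point below which the
curve leaves its large-k plateau is the minimum reliable replicate count.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .data import ExperimentSet
from .exceptions import ValidationError
from .reproducibility import PresenceMatrix, reproducibility_profile, \
    select_indicator_candidates

_Z_CLIP = 1e-7  # clip bootstrap probabilities away from {0, 1} before Phi^-1


@dataclass
class StabilityCurve:
    k_grid: np.ndarray
    p_bar: np.ndarray  # mean corrected ("unbiased multiscale") joint inclusion
    se: np.ndarray
    p_raw: np.ndarray  # mean uncorrected bootstrap joint inclusion
    b1: int
    b2: int
    seed: int
    k_full: int
    k_min_hat: int | None = None


def _joint_from_sample(matrix: np.ndarray, idx, p_min: float) -> float:
    """Bootstrap joint inclusion on one sample of replicate columns.

    Indicators are re-selected within the sample (marginal >= p_min among the
    candidate rows); the estimate is the fraction L*/k of sampled replicates
    (with multiplicity) that contain every selected indicator.  An empty
    selection flags every replicate reproducible, giving 1.
    """
    sub = matrix[:, idx]
    k = sub.shape[1]
    marg = sub.sum(axis=1) / k
    sel = marg >= p_min
    if not sel.any():
        return 1.0
    return float(sub[sel].all(axis=0).sum() / k)


def _bootstrap_means(matrix: np.ndarray, k_grid, p_min: float, b1, rng) -> np.ndarray:
    """Scale-wise mean bootstrap joint inclusion; b1=None enumerates exhaustively."""
    n, k_full = matrix.shape
    out = np.empty(len(k_grid))
    for i, k in enumerate(k_grid):
        if b1 is None:
            vals = [_joint_from_sample(matrix, list(idx), p_min)
                    for idx in itertools.product(range(k_full), repeat=k)]
        else:
            cols = rng.integers(0, k_full, size=(b1, k))
            vals = [_joint_from_sample(matrix, idx, p_min) for idx in cols]
        out[i] = float(np.mean(vals))
    return out


def _multiscale_correction(bp: np.ndarray, k_grid: np.ndarray, k_full: int,
                           eps: float) -> np.ndarray:
    """Signed-distance/curvature correction of scale-wise bootstrap probabilities.

    The two parameters are fitted on the non-degenerate scales only (bootstrap
    probabilities away from 0 and 1 by the granularity ``eps``); with fewer
    than two such scales, or a constant profile, no correction is applied.
    """
    if np.ptp(bp) < 1e-12:
        return bp.copy()  # degenerate: constant across scales, nothing to correct
    usable = (bp > eps) & (bp < 1.0 - eps)
    if usable.sum() < 2:
        return bp.copy()
    z = norm.ppf(1.0 - np.clip(bp, _Z_CLIP, 1.0 - _Z_CLIP))
    tau = np.sqrt(k_full / k_grid)
    X = np.column_stack([tau, 1.0 / tau])
    (v, c), *_ = np.linalg.lstsq(X[usable], z[usable], rcond=None)
    # replace the fitted scale trend v*tau + c/tau by its value at the full
    # scale (tau = 1): the corrected value equals the raw one at k = K, and
    # scales whose bootstrap probabilities cannot be reconciled with the
    # two-parameter model stand out against the plateau
    z_corr = z - (v * tau + c / tau) + (v + c)
    return np.clip(1.0 - norm.cdf(z_corr), 0.0, 1.0)


def multiscale_joint_inclusion(expset: ExperimentSet | PresenceMatrix,
                               p_min: float,
                               k_grid,
                               b1: int | None = 10,
                               b2: int = 128,
                               seed: int = 0,
                               mst: float = -np.inf,
                               rit: float | None = None) -> StabilityCurve:
    """Mean and standard error of the corrected joint inclusion across scales.

    ``b1`` bootstrap samples of k replicates (with replacement) are drawn at
    each scale (``b1=None`` enumerates all K^k samples exhaustively — only
    sensible for tiny K); the whole procedure is repeated ``b2`` times.
    Indicator candidates are fixed once from the full-K profile (score >=
    RIT) and re-selected at ``p_min`` within every bootstrap sample.
    """
    if isinstance(expset, ExperimentSet):
        matrix = PresenceMatrix.from_experiment(expset, mst=mst)
    else:
        matrix = expset
    k_grid = np.asarray(sorted(k_grid), dtype=int)
    if k_grid.min() < 2:
        raise ValidationError("experimental scales must be >= 2")
    if k_grid.max() > matrix.k:
        raise ValidationError(
            f"largest scale {k_grid.max()} exceeds the available K={matrix.k}")
    if (b1 is not None and b1 < 1) or b2 < 1:
        raise ValidationError("b1 and b2 must be >= 1")

    if rit is None:
        rit = reproducibility_profile(matrix).rit
    cand = select_indicator_candidates(matrix, rit)
    rows = matrix.protein_index(sorted(cand.protein_ids))
    sub = matrix.matrix[rows].astype(np.int64)

    rng = np.random.default_rng(seed)
    eps = 0.0 if b1 is None else 1.0 / (2.0 * b1)
    raw = np.empty((b2, len(k_grid)))
    corrected = np.empty((b2, len(k_grid)))
    for b in range(b2):
        bp = _bootstrap_means(sub, k_grid, p_min, b1, rng)
        raw[b] = bp
        corrected[b] = _multiscale_correction(bp, k_grid, matrix.k, eps)
    p_bar = corrected.mean(axis=0)
    se = corrected.std(axis=0, ddof=1) / np.sqrt(b2) if b2 > 1 else np.zeros(len(k_grid))
    return StabilityCurve(k_grid=k_grid, p_bar=p_bar, se=se, p_raw=raw.mean(axis=0),
                          b1=-1 if b1 is None else b1, b2=b2, seed=seed,
                          k_full=matrix.k)


def detect_kmin(curve: StabilityCurve, tolerance_se_mult: float = 2.0,
                loess_frac: float = 0.5) -> int | None:
    """Change-point: the smallest scale from which the curve stays on its plateau.

    The curve is smoothed by LOESS; the plateau is the mean of the
    smoothed upper half of the scale grid, and the plateau's noise scale is
    estimated from the residuals of the curve around its smooth over that
    same upper half.  The detected minimum replicate count is the smallest
    k such that the smoothed curve at every scale >= k stays within
    ``tolerance_se_mult`` times the larger of the standard error and the
    plateau residual scale.  (A band built from the standard error alone
    would shrink without bound as the outer bootstrap grows, leaving no
    admissible plateau on any stochastic curve.)  Returns ``None`` with a
    warning when the curve never settles.
    """
    if len(curve.k_grid) < 4:
        raise ValidationError("need at least 4 scale grid points to detect a plateau")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    # non-robust smoothing on purpose: the inflated small-scale estimates are
    # the breakdown signal, not outliers to be downweighted
    smoothed = lowess(curve.p_bar, curve.k_grid.astype(float), frac=loess_frac,
                      it=0, return_sorted=False)
    upper = curve.k_grid >= np.median(curve.k_grid)
    plateau = float(np.mean(smoothed[upper]))
    resid_sd = float(np.std(curve.p_bar[upper] - smoothed[upper], ddof=1))
    band = tolerance_se_mult * np.maximum(curve.se, max(resid_sd, 1e-9))
    ok = np.abs(smoothed - plateau) <= band
    # smallest k from which everything above stays within the plateau band
    for i in range(len(ok)):
        if ok[i:].all():
            return int(curve.k_grid[i])
    warnings.warn("no plateau detected: the stability curve trends throughout")
    return None
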