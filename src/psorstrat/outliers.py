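"""Outlier subjects in signature-score space.

The score matrix is reduced to its first two principal components; each
axis is screened with a single (non-iterated) Grubbs test, and only when
either axis shows evidence of an outlier is the bivariate step run: a
minimum-covariance-determinant fit of center and scatter, flagging
subjects whose squared robust Mahalanobis distance exceeds the 0.975
chi-square(2) quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import EmpiricalCovariance, MinCovDet

from .stratify import ScoreMatrix

MCD_SUPPORT_FRACTION = 0.75
CHI2_QUANTILE = 0.975


def top2_pcs(matrix: ScoreMatrix | pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA: scores on the first two axes and their variance fractions."""
    df = matrix.values if isinstance(matrix, ScoreMatrix) else matrix
    if df.shape[0] < 3 or df.shape[1] < 2:
        raise ValueError("PCA needs >=3 subjects and >=2 features")
    X = df.to_numpy(float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] <= 0:
        raise ValueError("score matrix is constant; PCA plane undefined")
    # rank-1 data is allowed: the second axis simply carries zero variance
    scores = U[:, :2] * S[:2]
    # sign convention: largest-|loading| entry of each axis is positive
    for j in range(2):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            scores[:, j] *= -1
    var = S**2
    var_explained = var[:2] / var.sum()
    return (
        pd.DataFrame(scores, index=df.index, columns=["PC1", "PC2"]),
        var_explained,
    )


def grubbs_test(x) -> tuple[float, float]:
    """Single two-sided Grubbs test for one outlier.

    G = max |x_i - mean| / sd; p = min(1, 2n * P(T_{n-2} > t*)) with
    t* = sqrt(n (n-2) G^2 / ((n-1)^2 - n G^2)).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    # relative guard: mean-subtraction roundoff can leave s ~ 1e-20 on
    # an exactly constant sample
    if s <= 1e-12 * max(1.0, np.abs(x).max()):
        return 0.0, 1.0
    G = float(np.max(np.abs(x - x.mean())) / s)
    denom = (n - 1) ** 2 - n * G**2
    if denom <= 0:  # G at its algebraic maximum
        return G, 0.0
    t_star = np.sqrt(n * (n - 2) * G**2 / denom)
    p = min(1.0, 2.0 * n * float(stats.t.sf(t_star, n - 2)))
    return G, p


def bivariate_outliers(
    pc_scores: pd.DataFrame,
    quantile: float = CHI2_QUANTILE,
    support_fraction: float = MCD_SUPPORT_FRACTION,
    robust: bool = True,
    random_state: int = 0,
) -> tuple[pd.Series, dict]:
    """Robust-Mahalanobis outlier flags in the 2-D principal plane."""
    if len(pc_scores) < 10:
        raise ValueError("robust estimation needs >=10 subjects")
    X = pc_scores.to_numpy(float)
    if np.trace(np.cov(X, rowvar=False)) < 1e-12:
        # numerically constant cloud: nothing can be an outlier
        flags = pd.Series(False, index=pc_scores.index, name="outlier")
        info = {
            "cutoff": float(stats.chi2.ppf(quantile, df=2)),
            "robust_center": X.mean(axis=0).tolist(),
            "robust_scatter": np.cov(X, rowvar=False).tolist(),
            "distances_sq": pd.Series(0.0, index=pc_scores.index),
        }
        return flags, info
    if robust:
        est = MinCovDet(support_fraction=support_fraction,
                        random_state=random_state).fit(X)
        if np.linalg.det(est.covariance_) <= 0:
            raise ValueError(
                "degenerate robust scatter; rerun with robust=False "
                "(classical covariance fallback)"
            )
    else:
        est = EmpiricalCovariance().fit(X)
    d2 = est.mahalanobis(X)
    cutoff = float(stats.chi2.ppf(quantile, df=2))
    flags = pd.Series(d2 > cutoff, index=pc_scores.index, name="outlier")
    info = {
        "cutoff": cutoff,
        "robust_center": est.location_.tolist(),
        "robust_scatter": est.covariance_.tolist(),
        "distances_sq": pd.Series(d2, index=pc_scores.index),
    }
    return flags, info


@dataclass
class OutlierReport:
    pc_scores: pd.DataFrame
    var_explained: np.ndarray
    grubbs: dict  # axis -> (G, p)
    gate_open: bool
    bivariate_flags: pd.Series
    cutoff: float | None
    robust_center: list | None
    robust_scatter: list | None
    distances_sq: pd.Series | None

    @property
    def outliers(self) -> list:
        return list(self.bivariate_flags.index[self.bivariate_flags])


def detect_outliers(
    matrix: ScoreMatrix | pd.DataFrame,
    alpha: float = 0.05,
    quantile: float = CHI2_QUANTILE,
    robust: bool = True,
    random_state: int = 0,
) -> OutlierReport:
    """PCA -> per-axis Grubbs gate -> (conditionally) bivariate MCD flags."""
    pcs, var_explained = top2_pcs(matrix)
    grubbs = {axis: grubbs_test(pcs[axis]) for axis in ("PC1", "PC2")}
    gate_open = any(p < alpha for _, p in grubbs.values())
    if gate_open:
        flags, info = bivariate_outliers(
            pcs, quantile=quantile, robust=robust, random_state=random_state
        )
        return OutlierReport(
            pcs, var_explained, grubbs, True, flags,
            info["cutoff"], info["robust_center"], info["robust_scatter"],
            info["distances_sq"],
        )
    flags = pd.Series(False, index=pcs.index, name="outlier")
    return OutlierReport(pcs, var_explained, grubbs, False, flags,
                         None, None, None, None)
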