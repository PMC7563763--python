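"""Power-law species-area fitting via ordinary least squares.

The species-area relationship (SAR) for isolates is modelled as the power
law S = c·A^z, fitted in its linearised form

    log10(S) = log10(c) + z · log10(A)

by OLS.  ``c`` (back-transformed intercept) is the expected number of
species per unit area and reflects dispersal ability; ``z`` (slope) governs
how fast richness accumulates with area, typically 0.2-0.4 for isolates.

Model comparison uses the small-sample corrected Akaike Information
Criterion (AICc) under the Gaussian maximum-likelihood convention, counting
the residual variance as a parameter: k = (number of regression
coefficients) + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import GroupDataset

#: Relative threshold below which an RSS counts as an exact (machine-zero) fit.
_RSS_ZERO_RTOL = 1e-12


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = tuple(columns)
        super().__init__(
            f"design matrix is singular; collinear columns among {list(columns)}"
        )


@dataclass(frozen=True)
class OlsFit:
    """A fitted linear model with classical (Student-t) inference.

    ``k_beta`` counts the regression coefficients including the intercept;
    the AICc parameter count is ``k_beta + 1`` (residual variance).  For an
    exactly interpolating fit (RSS = 0) the log-likelihood diverges and
    ``aicc`` carries a ``-inf`` sentinel, which ranks first.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rss: float
    n: int
    k_beta: int
    r_squared: float
    r_squared_adj: float
    log_likelihood: float
    aicc: float
    rank_deficient: bool = False

    @property
    def df_resid(self) -> int:
        return self.n - self.k_beta


def gaussian_log_likelihood(n: int, rss: float) -> float:
    """Maximised Gaussian log-likelihood of an OLS fit: -(n/2)(ln 2π + ln(RSS/n) + 1)."""
    if rss <= 0:
        return math.inf
    return -(n / 2.0) * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)


def aicc(n: int, k: int, rss: float) -> float:
    """Small-sample corrected AIC for a Gaussian model with ``k`` parameters.

    ``k`` counts all estimated parameters including the residual variance.
    AIC = -2 logLik + 2k; AICc = AIC + 2k(k+1)/(n - k - 1).
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: need n > k + 1 (n={n}, k={k})")
    if rss <= 0:
        return -math.inf
    aic = -2.0 * gaussian_log_likelihood(n, rss) + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_ols(
    response,
    predictors: Mapping[str, Sequence[float]],
    *,
    include_intercept: bool = True,
    on_singular: str = "raise",
) -> OlsFit:
    """Fit an OLS regression of ``response`` on named ``predictors``.

    Inference is classical: SE from s²(XᵀX)⁻¹ with s² = RSS/(n - k_beta),
    two-sided p-values from Student's t with n - k_beta df.

    ``on_singular`` is ``"raise"`` (default) or ``"pinv"``: a rank-deficient
    design either raises :class:`SingularDesignError` or is fitted with the
    minimum-norm pseudo-inverse solution and flagged ``rank_deficient``.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame({name: np.asarray(col, dtype=float) for name, col in predictors.items()})
    if include_intercept:
        X.insert(0, "intercept", 1.0)
    if X.empty:
        X = pd.DataFrame({"intercept": np.ones_like(y)})
    n, k_beta = X.shape
    if n <= k_beta:
        raise ValueError(f"need n > number of coefficients (n={n}, k_beta={k_beta})")

    rank = np.linalg.matrix_rank(X.to_numpy())
    deficient = rank < k_beta
    if deficient and on_singular == "raise":
        raise SingularDesignError(X.columns)

    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    tss = float(((y - y.mean()) ** 2).sum()) if include_intercept else float((y**2).sum())
    zero_rss = rss <= _RSS_ZERO_RTOL * max(tss, 1.0)
    if zero_rss:
        rss = 0.0

    k = k_beta + 1
    aicc_value = aicc(n, k, rss) if n - k - 1 > 0 else math.nan
    return OlsFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        rss=rss,
        n=n,
        k_beta=k_beta,
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        log_likelihood=gaussian_log_likelihood(n, rss),
        aicc=aicc_value,
        rank_deficient=bool(deficient),
    )


@dataclass(frozen=True)
class SARFit:
    """A fitted power-law SAR in linearised form for one beetle group."""

    group: str
    log_c: float
    log_c_se: float
    z: float
    z_se: float
    t_log_c: float
    t_z: float
    p_log_c: float
    p_z: float
    r_squared: float
    n: int
    plus_one_response: bool
    ols: OlsFit

    @property
    def c(self) -> float:
        """Back-transformed intercept: expected species per unit area (km²)."""
        return 10.0**self.log_c


def fit_sar(dataset: GroupDataset) -> SARFit:
    """Fit log10(S) = log10(c) + z·log10(A) for one group's complete cases."""
    if not dataset.transformed:
        raise ValueError("dataset must be log-transformed before fitting")
    fit = fit_ols(dataset.response, {"log_area": dataset.predictors["log_area"]})
    return SARFit(
        group=dataset.group,
        log_c=float(fit.params["intercept"]),
        log_c_se=float(fit.bse["intercept"]),
        z=float(fit.params["log_area"]),
        z_se=float(fit.bse["log_area"]),
        t_log_c=float(fit.tvalues["intercept"]),
        t_z=float(fit.tvalues["log_area"]),
        p_log_c=float(fit.pvalues["intercept"]),
        p_z=float(fit.pvalues["log_area"]),
        r_squared=fit.r_squared,
        n=fit.n,
        plus_one_response=dataset.plus_one_response,
        ols=fit,
    )


def predict_richness(fit: SARFit, area: float) -> float:
    """Expected species count at ``area`` km² from a fitted SAR.

    If the group was fitted on log10(S + 1), the prediction is
    back-transformed accordingly (floored at zero).
    """
    if area <= 0:
        raise ValueError(f"area must be > 0, got {area}")
    s = fit.c * area**fit.z
    if fit.plus_one_response:
        s = max(s - 1.0, 0.0)
    return s


def sar_summary(fits: Sequence[SARFit]) -> pd.DataFrame:
    """Long-format summary of SAR fits: one row per parameter per group."""
    rows = []
    for f in fits:
        rows.append(
            {
                "group": f.group, "parameter": "log_c", "estimate": f.log_c,
                "se": f.log_c_se, "t": f.t_log_c, "p": f.p_log_c,
                "r_squared": f.r_squared, "n": f.n,
            }
        )
        rows.append(
            {
                "group": f.group, "parameter": "z", "estimate": f.z,
                "se": f.z_se, "t": f.t_z, "p": f.p_z,
                "r_squared": f.r_squared, "n": f.n,
            }
        )
    return pd.DataFrame(rows)
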