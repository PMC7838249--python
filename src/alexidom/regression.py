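"""Standardized OLS with diagnostics and HC3 robust standard errors.

The study model regresses BDI on eight standardized predictors (age,
sex, PIQ, VIQ, AQ, DIF, DDF, EOT) per diagnostic group. Assumption
checks follow the published protocol: fraction of standardized
residuals beyond |2|, Durbin–Watson, variance inflation factors, and a
Breusch–Pagan test; a significant Breusch–Pagan result switches the
reported standard errors to the HC3 heteroscedasticity-consistent
sandwich (squared residuals weighted by (1 - h_ii)^-2).

Fitting is delegated to :mod:`statsmodels` (QR/pinv-based OLS, HC3
covariance, Breusch–Pagan, Durbin–Watson); this module owns the
standardization, the selection rule and the reporting surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

#: fixed study model: outcome and predictor columns of a scored table
STUDY_OUTCOME = "bdi"
STUDY_PREDICTORS = ("age", "sex", "piq", "viq", "aq", "dif", "ddf", "eot")


@dataclass
class RegressionFit:
    """Fitted (optionally standardized) OLS model.

    ``beta``/``se_plain``/``se_adj`` cover the predictors only (the
    intercept of a standardized fit is ~0 by construction and kept
    internal). ``se_adj`` is the HC3 sandwich standard error.
    """

    predictor_names: list[str]
    beta: np.ndarray
    se_plain: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    r2: float
    n: int
    k: int
    standardized: bool
    intercept: float
    design: np.ndarray = field(repr=False)  # includes constant column
    y: np.ndarray = field(repr=False)
    se_adj: np.ndarray | None = None

    def conf_int(self, robust: bool = False, conf: float = 0.95):
        """Coefficient CIs using the t distribution with n-k-1 df."""
        se = self.se_adj if robust else self.se_plain
        if se is None:
            raise ValueError("HC3 errors not computed yet")
        tcrit = stats.t.ppf(0.5 + conf / 2.0, self.n - self.k - 1)
        return np.column_stack([self.beta - tcrit * se, self.beta + tcrit * se])


@dataclass
class DiagnosticsReport:
    frac_std_resid_gt2: float
    durbin_watson: float
    vif: dict[str, float]
    bp_stat: float
    bp_p: float
    heteroscedastic: bool
    bp_variant: str = "koenker"


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean(axis=0)) / a.std(axis=0, ddof=1)


def fit_standardized_ols(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    predictor_names: list[str] | None = None,
    standardize: bool = True,
) -> RegressionFit:
    """OLS of y on X with all variables z-scored (n-1 SDs) by default.

    Binary indicators (e.g. the 0/1 sex code) are standardized like any
    other predictor, so their coefficients are per-SD effects. The fit
    uses statsmodels' stable pseudoinverse path, never explicit
    normal-equation inversion. Rank-deficient designs are rejected with
    the offending columns named.
    """
    if isinstance(X, pd.DataFrame):
        predictor_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if predictor_names is None:
            predictor_names = [f"x{j + 1}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    if standardize:
        sds = X.std(axis=0, ddof=1)
        if (sds == 0).any():
            bad = [predictor_names[j] for j in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant predictors cannot be standardized: {bad}")
        X = _zscore(X)
        y = _zscore(y)

    Z = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Z) < k + 1:
        # name columns that are linearly dependent on the preceding ones
        bad = []
        for j in range(1, k + 1):
            if np.linalg.matrix_rank(Z[:, : j + 1]) < j + 1:
                bad.append(predictor_names[j - 1])
        raise ValueError(f"rank-deficient design; dependent columns: {bad}")

    res = sm.OLS(y, Z).fit()
    leverage = res.get_influence().hat_matrix_diag
    return RegressionFit(
        predictor_names=predictor_names,
        beta=res.params[1:].copy(),
        se_plain=res.bse[1:].copy(),
        residuals=res.resid.copy(),
        leverage=leverage,
        r2=float(res.rsquared),
        n=n, k=k,
        standardized=standardize,
        intercept=float(res.params[0]),
        design=Z, y=y,
    )


def hc3_covariance(fit: RegressionFit) -> np.ndarray:
    """HC3 sandwich SEs: sqrt(diag((Z'Z)^-1 Z' D Z (Z'Z)^-1)) with
    D = diag(e_i^2 / (1 - h_ii)^2). Fills ``fit.se_adj`` and returns it.

    Points with leverage 1 predict themselves exactly and are rejected.
    """
    if (fit.leverage >= 1.0 - 1e-12).any():
        raise ValueError("leverage of 1 encountered; HC3 weight undefined")
    res = sm.OLS(fit.y, fit.design).fit(cov_type="HC3")
    fit.se_adj = res.bse[1:].copy()
    return fit.se_adj


def breusch_pagan(
    fit: RegressionFit, variant: str = "koenker"
) -> tuple[float, float]:
    """Breusch–Pagan LM test of residual variance on the design.

    ``koenker`` (default) is the studentized form — n * R^2 from
    regressing e^2 on the predictors, chi-square(k) — robust to
    non-normality; ``classic`` is the original normality-assuming form.
    """
    if variant not in ("koenker", "classic"):
        raise ValueError("variant must be 'koenker' or 'classic'")
    lm, lm_p, _, _ = het_breuschpagan(
        fit.residuals, fit.design, robust=(variant == "koenker"))
    return float(lm), float(lm_p)


def diagnostics(
    fit: RegressionFit, bp_variant: str = "koenker", alpha: float = 0.05
) -> DiagnosticsReport:
    """Assumption checks of the study protocol.

    Standardized residuals are internally studentized,
    e_i / (s sqrt(1 - h_ii)); Durbin–Watson uses the input row order
    (cross-sectional data carry no natural time order — the statistic is
    reported for protocol completeness); VIF_j = 1/(1 - R^2_j) from each
    predictor's auxiliary regression; ``heteroscedastic`` flags
    bp_p < alpha (strict).
    """
    e = fit.residuals
    s = np.sqrt(e @ e / (fit.n - fit.k - 1))
    if s == 0:
        std_resid = np.zeros_like(e)
    else:
        std_resid = e / (s * np.sqrt(1.0 - fit.leverage))
    frac = float((np.abs(std_resid) > 2.0).mean())
    dw = float(durbin_watson(e))
    vif = {
        name: float(variance_inflation_factor(fit.design, j + 1))
        for j, name in enumerate(fit.predictor_names)
    }
    bp_stat, bp_p = breusch_pagan(fit, bp_variant)
    return DiagnosticsReport(
        frac_std_resid_gt2=frac, durbin_watson=dw, vif=vif,
        bp_stat=bp_stat, bp_p=bp_p,
        heteroscedastic=bool(bp_p < alpha), bp_variant=bp_variant)


def select_error_model(report: DiagnosticsReport) -> str:
    """``'HC3'`` when the Breusch–Pagan test is significant (p < .05,
    strict), else ``'plain'`` — the published decision rule."""
    return "HC3" if report.heteroscedastic else "plain"


def model_f_from_r2(r2: float, n: int, k: int) -> tuple[float, float]:
    """Model F = (R^2/k) / ((1-R^2)/(n-k-1)) with its upper-tail p."""
    if not 0.0 <= r2 < 1.0:
        raise ValueError("R^2 must lie in [0, 1)")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    p = float(stats.f.sf(f, k, n - k - 1))
    return float(f), p


def coefficient_table(fit: RegressionFit, robust: bool = False) -> pd.DataFrame:
    """Tidy per-predictor table: beta, SE (plain and HC3 when computed),
    t and p using the t distribution with n-k-1 df."""
    se = fit.se_adj if robust else fit.se_plain
    if se is None:
        raise ValueError("HC3 errors requested but not computed")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.beta / se, np.inf * np.sign(fit.beta))
    p = 2.0 * stats.t.sf(np.abs(t), fit.n - fit.k - 1)
    return pd.DataFrame({
        "predictor": fit.predictor_names,
        "beta": fit.beta,
        "se": fit.se_plain,
        "se_adj": fit.se_adj if fit.se_adj is not None else np.nan,
        "t": t, "p": p,
    })
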