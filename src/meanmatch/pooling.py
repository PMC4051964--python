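"""Analysis-model fitting and Rubin's-rules combination.

Each completed dataset is analysed by a normal-errors linear regression of
the outcome y on the covariate x (optionally with its square), and the M
per-imputation estimates of a coefficient are combined into

    Q_bar = mean(Q_m),     W = mean(U_m),     B = var(Q_m),
    T = W + (1 + 1/M) B,

with a t reference distribution on nu degrees of freedom.  By default nu
is the Barnard-Rubin small-sample adjustment, which is bounded above by
the complete-data residual degrees of freedom; the classic large-sample
formula nu_old = (M-1)(1 + W/((1+1/M)B))^2 is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import SingularDesignError

__all__ = ["AnalysisFit", "PooledEstimate", "fit_analysis_model", "rubin_pool"]

_FORMULAS = ("linear", "quadratic")


@dataclass(frozen=True)
class AnalysisFit:
    """OLS fit of the analysis model in one completed dataset."""

    params: dict[str, float]
    variances: dict[str, float]       # squared conventional standard errors
    dof: int                          # residual degrees of freedom
    formula: str

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        half = scipy.stats.t.ppf(0.5 + level / 2, self.dof) * np.sqrt(
            self.variances[term]
        )
        return self.params[term] - half, self.params[term] + half


def fit_analysis_model(data, formula: str = "linear") -> AnalysisFit:
    """Fit y ~ x (linear) or y ~ x + x2 (quadratic) by OLS.

    ``data`` is a DataFrame or mapping with columns/keys "x" and "y"; a
    passively imputed "x2" column is used when present, otherwise the
    square is computed from x.  Standard errors are the conventional
    model-based ones.
    """
    if formula not in _FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; known: {_FORMULAS}")
    x = np.asarray(data["x"], dtype=float)
    y = np.asarray(data["y"], dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("analysis data must be complete; impute first")
    cols = [np.ones_like(x), x]
    names = ["intercept", "x"]
    if formula == "quadratic":
        try:
            x2 = np.asarray(data["x2"], dtype=float)
        except (KeyError, IndexError):
            x2 = x * x
        cols.append(x2)
        names.append("x2")
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError(
            f"analysis design for formula {formula!r} is rank deficient"
        )
    res = sm.OLS(y, design).fit()
    return AnalysisFit(
        params=dict(zip(names, np.asarray(res.params, dtype=float))),
        variances=dict(zip(names, np.asarray(res.bse, dtype=float) ** 2)),
        dof=int(res.df_resid),
        formula=formula,
    )


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of M per-imputation estimates."""

    q_bar: float
    w: float
    b: float
    t: float
    nu: float
    ci_low: float
    ci_high: float
    m: int
    fmi: float                         # (1 + 1/M) B / T

    def to_record(self) -> dict:
        return {
            "estimate": self.q_bar,
            "se": float(np.sqrt(self.t)),
            "nu": self.nu,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "within_var": self.w,
            "between_var": self.b,
            "fmi": self.fmi,
            "m": self.m,
        }


def rubin_pool(
    estimates,
    variances,
    complete_data_dof: int,
    dof_method: str = "barnard_rubin",
    level: float = 0.95,
) -> PooledEstimate:
    """Combine M estimates and their variances by Rubin's rules.

    ``complete_data_dof`` is the residual degrees of freedom the analysis
    model would have with no missing data; it caps the Barnard-Rubin
    reference degrees of freedom.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-d and same length")
    m = q.shape[0]
    if m < 2:
        raise ValueError("pooling needs M >= 2 (between-variance undefined)")
    if np.any(u <= 0):
        raise ValueError("all within-imputation variances must be positive")
    if dof_method not in ("barnard_rubin", "classic"):
        raise ValueError(f"unknown dof_method {dof_method!r}")

    q_bar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b

    if b > 0:
        lam = (1.0 + 1.0 / m) * b / t
        nu_old = (m - 1) / lam**2
    else:
        lam = 0.0
        nu_old = np.inf
    if dof_method == "classic":
        nu = nu_old
    else:
        dc = float(complete_data_dof)
        nu_obs = (dc + 1.0) / (dc + 3.0) * dc * (1.0 - lam)
        nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs) if np.isfinite(nu_old) else nu_obs
    if not np.isfinite(nu):
        nu = float(complete_data_dof)

    half = scipy.stats.t.ppf(0.5 + level / 2.0, nu) * np.sqrt(t)
    return PooledEstimate(
        q_bar=q_bar,
        w=w,
        b=b,
        t=float(t),
        nu=float(nu),
        ci_low=q_bar - half,
        ci_high=q_bar + half,
        m=m,
        fmi=(1.0 + 1.0 / m) * b / t,
    )


def pooled_table(pooled: dict[str, PooledEstimate]) -> pd.DataFrame:
    """Tidy one-row-per-term table of pooled results."""
    rows = []
    for term, pe in pooled.items():
        rec = pe.to_record()
        rec["term"] = term
        rows.append(rec)
    return pd.DataFrame(rows)[
        ["term", "estimate", "se", "nu", "ci_low", "ci_high",
         "within_var", "between_var", "fmi", "m"]
    ]
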