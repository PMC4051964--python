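"""Normal-errors linear imputation model.

The incomplete continuous variable ``x`` is modelled given fully observed
covariates ``z`` (which include an intercept column and, typically, the
analysis outcome ``y``) as

    x_h ~ N(alpha' z_h, sigma^2)        over the observed cases h.

This module fits that model by ordinary least squares, produces *proper*
parameter draws — either from the standard noninformative-prior posterior
or by the approximate Bayesian bootstrap (ABB) — and performs fully
parametric imputation of the missing cases j.  The donor-based methods
(predictive mean matching, local residual draws) consume the same fits and
draws; see :mod:`meanmatch.matching`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import InsufficientDataError, SingularDesignError

__all__ = [
    "IncompleteSample",
    "LinearFit",
    "ParameterDraw",
    "fit_imputation_model",
    "draw_parameters_posterior",
    "draw_parameters_abb",
    "predictive_mean",
    "impute_parametric",
]

# Relative threshold on pivoted-QR diagonal for declaring rank deficiency.
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class IncompleteSample:
    """One incomplete continuous variable plus complete covariates.

    Parameters
    ----------
    x : ndarray, shape (n,)
        The incomplete variable; missing entries are NaN.
    z : ndarray, shape (n, p)
        Fully observed covariate matrix, including an intercept column.

    Attributes
    ----------
    missing : boolean mask of missing entries of ``x``.
    observed_idx, missing_idx : index sets h (x observed) and j (x missing).
    """

    x: np.ndarray
    z: np.ndarray
    missing: np.ndarray = field(init=False)

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if z.shape[0] != x.shape[0]:
            raise ValueError(
                f"x has {x.shape[0]} rows but z has {z.shape[0]}"
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("covariate matrix z must be fully observed")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "missing", np.isnan(x))
        if self.n_obs < z.shape[1] + 1:
            raise InsufficientDataError(
                f"{self.n_obs} observed cases cannot identify "
                f"{z.shape[1]} coefficients plus a residual variance"
            )

    @classmethod
    def from_xy(cls, x, y) -> "IncompleteSample":
        """Build the canonical single-covariate sample: z = (1, y)."""
        y = np.asarray(y, dtype=float)
        return cls(np.asarray(x, dtype=float),
                   np.column_stack([np.ones_like(y), y]))

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def p(self) -> int:
        return self.z.shape[1]

    @property
    def observed_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.missing)

    @property
    def missing_idx(self) -> np.ndarray:
        return np.flatnonzero(self.missing)

    @property
    def n_obs(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.x)))

    @property
    def n_mis(self) -> int:
        return self.n - self.n_obs

    @property
    def x_obs(self) -> np.ndarray:
        return self.x[~self.missing]

    @property
    def z_obs(self) -> np.ndarray:
        return self.z[~self.missing]

    @property
    def z_mis(self) -> np.ndarray:
        return self.z[self.missing]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of the imputation model on the observed cases.

    ``r_factor`` is the upper-triangular R from the (thin) QR decomposition
    of the observed-case design, so (Z'Z)^-1 = R^-1 R^-T; it is the factor
    used to draw coefficients without forming an explicit inverse.
    """

    alpha_hat: np.ndarray
    sigma2_hat: float
    residuals: np.ndarray
    r_factor: np.ndarray
    dof: int
    n_obs: int

    @property
    def rss(self) -> float:
        return self.sigma2_hat * self.dof

    def to_record(self) -> dict:
        """Plain key-value serialization for logging/debugging."""
        return {
            "alpha_hat": [float(a) for a in self.alpha_hat],
            "sigma2_hat": float(self.sigma2_hat),
            "dof": int(self.dof),
            "n_obs": int(self.n_obs),
        }


@dataclass(frozen=True)
class ParameterDraw:
    """One proper draw (alpha*, sigma2*) of the imputation-model parameters."""

    alpha_star: np.ndarray
    sigma2_star: float
    seed_state: object = None

    def __post_init__(self):
        if not self.sigma2_star > 0:
            raise ValueError("sigma2_star must be strictly positive")

    def to_record(self) -> dict:
        return {
            "alpha_star": [float(a) for a in self.alpha_star],
            "sigma2_star": float(self.sigma2_star),
            "seed_state": self.seed_state,
        }


def _ols(x: np.ndarray, z: np.ndarray):
    """OLS via pivoted QR; returns (alpha_hat, residuals, rss, r_factor).

    Raises SingularDesignError naming the columns beyond the numerical
    rank, and InsufficientDataError when dof would be < 1.
    """
    n, p = z.shape
    if n <= p:
        raise InsufficientDataError(
            f"need more than {p} observed cases to estimate the residual "
            f"variance; got {n}"
        )
    q, r, piv = scipy.linalg.qr(z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * _RANK_RTOL if diag.size and diag[0] > 0 else 0.0
    rank = int(np.count_nonzero(diag > tol))
    if rank < p:
        bad = sorted(int(c) for c in piv[rank:])
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"columns {bad} are collinear with the others",
            columns=bad,
        )
    # Full rank: solve through the un-pivoted QR so r_factor matches z's
    # column order (needed for coefficient draws).
    q, r = np.linalg.qr(z)
    alpha = scipy.linalg.solve_triangular(r, q.T @ x)
    resid = x - z @ alpha
    rss = float(resid @ resid)
    return alpha, resid, rss, r


def fit_imputation_model(sample: IncompleteSample) -> LinearFit:
    """Fit x ~ N(alpha' z, sigma^2) by OLS on the observed cases.

    Returns the coefficient estimate, the unbiased residual-variance
    estimate RSS/(n_h - p), per-case residuals, and a QR factor of the
    observed-case design sufficient for posterior coefficient draws.
    """
    alpha, resid, rss, r = _ols(sample.x_obs, sample.z_obs)
    dof = sample.n_obs - sample.p
    return LinearFit(
        alpha_hat=alpha,
        sigma2_hat=rss / dof,
        residuals=resid,
        r_factor=r,
        dof=dof,
        n_obs=sample.n_obs,
    )


def draw_parameters_posterior(
    fit: LinearFit, rng: np.random.Generator
) -> ParameterDraw:
    """Draw (alpha*, sigma2*) from the noninformative-prior posterior.

    sigma2* = RSS / g with g ~ chi-squared(dof), then
    alpha* | sigma2* ~ N(alpha_hat, sigma2* (Z'Z)^-1), realised through the
    stored QR factor:  alpha* = alpha_hat + sqrt(sigma2*) R^-1 eps.
    """
    if fit.dof < 1:
        raise InsufficientDataError("cannot draw sigma2* with zero dof")
    g = rng.chisquare(fit.dof)
    rss = fit.rss
    if rss <= 0:
        # Degenerate exact fit: the posterior for sigma2 collapses; keep a
        # tiny positive variance so downstream draws remain well defined.
        rss = np.finfo(float).tiny
    sigma2_star = rss / g
    eps = rng.standard_normal(fit.alpha_hat.shape[0])
    alpha_star = fit.alpha_hat + np.sqrt(sigma2_star) * scipy.linalg.solve_triangular(
        fit.r_factor, eps
    )
    return ParameterDraw(alpha_star=alpha_star, sigma2_star=float(sigma2_star))


def draw_parameters_abb(
    sample: IncompleteSample, rng: np.random.Generator, max_attempts: int = 100
) -> ParameterDraw:
    """Approximate-Bayesian-bootstrap parameter draw.

    Refits the model on a with-replacement resample of the observed cases;
    singular resamples are redrawn up to ``max_attempts`` times, then the
    failure is surfaced rather than silently falling back (a silent
    fallback would bias the draws).
    """
    x_obs, z_obs = sample.x_obs, sample.z_obs
    n_h = x_obs.shape[0]
    last_error = None
    for _ in range(max_attempts):
        idx = rng.integers(0, n_h, size=n_h)
        try:
            alpha, _, rss, _ = _ols(x_obs[idx], z_obs[idx])
        except SingularDesignError as exc:
            last_error = exc
            continue
        dof = n_h - sample.p
        sigma2 = rss / dof
        if sigma2 <= 0:
            sigma2 = np.finfo(float).tiny
        return ParameterDraw(alpha_star=alpha, sigma2_star=float(sigma2))
    raise SingularDesignError(
        f"{max_attempts} consecutive bootstrap resamples were singular: "
        f"{last_error}"
    )


def predictive_mean(coefs: np.ndarray, z_rows: np.ndarray) -> np.ndarray:
    """Linear predictors alpha' z per row; pure, no randomness."""
    coefs = np.asarray(coefs, dtype=float)
    z_rows = np.asarray(z_rows, dtype=float)
    if z_rows.size == 0:
        return np.zeros(0)
    z_rows = np.atleast_2d(z_rows)
    if z_rows.shape[1] != coefs.shape[0]:
        raise ValueError(
            f"coefficient length {coefs.shape[0]} does not match row width "
            f"{z_rows.shape[1]}"
        )
    return z_rows @ coefs


def impute_parametric(
    sample: IncompleteSample, draw: ParameterDraw, rng: np.random.Generator
) -> np.ndarray:
    """Posterior-predictive imputations x*_j = alpha* z_j + N(0, sigma2*)."""
    mu = predictive_mean(draw.alpha_star, sample.z_mis)
    return mu + rng.normal(0.0, np.sqrt(draw.sigma2_star), size=mu.shape)
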