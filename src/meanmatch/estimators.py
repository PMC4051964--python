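"""Scikit-learn-style multiple-imputation transformer.

:class:`MultipleImputer` is the package's engine: it fits the normal-errors
linear imputation model once, takes one fresh proper parameter draw per
imputation, imputes every missing case by the configured method
(fully parametric, predictive mean matching, or local residual draws), and
exposes the M completed datasets in the stacked long format through
``transform``.  It follows the scikit-learn estimator contract
(``get_params``/``set_params``, fitted attributes with a trailing
underscore, ``fit``/``transform``) and composes with ``sklearn.clone`` and
pipelines operating on data frames.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .engine import MultipleImputations
from .errors import MeanMatchError
from .linear_model import (
    IncompleteSample,
    draw_parameters_abb,
    draw_parameters_posterior,
    fit_imputation_model,
    impute_parametric,
)
from .matching import MatchSpec, assign_donors, impute_lrd, impute_pmm

__all__ = ["MultipleImputer"]

_METHODS = ("parametric", "pmm", "lrd", "none")


def _as_seed_sequence(random_state):
    if isinstance(random_state, np.random.SeedSequence):
        return random_state
    if isinstance(random_state, np.random.Generator):
        # Derive a child sequence from the generator so repeated fits with
        # the same generator object advance its stream.
        return np.random.SeedSequence(
            int(random_state.integers(0, 2**63 - 1))
        )
    return np.random.SeedSequence(random_state)


class MultipleImputer(TransformerMixin, BaseEstimator):
    """Multiple imputation of one incomplete continuous variable.

    Parameters
    ----------
    method : {"parametric", "pmm", "lrd", "none"}
        Imputation method. "none" is a complete-cases passthrough.
    match_type : {0, 1, 2}
        Which coefficient vector enters each side of the matching distance
        (estimate vs proper draw); type 1 is recommended.
    pool_strategy : {"fixed_k", "caliper", "adaptive", "proportional"}
    k : int or None
        Donor-pool size for ``fixed_k``; ``None`` resolves to 10 for PMM
        and 20 for LRD (LRD tolerates, and benefits from, larger pools).
    delta_max : float or None
        Caliper half-width on the predictive-mean scale.
    closeness : float or None
        Exponent of the inverse-distance donation weight under the
        ``proportional`` strategy.
    sampling_rule : {"simple", "constrained", "slightly_constrained"}
    lrd_type : {0, 1, 2}
        LRD imputation type; only type 1 centres imputations at the drawn
        linear predictor, as parametric imputation does.
    penalty : float in (0, 1)
        Repeat-donation penalty for ``slightly_constrained`` sampling.
    m : int
        Number of imputations.
    draw_method : {"posterior", "abb"}
        Proper parameter draws from the noninformative-prior posterior or
        by the approximate Bayesian bootstrap.
    passive : dict or None
        Mapping ``target_column -> (transform_name, source_column)``
        recomputed in every completed dataset (e.g. ``{"x2": ("square",
        "x")}``).
    incomplete_column : str or None
        Name of the incomplete column when fitting a DataFrame; ``None``
        auto-detects the unique column containing missing values.
    random_state : int, SeedSequence, Generator, or None
        Master seed; one independent substream is spawned per imputation,
        so results do not depend on execution order.

    Attributes
    ----------
    model_ : LinearFit
        The imputation-model fit (absent for ``method="none"``).
    imputations_ : MultipleImputations
        Completed values, parameter draws, and donor assignments.
    incomplete_column_ : str
        Resolved name of the imputed column.
    n_features_in_ : int
    """

    def __init__(
        self,
        method: str = "pmm",
        match_type: int = 1,
        pool_strategy: str = "fixed_k",
        k: int | None = None,
        delta_max: float | None = None,
        closeness: float | None = None,
        sampling_rule: str = "simple",
        lrd_type: int = 1,
        penalty: float = 0.5,
        m: int = 10,
        draw_method: str = "posterior",
        passive: dict | None = None,
        incomplete_column: str | None = None,
        random_state=None,
    ):
        self.method = method
        self.match_type = match_type
        self.pool_strategy = pool_strategy
        self.k = k
        self.delta_max = delta_max
        self.closeness = closeness
        self.sampling_rule = sampling_rule
        self.lrd_type = lrd_type
        self.penalty = penalty
        self.m = m
        self.draw_method = draw_method
        self.passive = passive
        self.incomplete_column = incomplete_column
        self.random_state = random_state

    # -- configuration ---------------------------------------------------

    def _resolved_spec(self) -> MatchSpec:
        k = self.k
        if k is None:
            k = 20 if self.method == "lrd" else 10
        return MatchSpec(
            match_type=self.match_type,
            pool_strategy=self.pool_strategy,
            k=k,
            delta_max=self.delta_max,
            closeness=self.closeness,
            sampling_rule=self.sampling_rule,
            lrd_imputation_type=self.lrd_type,
            penalty=self.penalty,
        )

    def _coerce(self, X) -> IncompleteSample:
        if isinstance(X, IncompleteSample):
            self.incomplete_column_ = self.incomplete_column or "x"
            self.feature_names_in_ = None
            self.n_features_in_ = X.z.shape[1]
            return X
        if isinstance(X, pd.DataFrame):
            frame = X
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            frame = pd.DataFrame(
                arr, columns=[f"x{i}" for i in range(arr.shape[1])]
            )
        col = self.incomplete_column
        if col is None:
            with_na = [c for c in frame.columns if frame[c].isna().any()]
            if len(with_na) != 1:
                raise ValueError(
                    "expected exactly one column with missing values, "
                    f"found {with_na}; set incomplete_column explicitly"
                )
            col = with_na[0]
        elif col not in frame.columns:
            raise ValueError(f"incomplete_column {col!r} not in data")
        others = [c for c in frame.columns if c != col]
        z = np.column_stack(
            [np.ones(len(frame))]
            + [frame[c].to_numpy(dtype=float) for c in others]
        )
        self.incomplete_column_ = col
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        return IncompleteSample(frame[col].to_numpy(dtype=float), z)

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y=None):
        """Fit the imputation model and draw the M completed versions."""
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.draw_method not in ("posterior", "abb"):
            raise ValueError(f"unknown draw_method {self.draw_method!r}")
        sample = self._coerce(X)
        spec = self._resolved_spec() if self.method in ("pmm", "lrd") else None
        if spec is not None and spec.pool_strategy == "fixed_k" and spec.k == 1:
            warnings.warn(
                "single-donor matching (k=1) underestimates between-"
                "imputation variance and is strongly discouraged; "
                "use a pool of around 10 donors",
                UserWarning,
                stacklevel=2,
            )

        seed_seq = _as_seed_sequence(self.random_state)
        substreams = seed_seq.spawn(self.m)

        fit = None
        if self.method != "none":
            fit = fit_imputation_model(sample)

        x_imputed = np.full((self.m, sample.n_mis), np.nan)
        draws, assignments = [], []
        for i, ss in enumerate(substreams):
            rng = np.random.default_rng(ss)
            if self.method == "none":
                draws.append(None)
                assignments.append(None)
                continue
            if self.draw_method == "abb":
                draw = draw_parameters_abb(sample, rng)
            else:
                draw = draw_parameters_posterior(fit, rng)
            draws.append(draw)
            if self.method == "parametric":
                x_imputed[i] = impute_parametric(sample, draw, rng)
                assignments.append(None)
            else:
                assignment = assign_donors(fit, draw, sample, spec, rng)
                assignments.append(assignment)
                if self.method == "pmm":
                    x_imputed[i] = impute_pmm(sample, assignment)
                else:
                    x_imputed[i] = impute_lrd(
                        sample, assignment, fit, draw, spec.lrd_imputation_type
                    )

        self.model_ = fit
        self.sample_ = sample
        self.imputations_ = MultipleImputations(
            sample=sample,
            m=self.m,
            method=self.method,
            x_imputed=x_imputed,
            fit=fit,
            draws=draws,
            assignments=assignments,
            spec=spec,
            master_seed=repr(seed_seq.entropy),
            passive=self.passive,
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        """Return the M completed datasets stacked in long format.

        ``X`` must be the data the imputer was fitted on (multiple
        imputation completes the dataset it modelled; donors and draws are
        tied to it).  The output carries ``.imputation`` (1..M) and
        ``.row`` columns, with passive columns recomputed per copy.
        """
        if not hasattr(self, "imputations_"):
            raise MeanMatchError("MultipleImputer is not fitted")
        if isinstance(X, pd.DataFrame):
            if self.incomplete_column_ not in X.columns:
                raise ValueError("transform data must match the fitted data")
            x = X[self.incomplete_column_].to_numpy(dtype=float)
            data = X
        elif isinstance(X, IncompleteSample):
            x = X.x
            data = None
        else:
            arr = np.asarray(X, dtype=float)
            x = arr[:, list(self.feature_names_in_).index(self.incomplete_column_)] \
                if self.feature_names_in_ is not None else arr[:, 0]
            data = pd.DataFrame(arr, columns=self.feature_names_in_)
        fitted = self.sample_.x
        if x.shape != fitted.shape or not np.array_equal(
            np.isnan(x), np.isnan(fitted)
        ) or not np.allclose(x[~np.isnan(x)], fitted[~np.isnan(fitted)]):
            raise ValueError(
                "transform expects the same dataset the imputer was fitted "
                "on; refit to impute a different dataset"
            )
        return self.imputations_.to_long_frame(
            data=data, column=self.incomplete_column_
        )

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"allow_nan": True}
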