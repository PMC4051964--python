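"""Orchestration containers for M proper imputations of one variable.

The actual engine lives in :class:`meanmatch.estimators.MultipleImputer`
(a scikit-learn-style transformer); :func:`multiply_impute` is a thin
functional wrapper over it.  This module holds the result container, the
passive-transform registry, and the stacked long-format export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linear_model import IncompleteSample, LinearFit, ParameterDraw
from .matching import DonorAssignment, MatchSpec

__all__ = [
    "MultipleImputations",
    "multiply_impute",
    "apply_passive",
    "PASSIVE_TRANSFORMS",
]

PASSIVE_TRANSFORMS = {
    "square": np.square,
}


def apply_passive(
    completed: pd.DataFrame,
    transform: str,
    source: str = "x",
    target: str | None = None,
) -> pd.DataFrame:
    """Recompute a derived column from its (imputed) source column.

    The derived column is overwritten if present, so re-imputation never
    leaves stale values behind; the operation is idempotent for fixed
    source values.
    """
    if transform not in PASSIVE_TRANSFORMS:
        raise ValueError(
            f"unknown passive transform {transform!r}; "
            f"known: {sorted(PASSIVE_TRANSFORMS)}"
        )
    if completed[source].isna().any():
        raise ValueError(f"source column {source!r} still has missing values")
    out = completed.copy()
    out[target or f"{source}2"] = PASSIVE_TRANSFORMS[transform](
        out[source].to_numpy()
    )
    return out


@dataclass
class MultipleImputations:
    """M completed copies of one incomplete variable, with provenance."""

    sample: IncompleteSample
    m: int
    method: str
    x_imputed: np.ndarray              # (m, n_mis); NaN when method == "none"
    fit: LinearFit | None
    draws: list[ParameterDraw | None]
    assignments: list[DonorAssignment | None]
    spec: MatchSpec | None
    master_seed: object
    passive: dict | None = None        # target -> (transform, source)

    def completed_x(self, imputation: int) -> np.ndarray:
        """Full x vector for imputation ``imputation`` (0-based)."""
        x = self.sample.x.copy()
        if self.method != "none":
            x[self.sample.missing] = self.x_imputed[imputation]
        return x

    def to_long_frame(self, data: pd.DataFrame | None = None,
                      column: str = "x") -> pd.DataFrame:
        """Stacked long-format export with an ``.imputation`` column.

        ``data`` supplies the complete companion columns; when omitted a
        frame is built from the sample's covariate matrix (z0, z1, ...).
        """
        if data is None:
            data = pd.DataFrame(
                self.sample.z,
                columns=[f"z{i}" for i in range(self.sample.p)],
            )
        frames = []
        for m in range(self.m):
            frame = data.copy()
            frame[column] = self.completed_x(m)
            if self.passive:
                for target, (transform, source) in self.passive.items():
                    if self.method == "none" and frame[source].isna().any():
                        continue
                    frame = apply_passive(frame, transform, source, target)
            frame.insert(0, ".imputation", m + 1)
            frame.insert(1, ".row", np.arange(self.sample.n))
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def provenance(self) -> dict:
        """JSON-serializable record of seeds, spec, and parameter draws."""
        return {
            "method": self.method,
            "m": self.m,
            "master_seed": self.master_seed,
            "spec": None if self.spec is None else vars(self.spec).copy(),
            "fit": None if self.fit is None else self.fit.to_record(),
            "draws": [
                None if d is None else d.to_record() for d in self.draws
            ],
        }

    def assignment_table(self) -> pd.DataFrame:
        """Audit export: one row per (imputation, recipient) donor match."""
        rows = []
        j_rows = self.sample.missing_idx
        h_rows = self.sample.observed_idx
        for m, a in enumerate(self.assignments):
            if a is None:
                continue
            for r in range(j_rows.shape[0]):
                rows.append(
                    {
                        "imputation": m + 1,
                        "recipient_row": int(j_rows[r]),
                        "donor_row": int(h_rows[a.donor_idx[r]]),
                        "delta": float(a.delta[r]),
                        "pool_size": int(a.pool_size[r]),
                        "same_sign_pool": bool(a.same_sign_pool[r]),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "imputation",
                "recipient_row",
                "donor_row",
                "delta",
                "pool_size",
                "same_sign_pool",
            ],
        )


def multiply_impute(
    sample: IncompleteSample,
    method: str = "pmm",
    spec: MatchSpec | None = None,
    m: int = 10,
    rng=None,
    draw_method: str = "posterior",
    passive: dict | None = None,
) -> MultipleImputations:
    """Produce M proper imputations of ``sample`` by the chosen method.

    Thin functional wrapper over :class:`meanmatch.estimators.MultipleImputer`.
    """
    from .estimators import MultipleImputer

    spec = spec if spec is not None else MatchSpec(
        k=20 if method == "lrd" else 10
    )
    imp = MultipleImputer(
        method=method,
        match_type=spec.match_type,
        pool_strategy=spec.pool_strategy,
        k=spec.k,
        delta_max=spec.delta_max,
        closeness=spec.closeness,
        sampling_rule=spec.sampling_rule,
        lrd_type=spec.lrd_imputation_type,
        penalty=spec.penalty,
        m=m,
        draw_method=draw_method,
        passive=passive,
        random_state=rng,
    )
    imp.fit(sample)
    return imp.imputations_
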