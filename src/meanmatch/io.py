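"""Delimited-text readers/writers and scenario configuration.

All tables are plain comma-separated text.  Reading is strict: a cell is
either numeric or one of the configured missing markers, and anything
else (including locale decimal commas) is an error naming the offending
row and column.  Completed imputations are written in the stacked long
format (one ``.imputation`` index column) with a JSON provenance sidecar.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError
from .simulation import Scenario, method_from_name

__all__ = [
    "DatasetTable",
    "read_table",
    "write_table",
    "write_stacked_imputations",
    "read_scenario_config",
    "write_scenario_config",
    "DEFAULT_MISSING_MARKERS",
]

DEFAULT_MISSING_MARKERS = frozenset({"", "NA", "."})


@dataclass(frozen=True)
class DatasetTable:
    """Rectangular numeric table with an explicit missing-value mask."""

    columns: tuple[str, ...]
    values: np.ndarray            # (n, k) float, NaN where missing
    provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


def read_table(path, missing_markers=DEFAULT_MISSING_MARKERS) -> DatasetTable:
    """Read a delimited text table with a header row.

    Cells matching a missing marker become NaN; any other non-numeric cell
    raises :class:`DataFormatError` with 1-based row/column coordinates.
    """
    path = Path(path)
    markers = set(missing_markers)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DataFormatError(f"{path}: file is empty") from None
        header = [h.strip() for h in header]
        rows = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != len(header):
                raise DataFormatError(
                    f"{path}: row {lineno} has {len(rec)} cells, "
                    f"expected {len(header)}"
                )
            parsed = []
            for colno, cell in enumerate(rec, start=1):
                token = cell.strip()
                if token in markers:
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(token))
                except ValueError:
                    raise DataFormatError(
                        f"{path}: non-numeric cell {cell!r} at row {lineno}, "
                        f"column {colno} ({header[colno - 1]!r})"
                    ) from None
            rows.append(parsed)
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(header)))
    return DatasetTable(tuple(header), values, provenance=str(path))


def write_table(table, path, missing_marker: str = "NA",
                float_format: str = "%.17g") -> None:
    """Write a DataFrame or DatasetTable; NaN becomes ``missing_marker``.

    The default float format round-trips IEEE doubles exactly.
    """
    frame = table.to_frame() if isinstance(table, DatasetTable) else table
    frame.to_csv(path, index=False, na_rep=missing_marker,
                 float_format=float_format)


def write_stacked_imputations(mi, path, data=None, column="x") -> Path:
    """Write M completed copies in stacked long format plus a sidecar.

    The JSON sidecar (``<path>.json``) records the seed, method spec, fit
    and parameter draws needed to reproduce or audit the imputations.
    Returns the sidecar path.
    """
    path = Path(path)
    write_table(mi.to_long_frame(data=data, column=column), path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(mi.provenance(), indent=2, default=str))
    return sidecar


def _scenario_to_dict(scenario: Scenario) -> dict:
    cfg = {
        "study": scenario.study,
        "beta": scenario.beta,
        "mechanism": scenario.mechanism,
        "n": scenario.n,
        "pi": scenario.pi,
        "target_prop": scenario.target_prop,
        "m": scenario.m,
        "n_reps": scenario.n_reps,
        "seed": scenario.seed,
        "calibration_draws": scenario.calibration_draws,
    }
    if scenario.gamma0 is not None:
        cfg["gamma0"] = float(scenario.gamma0)
        cfg["gamma1"] = float(scenario.gamma1)
    if scenario.methods:
        cfg["methods"] = [m.name for m in scenario.methods]
    return cfg


def write_scenario_config(scenario: Scenario, path) -> None:
    """Persist a scenario (including any calibrated gammas) as YAML."""
    Path(path).write_text(yaml.safe_dump(_scenario_to_dict(scenario),
                                         sort_keys=False))


def read_scenario_config(path) -> Scenario:
    """Load a scenario config written by :func:`write_scenario_config`."""
    try:
        cfg = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise DataFormatError(f"{path}: invalid YAML: {exc}") from None
    if not isinstance(cfg, dict):
        raise DataFormatError(f"{path}: scenario config must be a mapping")
    try:
        methods = cfg.pop("methods", None)
        if methods is not None:
            cfg["methods"] = tuple(method_from_name(m) for m in methods)
        return Scenario(**cfg)
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"{path}: bad scenario config: {exc}") from None
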