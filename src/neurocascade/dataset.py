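"""Cohort data container: subjects x variables matrix with labels and roles.

Missing cells are represented as NaN in ``values``; the boolean
``missing_mask`` is always derived from that representation so the two can
never disagree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLE_DEMOGRAPHIC = "demographic"
ROLE_MMSE = "mmse_total"
ROLE_BATTERY = "battery_subscore"
VALID_ROLES = (ROLE_DEMOGRAPHIC, ROLE_MMSE, ROLE_BATTERY)


@dataclass
class CohortDataset:
    """Subjects x variables matrix with binary diagnosis labels.

    Parameters
    ----------
    values
        Real matrix of shape (n_subjects, n_variables); NaN marks missing.
    labels
        Per-subject binary label, 1 = dementia.
    variable_names
        Unique column names.
    variable_roles
        Per-variable tag: ``demographic``, ``mmse_total`` (exactly one) or
        ``battery_subscore``.
    """

    values: np.ndarray
    labels: np.ndarray
    variable_names: list[str]
    variable_roles: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D matrix")
        n, m = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of subjects")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        self.labels = self.labels.astype(np.int64)
        if len(self.variable_names) != m or len(self.variable_roles) != m:
            raise ValueError("variable_names/roles length must match columns")
        if len(set(self.variable_names)) != m:
            raise ValueError("variable_names must be unique")
        bad = set(self.variable_roles) - set(VALID_ROLES)
        if bad:
            raise ValueError(f"unknown variable roles: {sorted(bad)}")
        if self.variable_roles.count(ROLE_MMSE) != 1:
            raise ValueError("exactly one variable must be tagged mmse_total")

    # -- basic views ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean matrix, True exactly where a cell is missing."""
        return np.isnan(self.values)

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def columns_with_role(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.variable_roles) if r == role])

    @property
    def mmse_index(self) -> int:
        return self.variable_roles.index(ROLE_MMSE)

    def var_index(self, name: str) -> int:
        try:
            return self.variable_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown variable: {name}") from exc

    # -- screener / battery feature views ---------------------------------

    def screener_matrix(self) -> np.ndarray:
        """Demographics + MMSE total score (the stage-1 input), in column order."""
        cols = [i for i, r in enumerate(self.variable_roles) if r in (ROLE_DEMOGRAPHIC, ROLE_MMSE)]
        return self.values[:, cols]

    def battery_matrix(self, include_demographics: bool = True) -> np.ndarray:
        """Battery sub-scores followed by demographics (the stage-2 input).

        Sub-scores come first in instrument order so the head of the Hilbert
        traversal carries the assessment sequence, with demographics appended.
        """
        battery = [i for i, r in enumerate(self.variable_roles) if r == ROLE_BATTERY]
        cols = list(battery)
        if include_demographics:
            cols += [i for i, r in enumerate(self.variable_roles) if r == ROLE_DEMOGRAPHIC]
        return self.values[:, cols]

    # -- subsetting -------------------------------------------------------

    def take_rows(self, idx: np.ndarray) -> "CohortDataset":
        return CohortDataset(
            values=self.values[idx].copy(),
            labels=self.labels[idx].copy(),
            variable_names=list(self.variable_names),
            variable_roles=list(self.variable_roles),
            meta=dict(self.meta),
        )

    def with_values(self, values: np.ndarray) -> "CohortDataset":
        return CohortDataset(
            values=np.asarray(values, dtype=float).copy(),
            labels=self.labels.copy(),
            variable_names=list(self.variable_names),
            variable_roles=list(self.variable_roles),
            meta=dict(self.meta),
        )

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write cohort CSV (empty cell = missing) plus a JSON sidecar.

        The sidecar ``<path>.meta.json`` records variable roles and any
        generation config so a round-trip preserves the full dataset.
        """
        path = Path(path)
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", np.arange(self.n_subjects))
        df.to_csv(path, index=False)
        sidecar = {
            "variable_roles": dict(zip(self.variable_names, self.variable_roles)),
            "meta": self.meta,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortDataset":
        path = Path(path)
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        sidecar_path = Path(str(path) + ".meta.json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            roles = [sidecar["variable_roles"][n] for n in names]
            meta = sidecar.get("meta", {})
        else:
            # heuristic fallback: a column literally named mmse_total, the rest battery
            roles = [ROLE_MMSE if n == "mmse_total" else ROLE_BATTERY for n in names]
            meta = {}
        return cls(
            values=df[names].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            variable_names=names,
            variable_roles=roles,
            meta=meta,
        )
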