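"""Per-region removal of covariate effects by ordinary least squares.

Each region's thickness is regressed on the chosen covariates (with an
intercept) and the residuals carried forward to network construction.
The ``mean_thickness`` covariate is always recomputed from the 68 parcels
of the table being fitted, never read from file.

``scope`` controls the fitting unit: ``per_group`` fits each diagnostic
group separately (each group's association matrix is then built from its
own fits), ``pooled`` fits the whole sample at once. The per-group scope
is the default: it keeps one group's covariate structure from leaking
into the other's network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable, mean_cortical_thickness

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_thickness")
SCOPES = ("per_group", "pooled")


@dataclass(frozen=True)
class ResidualTable:
    """Subjects x regions residual thickness (mm, mean-zero per region)."""

    values: pd.DataFrame = field(repr=False)   # index subject_id
    groups: pd.Series = field(repr=False)      # subject_id -> group label
    covariates: tuple[str, ...]
    scope: str

    def group_matrix(self, group: str) -> np.ndarray:
        mask = (self.groups == group).to_numpy()
        return self.values.to_numpy(dtype=float)[mask]

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


def _design_matrix(table: CohortTable, covariates: tuple[str, ...],
                   rows: np.ndarray) -> np.ndarray:
    cols = [np.ones(rows.sum())]
    for cov in covariates:
        if cov == "mean_thickness":
            cols.append(mean_cortical_thickness(table)[rows])
        elif cov in table.data.columns:
            cols.append(table.data.loc[rows, cov].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown covariate: {cov!r}")
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, covariates: tuple[str, ...],
                unit: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name a covariate whose removal leaves the rank unchanged
    for k, cov in enumerate(covariates, start=1):
        reduced = np.delete(X, k, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            raise ValueError(
                f"rank-deficient design in {unit}: covariate {cov!r} is "
                "constant or collinear with the others")
    raise ValueError(f"rank-deficient design in {unit}")


def residualize_matrix(thickness: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of every thickness column on the design matrix."""
    beta, *_ = np.linalg.lstsq(X, thickness, rcond=None)
    return thickness - X @ beta


def residualize(table: CohortTable,
                covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                scope: str = "per_group") -> ResidualTable:
    """Fit thickness ~ 1 + covariates per region; return the residuals."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    covariates = tuple(covariates)
    thickness = table.thickness()
    n, _ = thickness.shape
    groups = table.data["group"]

    if scope == "pooled":
        units = [("pooled sample", np.ones(n, dtype=bool))]
    else:
        units = [(f"group {g!r}", (groups == g).to_numpy())
                 for g in sorted(groups.unique())]

    residuals = np.empty_like(thickness)
    for unit_name, rows in units:
        if rows.sum() <= len(covariates) + 1:
            raise ValueError(
                f"{unit_name} has {int(rows.sum())} subjects; need more than "
                f"{len(covariates) + 1} to fit {len(covariates)} covariates")
        X = _design_matrix(table, covariates, rows)
        _check_rank(X, covariates, unit_name)
        residuals[rows] = residualize_matrix(thickness[rows], X)

    values = pd.DataFrame(residuals,
                          index=table.data["subject_id"],
                          columns=table.atlas.regions)
    return ResidualTable(values=values,
                         groups=pd.Series(groups.to_numpy(),
                                          index=table.data["subject_id"]),
                         covariates=covariates, scope=scope)
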