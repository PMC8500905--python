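"""Cohort tables and the Desikan-Killiany region atlas.

All matrices and nodal vectors produced downstream are indexed against the
canonical region ordering defined by :class:`RegionAtlas`: the 34
Desikan-Killiany cortical parcels of the left hemisphere followed by the
same 34 parcels of the right hemisphere, grouped by lobe. Region identifiers
follow the FreeSurfer ``aparc`` convention (``lh_entorhinal``,
``rh_cuneus``, ...), so tables exported from ``aparcstats2table`` line up
after renaming.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COVARIATE_COLUMNS = ("age", "sex", "education")
GROUP_LABELS = ("control", "patient")

#: plausibility band for cortical thickness in mm; values outside are
#: treated as validation errors, never silently dropped
THICKNESS_MIN_MM = 0.5
THICKNESS_MAX_MM = 5.0


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the input contract."""


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered list of the 68 cortical regions with lobe grouping."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"region_id", "hemisphere", "dk_name", "lobe"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        ids = self.table["region_id"]
        if ids.duplicated().any():
            raise ValueError("atlas region_ids are not unique")

    @classmethod
    def default(cls) -> "RegionAtlas":
        """The packaged 68-region Desikan-Killiany atlas."""
        ref = importlib.resources.files("scovnet.data") / "dk_atlas.tsv"
        with importlib.resources.as_file(ref) as path:
            table = pd.read_csv(path, sep="\t")
        return cls(table)

    @property
    def regions(self) -> list[str]:
        return list(self.table["region_id"])

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def lobe_of(self, region_id: str) -> str:
        row = self.table.loc[self.table["region_id"] == region_id, "lobe"]
        if row.empty:
            raise KeyError(f"unknown region: {region_id}")
        return str(row.iloc[0])


@dataclass(frozen=True)
class CohortTable:
    """Validated per-subject covariates and regional thickness (mm).

    ``data`` holds one row per subject with columns ``subject_id``,
    ``group`` (control/patient), ``age``, ``sex`` (0/1), ``education`` and
    the 68 region columns in atlas order.
    """

    data: pd.DataFrame = field(repr=False)
    atlas: RegionAtlas = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_LABELS}

    def thickness(self) -> np.ndarray:
        """Subjects x regions thickness matrix in atlas order."""
        return self.data[self.atlas.regions].to_numpy(dtype=float)

    def subset(self, group: str) -> "CohortTable":
        if group not in GROUP_LABELS:
            raise ValueError(f"unknown group label: {group!r}")
        sub = self.data[self.data["group"] == group].reset_index(drop=True)
        return CohortTable(sub, self.atlas)


def validate_cohort(data: pd.DataFrame, atlas: RegionAtlas,
                    check_range: bool = True) -> CohortTable:
    """Validate a raw cohort frame and reorder regions to atlas order.

    ``check_range`` applies the thickness plausibility band; it is the
    input contract for real data files, while simulated cohorts may be
    pushed into deliberately extreme regimes.
    """
    missing_cov = [c for c in ("subject_id", "group", *COVARIATE_COLUMNS)
                   if c not in data.columns]
    if missing_cov:
        raise CohortValidationError(f"missing covariate columns: {missing_cov}")
    missing_regions = [r for r in atlas.regions if r not in data.columns]
    if missing_regions:
        raise CohortValidationError(
            f"missing region columns: {missing_regions}")

    if data["subject_id"].duplicated().any():
        dupes = data.loc[data["subject_id"].duplicated(), "subject_id"]
        raise CohortValidationError(
            f"duplicate subject_id values: {sorted(set(dupes))}")
    bad_groups = sorted(set(data["group"]) - set(GROUP_LABELS))
    if bad_groups:
        raise CohortValidationError(
            f"unknown group labels {bad_groups}; expected {GROUP_LABELS}")

    ordered = data[["subject_id", "group", *COVARIATE_COLUMNS, *atlas.regions]]
    ordered = ordered.reset_index(drop=True)

    thick = ordered[atlas.regions].apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(thick.to_numpy(dtype=float))
    if check_range:
        bad |= (thick.to_numpy(dtype=float) <= THICKNESS_MIN_MM)
        bad |= (thick.to_numpy(dtype=float) >= THICKNESS_MAX_MM)
    if bad.any():
        rows, cols = np.nonzero(bad)
        offenders = [
            (str(ordered.loc[r, "subject_id"]), atlas.regions[c],
             data.loc[r, atlas.regions[c]])
            for r, c in zip(rows[:10], cols[:10])
        ]
        raise CohortValidationError(
            "thickness values missing or outside the "
            f"({THICKNESS_MIN_MM}, {THICKNESS_MAX_MM}) mm plausibility band: "
            f"{offenders}")
    ordered[atlas.regions] = thick
    ordered["age"] = pd.to_numeric(ordered["age"])
    ordered["sex"] = pd.to_numeric(ordered["sex"])
    ordered["education"] = pd.to_numeric(ordered["education"])
    return CohortTable(ordered, atlas)


def read_cohort(path, atlas: RegionAtlas | None = None) -> CohortTable:
    """Read and validate a TSV/CSV cohort table.

    The delimiter is auto-detected from the header line; columns may be in
    any order and are reordered to the canonical atlas order.
    """
    atlas = atlas or RegionAtlas.default()
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    raw = pd.read_csv(path, sep=sep)
    return validate_cohort(raw, atlas)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort table as TSV (6 decimals, round-trips exactly)."""
    table.data.to_csv(path, sep="\t", index=False, float_format="%.6f")


def mean_cortical_thickness(table: CohortTable) -> np.ndarray:
    """Per-subject unweighted mean thickness over the 68 parcels (mm).

    The published workflow adjusts for "mean cortical thickness" without
    stating whether it is surface-area weighted; with no area data in a
    thickness table the unweighted parcel mean is used.
    """
    return table.thickness().mean(axis=1)
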