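"""Data model and CSV I/O for plot-level multi-environment trial (MET)
data, zone membership and location covariates.

A plot record carries the design factors of a resolvable incomplete-block
(alpha-design) trial: location, zone, replicate, incomplete block nested in
(location, replicate), genotype, and the yield in g/m^2.  Locations are
stratified into agro-ecological zones; every location belongs to exactly
one zone.  The covariate table holds location-specific soil covariates
(e.g. clay %, pH, humus %) for both tested locations and *new* locations
that have covariates but no yield records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "PLOT_COLUMNS",
    "Dataset",
    "CovariateTable",
    "SchemaError",
    "DuplicateRecordError",
    "ConsistencyError",
    "read_plot_data",
    "write_plot_data",
    "read_covariate_table",
    "write_covariate_table",
    "validate_dataset",
]

PLOT_COLUMNS = ["location", "zone", "replicate", "block", "genotype", "yield"]


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class DuplicateRecordError(ValueError):
    """Two plot records share (location, replicate, block, genotype)."""


class ConsistencyError(ValueError):
    """Zone membership or location coverage disagrees between inputs."""


@dataclass
class Dataset:
    """Validated plot-level MET data.

    Attributes
    ----------
    plots : DataFrame with the six plot columns, one row per plot.
    zones : mapping location -> zone.
    genotypes, locations : sorted rosters.
    """

    plots: pd.DataFrame
    zones: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.plots
        missing = [c for c in PLOT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"plot data missing column(s): {', '.join(missing)}")
        df = df[PLOT_COLUMNS].copy()
        for c in PLOT_COLUMNS[:-1]:
            df[c] = df[c].astype(str)
        bad = df.index[pd.to_numeric(df["yield"], errors="coerce").isna()
                       & df["yield"].notna()]
        if len(bad):
            raise SchemaError(f"non-numeric yield in row {int(bad[0])}")
        df["yield"] = pd.to_numeric(df["yield"])
        key = ["location", "replicate", "block", "genotype"]
        dup = df.duplicated(key)
        if dup.any():
            row = df[dup].iloc[0]
            raise DuplicateRecordError(
                "duplicate plot record: location=%s replicate=%s block=%s genotype=%s"
                % tuple(row[k] for k in key))
        zmap = df.drop_duplicates("location").set_index("location")["zone"].to_dict()
        multi = df.groupby("location")["zone"].nunique()
        if (multi > 1).any():
            loc = multi[multi > 1].index[0]
            raise ConsistencyError(f"location {loc!r} mapped to multiple zones")
        self.plots = df.reset_index(drop=True)
        self.zones = dict(zmap) if not self.zones else self.zones

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.plots["genotype"].unique())

    @property
    def locations(self) -> list[str]:
        return sorted(self.plots["location"].unique())

    @property
    def zone_list(self) -> list[str]:
        return sorted(set(self.zones.values()))

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return len(self.genotypes)

    @property
    def J(self) -> int:
        return len(self.locations)

    def subset_locations(self, keep) -> "Dataset":
        keep = set(keep)
        df = self.plots[self.plots["location"].isin(keep)]
        return Dataset(df.reset_index(drop=True))


@dataclass
class CovariateTable:
    """Location-specific covariates, aligned to a dataset.

    ``table`` is indexed by location with a ``zone`` column, an ``is_new``
    boolean flag (new locations have covariates but no yield records) and
    one column per named covariate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.name != "location":
            if "location" not in df.columns:
                raise SchemaError("covariate table missing column: location")
            df = df.set_index("location")
        df.index = df.index.astype(str)
        if "zone" not in df.columns:
            raise SchemaError("covariate table missing column: zone")
        if "is_new" not in df.columns:
            df = df.assign(is_new=False)
        df["zone"] = df["zone"].astype(str)
        df["is_new"] = df["is_new"].astype(bool)
        self.table = df

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("zone", "is_new")]

    @property
    def new_locations(self) -> list[str]:
        return sorted(self.table.index[self.table["is_new"]])

    @property
    def tested_locations(self) -> list[str]:
        return sorted(self.table.index[~self.table["is_new"]])

    def value(self, location: str, covariate: str) -> float:
        return float(self.table.loc[str(location), covariate])

    def zone_of(self, location: str) -> str:
        return str(self.table.loc[str(location), "zone"])


def read_plot_data(path) -> Dataset:
    """Read plot-level trial data from CSV (comma-separated, UTF-8 header).

    Raises :class:`SchemaError` for missing columns or unparseable yields
    and :class:`DuplicateRecordError` for repeated plot keys.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plot data missing column(s): {', '.join(missing)}")
    return Dataset(df)


def write_plot_data(dataset: Dataset, path) -> None:
    dataset.plots.to_csv(path, index=False)


def read_covariate_table(path, dataset: Dataset | None = None) -> CovariateTable:
    """Read the location-covariate CSV and, when a dataset is given, check
    coverage (every tested location present) and zone consistency."""
    df = pd.read_csv(path)
    table = CovariateTable(df)
    if dataset is not None:
        align_covariates(table, dataset)
    return table


def align_covariates(table: CovariateTable, dataset: Dataset) -> CovariateTable:
    missing = [l for l in dataset.locations if l not in table.table.index]
    if missing:
        raise ConsistencyError(
            f"tested location(s) missing from covariate table: {', '.join(missing)}")
    for loc, zone in dataset.zones.items():
        if table.zone_of(loc) != zone:
            raise ConsistencyError(
                f"zone mismatch for location {loc!r}: plot data says {zone!r}, "
                f"covariate table says {table.zone_of(loc)!r}")
    flagged = set(table.new_locations) & set(dataset.locations)
    if flagged:
        raise ConsistencyError(
            f"location(s) flagged new but present in plot data: {sorted(flagged)}")
    return table


def write_covariate_table(table: CovariateTable, path) -> None:
    table.table.reset_index().to_csv(path, index=False)


def validate_dataset(dataset: Dataset) -> dict:
    """Pure connectivity/replication report for a dataset.

    Lists genotype x location connectivity, replicate counts per location,
    whether the genotype x location table is complete, and warnings (e.g. a
    single-location dataset leaves stage-II variance components
    inestimable).  Never raises.
    """
    df = dataset.plots
    cell = df.groupby(["genotype", "location"]).size().unstack(fill_value=0)
    cell = cell.reindex(index=dataset.genotypes, columns=dataset.locations,
                        fill_value=0)
    incomplete = [(g, l) for g in dataset.genotypes for l in dataset.locations
                  if cell.loc[g, l] == 0]
    reps = df.groupby("location")["replicate"].nunique().to_dict()
    warnings = []
    if dataset.J < 2:
        warnings.append("single location: stage-II location and genotype x "
                        "location variance components are inestimable")
    for loc, r in reps.items():
        if r < 2:
            warnings.append(f"location {loc!r} has a single replicate: "
                            "replicate variance inestimable in stage I")
    report = {
        "n_genotypes": dataset.I,
        "n_locations": dataset.J,
        "n_zones": len(dataset.zone_list),
        "zones": {z: sorted(l for l, zz in dataset.zones.items() if zz == z)
                  for z in dataset.zone_list},
        "replicates_per_location": reps,
        "fully_connected": not incomplete,
        "incomplete_cells": incomplete,
        "warnings": warnings,
    }
    return report


def report_to_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str))
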