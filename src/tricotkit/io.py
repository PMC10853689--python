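"""Plain-text persistence: design, observations, covariates and weather CSVs.

All files are UTF-8 CSV with headers. Observation files carry blind A/B/C
positions only; option names never appear in participant-facing collection
artifacts.
"""

from __future__ import annotations

import csv
import datetime as dt
import io as _io
from pathlib import Path

import pandas as pd

from .agroclimate import DailyWeather
from .design import DesignError, DesignSpec, Package, TrialDesign
from .pltree import CovariateTable
from .rankings import TricotResponse

__all__ = [
    "write_design_csv",
    "read_design_csv",
    "write_observations_csv",
    "read_observations_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "read_weather_csv",
]

DESIGN_HEADER = ["package_id", "option_a", "option_b", "option_c"]
OBS_HEADER = ["package_id", "trait", "best", "worst"]


def write_design_csv(design: TrialDesign, path: str | Path) -> None:
    """One row per package: package_id,option_a,option_b,option_c."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(DESIGN_HEADER)
        for pkg in design.packages:
            writer.writerow([pkg.package_id, *pkg.options])


def read_design_csv(path: str | Path, seed: int = 0) -> TrialDesign:
    """Parse a design CSV, validating ids and within-block distinctness."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DesignError(f"{path}: empty design file") from None
        if [h.strip().lower() for h in header] != DESIGN_HEADER:
            raise DesignError(
                f"{path}: malformed header {header!r}, expected {DESIGN_HEADER}"
            )
        packages = []
        seen_ids = set()
        option_order: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != 4:
                raise DesignError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            try:
                pid = int(row[0])
            except ValueError:
                raise DesignError(
                    f"{path}:{lineno}: package_id {row[0]!r} is not an integer"
                ) from None
            if pid in seen_ids:
                raise DesignError(f"{path}:{lineno}: duplicate package_id {pid}")
            seen_ids.add(pid)
            options = tuple(cell.strip() for cell in row[1:4])
            if len(set(options)) != 3:
                raise DesignError(
                    f"{path}:{lineno}: option repeated within the block: {options}"
                )
            for opt in options:
                if opt not in option_order:
                    option_order.append(opt)
            packages.append(Package(package_id=pid, options=options))
    packages.sort(key=lambda p: p.package_id)
    spec = DesignSpec(
        n_options=len(option_order),
        n_packages=len(packages),
        option_names=tuple(option_order),
        seed=seed,
    )
    return TrialDesign(spec=spec, packages=tuple(packages))


def write_observations_csv(
    responses: list[TricotResponse], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBS_HEADER)
        for r in responses:
            writer.writerow(
                [r.package_id, r.trait, r.best or "", r.worst or ""]
            )


def read_observations_csv(path: str | Path) -> list[TricotResponse]:
    responses = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = set(OBS_HEADER)
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: observations header must include {sorted(required)}"
            )
        for row in reader:
            responses.append(
                TricotResponse(
                    package_id=int(row["package_id"]),
                    trait=row["trait"],
                    best=row["best"].strip() or None,
                    worst=row["worst"].strip() or None,
                )
            )
    return responses


def write_covariates_csv(covariates: CovariateTable, path: str | Path) -> None:
    covariates.table.to_csv(path, index=False)


def read_covariates_csv(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path))


def read_weather_csv(path: str | Path) -> list[DailyWeather]:
    """Read date,tmin,tmax,precip rows with ISO-8601 dates."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"date", "tmin", "tmax", "precip"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: weather header must include {sorted(required)}")
        for row in reader:
            records.append(
                DailyWeather(
                    date=dt.date.fromisoformat(row["date"].strip()),
                    tmin=float(row["tmin"]),
                    tmax=float(row["tmax"]),
                    precip=float(row["precip"]),
                )
            )
    records.sort(key=lambda r: r.date)
    return records


def design_to_csv_string(design: TrialDesign) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(DESIGN_HEADER)
    for pkg in design.packages:
        writer.writerow([pkg.package_id, *pkg.options])
    return buf.getvalue()
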