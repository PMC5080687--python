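"""Reading and writing endpoint tables and fermentation time courses.

Endpoint tables are delimited text (CSV, or TSV by extension) with one row
per fermentation condition. Species columns are declared in the header with
an explicit role prefix and unit suffix, e.g. ``consumed_glucose_g_per_L``
or ``product_butanol_g_per_L`` — long names over positional columns so a
substrate can never silently be read as a product.

Time courses are CSV with a ``time_h`` column, optional ``dcw_g_per_L`` and
``ph`` columns, and one ``<species>_g_per_L`` column per tracked compound.
A leading ``# noise_tolerance=<g/L>`` comment declares the measurement
jitter under which substrate series are still accepted as non-increasing.

The bundled fixtures (:func:`fixtures`) transcribe the endpoint tables of a
glucose/glycerol isopropanol–butanol fermentation study of *Clostridium*
sp. A1424: nine single-substrate conditions, five glucose:glycerol ratio
conditions, and four headline pH-/crude-glycerol conditions, so the whole
analysis pipeline runs offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .registry import SpeciesRegistry, default_registry

__all__ = [
    "EndpointRecord",
    "TimeCourse",
    "FixtureSets",
    "read_endpoints",
    "write_endpoints",
    "read_timecourse",
    "write_timecourse",
    "fixtures",
]

_UNIT_SUFFIX = "_g_per_L"


@dataclass
class EndpointRecord:
    """One fermentation condition's net consumption and final titers.

    ``substrates_consumed`` holds net consumed substrate (initial minus
    residual) in g/L; ``products`` holds final titers in g/L. A zero product
    titer is a measured zero and is kept; substrates with zero net
    consumption are dropped at construction.
    """

    label: str
    duration_h: float
    substrates_consumed: dict[str, float]
    products: dict[str, float]
    ph_control: str | float | None = None

    def __post_init__(self) -> None:
        reg = default_registry()
        if not (self.duration_h > 0):
            raise ValidationError(f"{self.label!r}: duration_h must be > 0")
        self.substrates_consumed = self._check(
            reg, self.substrates_consumed, want="substrate", drop_zero=True
        )
        self.products = self._check(reg, self.products, want="product", drop_zero=False)

    def _check(
        self,
        reg: SpeciesRegistry,
        concs: Mapping[str, float],
        want: str,
        drop_zero: bool,
    ) -> dict[str, float]:
        out: dict[str, float] = {}
        for sp_id, conc in concs.items():
            sp = reg.get(sp_id)
            if not math.isfinite(conc) or conc < 0:
                raise ValidationError(
                    f"{self.label!r}: invalid {want} concentration {conc} for {sp.id}"
                )
            ok = sp.is_substrate if want == "substrate" else sp.is_product
            if not ok:
                raise ValidationError(
                    f"{self.label!r}: species {sp.id!r} has role {sp.role!r}, "
                    f"cannot appear as {want}"
                )
            if drop_zero and conc == 0:
                continue
            out[sp.id] = float(conc)
        return out

    @property
    def total_substrate_g(self) -> float:
        """Total net consumed substrate, g/L."""
        return sum(self.substrates_consumed.values())

    def product_titer(self, species_id: str) -> float:
        """Final titer of one product (0 if absent), g/L."""
        return self.products.get(default_registry().resolve(species_id), 0.0)

    def scaled(self, factor: float) -> "EndpointRecord":
        """Record with all concentrations multiplied by ``factor``."""
        return EndpointRecord(
            label=self.label,
            duration_h=self.duration_h,
            substrates_consumed={k: v * factor for k, v in self.substrates_consumed.items()},
            products={k: v * factor for k, v in self.products.items()},
            ph_control=self.ph_control,
        )


@dataclass
class TimeCourse:
    """Sampled batch-fermentation trajectories.

    ``times`` is strictly increasing and starts at 0 h; every series has the
    same length. ``noise_tolerance`` (g/L) is the measurement jitter under
    which substrate series are still accepted as non-increasing.
    """

    times: np.ndarray
    series: dict[str, np.ndarray]
    biomass: np.ndarray | None = None
    ph: np.ndarray | None = None
    noise_tolerance: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError("times must be a non-empty 1-D array")
        if self.times[0] != 0:
            raise ValidationError("times must start at 0 h")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        n = self.times.size
        reg = default_registry()
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for name, values in self.series.items():
            reg.get(name)
            if values.shape != (n,):
                raise ValidationError(f"series {name!r} length {values.size} != {n}")
            if np.any(values < 0):
                raise ValidationError(f"series {name!r} has negative values")
            if reg.get(name).is_substrate and not reg.get(name).is_product:
                rises = np.diff(values)
                if np.any(rises > self.noise_tolerance + 1e-9):
                    raise ValidationError(
                        f"substrate series {name!r} increases by more than the "
                        f"declared noise tolerance {self.noise_tolerance} g/L"
                    )
        for attr in ("biomass", "ph"):
            values = getattr(self, attr)
            if values is not None:
                values = np.asarray(values, dtype=float)
                if values.shape != (n,):
                    raise ValidationError(f"{attr} length {values.size} != {n}")
                setattr(self, attr, values)

    def __len__(self) -> int:
        return int(self.times.size)

    def at(self, time_h: float) -> dict[str, float]:
        """Linearly interpolated concentrations at ``time_h``."""
        if not (self.times[0] <= time_h <= self.times[-1]):
            raise ValidationError(
                f"time {time_h} h outside sampled range "
                f"[{self.times[0]}, {self.times[-1]}] h"
            )
        return {
            name: float(np.interp(time_h, self.times, values))
            for name, values in self.series.items()
        }


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def _parse_species_column(name: str) -> tuple[str, str] | None:
    """``consumed_glucose_g_per_L`` → ("substrate", "glucose"); None if not a species column."""
    if not name.endswith(_UNIT_SUFFIX):
        return None
    stem = name[: -len(_UNIT_SUFFIX)]
    if stem.startswith("consumed_"):
        return "substrate", stem[len("consumed_"):]
    if stem.startswith("product_"):
        return "product", stem[len("product_"):]
    return None


def read_endpoints(path: str | Path) -> list[EndpointRecord]:
    """Read an endpoint table; malformed rows are reported with line numbers.

    Raises
    ------
    ValidationError
        Missing duration, negative value, unknown species column, or any
        per-row constraint violation (the message carries the file line).
    """
    reg = default_registry()
    df = pd.read_csv(path, sep=_sep_for(path))
    if "label" not in df.columns or "duration_h" not in df.columns:
        raise ValidationError(f"{path}: endpoint table needs 'label' and 'duration_h' columns")
    roles: dict[str, tuple[str, str]] = {}
    for col in df.columns:
        if col in ("label", "duration_h", "ph_control"):
            continue
        parsed = _parse_species_column(col)
        if parsed is None:
            raise ValidationError(
                f"{path}: unrecognized column {col!r} (expected consumed_/product_ "
                f"prefix and {_UNIT_SUFFIX} suffix)"
            )
        role, sp_id = parsed
        if sp_id not in reg:
            raise ValidationError(f"{path}: unknown species column {col!r}")
        roles[col] = (role, reg.resolve(sp_id))

    records: list[EndpointRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            if pd.isna(row["duration_h"]):
                raise ValidationError("missing duration_h")
            consumed: dict[str, float] = {}
            products: dict[str, float] = {}
            for col, (role, sp_id) in roles.items():
                raw = row[col]
                value = 0.0 if pd.isna(raw) else float(raw)
                if role == "substrate":
                    consumed[sp_id] = value
                else:
                    products[sp_id] = value
            ph = row.get("ph_control")
            records.append(
                EndpointRecord(
                    label=str(row["label"]),
                    duration_h=float(row["duration_h"]),
                    substrates_consumed=consumed,
                    products=products,
                    ph_control=None if (ph is None or pd.isna(ph)) else ph,
                )
            )
        except ValidationError as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    return records


def write_endpoints(records: list[EndpointRecord], path: str | Path) -> None:
    """Write an endpoint table in the dialect :func:`read_endpoints` accepts."""
    sub_ids = sorted({sp for r in records for sp in r.substrates_consumed})
    prod_ids = sorted({sp for r in records for sp in r.products})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "label": r.label,
            "duration_h": r.duration_h,
            "ph_control": "none" if r.ph_control is None else r.ph_control,
        }
        for sp in sub_ids:
            row[f"consumed_{sp}{_UNIT_SUFFIX}"] = r.substrates_consumed.get(sp, 0.0)
        for sp in prod_ids:
            row[f"product_{sp}{_UNIT_SUFFIX}"] = r.products.get(sp, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, float_format="%.10g")


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a time-course CSV written by :func:`write_timecourse` (lossless)."""
    noise_tolerance = 0.0
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "noise_tolerance=" in first:
            noise_tolerance = float(first.split("noise_tolerance=")[1])
    df = pd.read_csv(path, skiprows=skip)
    if "time_h" not in df.columns:
        raise ValidationError(f"{path}: time course needs a 'time_h' column")
    if df.isna().any().any():
        raise ValidationError(f"{path}: ragged or missing values in time course")
    times = df["time_h"].to_numpy(dtype=float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValidationError(f"{path}: non-monotone time column")
    series = {}
    biomass = ph = None
    for col in df.columns:
        if col == "time_h":
            continue
        if col == "dcw_g_per_L":
            biomass = df[col].to_numpy(dtype=float)
        elif col == "ph":
            ph = df[col].to_numpy(dtype=float)
        elif col.endswith(_UNIT_SUFFIX):
            series[col[: -len(_UNIT_SUFFIX)]] = df[col].to_numpy(dtype=float)
        else:
            raise ValidationError(f"{path}: unrecognized time-course column {col!r}")
    return TimeCourse(times=times, series=series, biomass=biomass, ph=ph,
                      noise_tolerance=noise_tolerance)


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    """Write a time course to CSV at full float precision (lossless round trip)."""
    data: dict[str, np.ndarray] = {"time_h": tc.times}
    if tc.biomass is not None:
        data["dcw_g_per_L"] = tc.biomass
    if tc.ph is not None:
        data["ph"] = tc.ph
    for name, values in tc.series.items():
        data[f"{name}{_UNIT_SUFFIX}"] = values
    with open(path, "w", newline="") as fh:
        fh.write(f"# noise_tolerance={tc.noise_tolerance!r}\n")
        pd.DataFrame(data).to_csv(fh, index=False, float_format="%.17g")


@dataclass(frozen=True)
class FixtureSets:
    """Bundled endpoint fixtures, keyed by condition label."""

    table2: dict[str, EndpointRecord] = field(default_factory=dict)
    table3: dict[str, EndpointRecord] = field(default_factory=dict)
    reported: dict[str, EndpointRecord] = field(default_factory=dict)


def _load_bundled(name: str) -> dict[str, EndpointRecord]:
    with resources.as_file(resources.files("ibferm.data").joinpath(name)) as path:
        return {r.label: r for r in read_endpoints(path)}


def fixtures() -> FixtureSets:
    """The bundled study endpoints.

    Returns
    -------
    FixtureSets
        ``table2``: nine single-substrate serum-bottle conditions (28 h,
        sucrose 36 h). ``table3``: five glucose:glycerol mass-ratio
        conditions ("22:0" … "9:13"; 28 h, "9:13" 25 h). ``reported``:
        headline conditions — 16 h glucose harvest, 41 g/L glucose,
        pH-5.5-controlled fermenter (32 h), and the glucose + crude-glycerol
        14:8 mixture (24 h).
    """
    return FixtureSets(
        table2=_load_bundled("table2_endpoints.csv"),
        table3=_load_bundled("table3_endpoints.csv"),
        reported=_load_bundled("reported_endpoints.csv"),
    )
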