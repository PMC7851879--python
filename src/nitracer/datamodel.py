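"""Domain types, unit conventions and tabular I/O shared by all pipeline stages.

Unit conventions are fixed and never inferred: time in hours, concentrations
in µM (µmol L⁻¹), water volume in L, sediment area in m², biomass as grams
of shell-free dry weight (SFDW).  Incubation tables are long (tidy) CSV,
one row per (vessel, time, analyte) measurement.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A table or config does not match the expected schema."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


class Analyte(str, enum.Enum):
    """Measured solutes and N₂ isotopologues.

    N2_28/29/30 are the ²⁸N₂/²⁹N₂/³⁰N₂ isotopologues expressed as µM N₂;
    NH4_15N is the ¹⁵NH₄⁺ concentration (µM).
    """

    O2 = "O2"
    NH4 = "NH4"
    NO2 = "NO2"
    NOX = "NOx"
    PO4 = "PO4"
    TDN = "TDN"
    N2_28 = "N2_28"
    N2_29 = "N2_29"
    N2_30 = "N2_30"
    NH4_15N = "NH4_15N"


class VesselKind(str, enum.Enum):
    CORE = "core"
    MICROCOSM = "microcosm"


class TracerLabel(str, enum.Enum):
    NO3_15N = "NO3_15N"
    NH4_15N = "NH4_15N"
    N2_30 = "N2_30"


@dataclass(frozen=True)
class IncubationSeries:
    """Timestamped concentrations of one analyte in one vessel.

    Times are hours since closure, strictly increasing; concentrations in µM.
    """

    vessel_id: str
    analyte: Analyte
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size:
            raise ValidationError(
                f"vessel {self.vessel_id}/{self.analyte.value}: "
                f"{t.size} times but {c.size} concentrations"
            )
        if t.size == 0:
            raise ValidationError(f"vessel {self.vessel_id}: empty series")
        if np.any(t < 0):
            raise ValidationError(f"vessel {self.vessel_id}: negative time")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"vessel {self.vessel_id}/{self.analyte.value}: "
                "times not strictly increasing"
            )
        if np.any(c < 0):
            raise ValidationError(
                f"vessel {self.vessel_id}/{self.analyte.value}: "
                "negative concentration"
            )
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "concentrations", tuple(float(x) for x in c))

    @property
    def n(self) -> int:
        return len(self.times)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.concentrations)


# Inner diameter of the sediment core liners used for the areal basis (cm).
CORE_INNER_DIAMETER_CM = 8.4


@dataclass(frozen=True)
class VesselGeometry:
    """Vessel geometry and biomass.

    Cores carry a sediment area (m², from the liner inner diameter);
    microcosms have no areal basis and normalize by biomass instead.
    biomass_sfdw_g is 0 for bare-sediment cores and water-only controls.
    """

    kind: VesselKind
    water_volume_l: float
    sediment_area_m2: float | None = None
    biomass_sfdw_g: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", VesselKind(self.kind))
        if self.water_volume_l <= 0:
            raise ValidationError("water_volume_l must be > 0")
        if self.kind is VesselKind.CORE:
            if self.sediment_area_m2 is None or self.sediment_area_m2 <= 0:
                raise ValidationError("core vessels need sediment_area_m2 > 0")
        if self.biomass_sfdw_g < 0:
            raise ValidationError("biomass_sfdw_g must be >= 0")

    @staticmethod
    def core_area_from_diameter(inner_diameter_cm: float = CORE_INNER_DIAMETER_CM) -> float:
        """Sediment area (m²) of a cylindrical core liner."""
        r_m = inner_diameter_cm / 100.0 / 2.0
        return math.pi * r_m**2

    @classmethod
    def core(
        cls,
        water_volume_l: float,
        inner_diameter_cm: float = CORE_INNER_DIAMETER_CM,
        biomass_sfdw_g: float = 0.0,
    ) -> "VesselGeometry":
        return cls(
            kind=VesselKind.CORE,
            water_volume_l=water_volume_l,
            sediment_area_m2=cls.core_area_from_diameter(inner_diameter_cm),
            biomass_sfdw_g=biomass_sfdw_g,
        )

    @classmethod
    def microcosm(cls, water_volume_l: float = 0.227, biomass_sfdw_g: float = 0.0) -> "VesselGeometry":
        return cls(
            kind=VesselKind.MICROCOSM,
            water_volume_l=water_volume_l,
            biomass_sfdw_g=biomass_sfdw_g,
        )


@dataclass(frozen=True)
class TracerSpec:
    """What ¹⁵N label was added to a vessel.

    epsilon is the ¹⁵N mole fraction of the labeled dissolved pool after
    addition: ε for NO₃⁻, f_a for NH₄⁺, or the source N₂ atom-fraction for
    dissolved ³⁰N₂ additions.
    """

    label: TracerLabel
    added_concentration_um: float
    epsilon: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValidationError("epsilon must be in [0, 1]")
        if self.added_concentration_um < 0:
            raise ValidationError("added_concentration_um must be >= 0")


@dataclass
class ConcentrationSet:
    """One row of nutrient concentrations (µM) with derived quantities.

    NO₃⁻ is derived as NOx⁻ − NO₂⁻, DIN as NH₄⁺ + NOx⁻, DON as TDN − DIN.
    Negative derived values clip to 0 and leave a persistent flag.
    """

    nh4: float
    no2: float
    nox: float
    tdn: float = math.nan
    po4: float = math.nan
    no3: float = math.nan
    din: float = math.nan
    don: float = math.nan
    flags: set[str] = field(default_factory=set)


def derive_concentrations(raw: ConcentrationSet) -> ConcentrationSet:
    """Populate NO₃⁻, DIN and DON from the measured NH₄⁺/NO₂⁻/NOx⁻/TDN.

    Returns a new ConcentrationSet; negatives from noise near zero are
    clipped to 0 with ``NO3_CLIPPED`` / ``DON_CLIPPED`` flags retained.
    """
    out = dataclasses.replace(raw, flags=set(raw.flags))
    no3 = raw.nox - raw.no2
    if no3 < 0:
        out.flags.add("NO3_CLIPPED")
        no3 = 0.0
    out.no3 = no3
    out.din = raw.nh4 + raw.nox
    if not math.isnan(raw.tdn):
        don = raw.tdn - out.din
        if don < 0:
            out.flags.add("DON_CLIPPED")
            don = 0.0
        out.don = don
    return out


class FluxMode(str, enum.Enum):
    REGRESSION = "regression"
    ENDPOINT = "endpoint"


@dataclass
class RunConfig:
    """Thresholds and plumbing for a pipeline run.

    significance_alpha_denit/dnra gate the slope regressions for
    denitrification (p < 0.05) and DNRA (p < 0.10); o2_drawdown_limit is
    the maximal relative O₂ change tolerated before flagging a core
    incubation; fixation_sd_multiplier is the k of the k×SD atom%-excess
    detection rule; independence_tolerance is the relative difference
    accepted between tracer levels in the r-IPT independence check.
    """

    significance_alpha_denit: float = 0.05
    significance_alpha_dnra: float = 0.10
    o2_drawdown_limit: float = 0.20
    fixation_sd_multiplier: float = 2.0
    independence_tolerance: float = 0.25
    flux_mode: FluxMode = FluxMode.REGRESSION
    control_correct_microcosms: bool = True
    anammox_corrects_dtot: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "significance_alpha_denit",
            "significance_alpha_dnra",
            "o2_drawdown_limit",
            "independence_tolerance",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.fixation_sd_multiplier < 0:
            raise ValidationError("fixation_sd_multiplier must be >= 0")
        self.flux_mode = FluxMode(self.flux_mode)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flux_mode"] = self.flux_mode.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise SchemaError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Tabular I/O (long/tidy layout)
# ---------------------------------------------------------------------------

SERIES_COLUMNS = ["vessel_id", "time_h", "analyte", "concentration_uM"]
GEOMETRY_COLUMNS = ["vessel_id", "kind", "water_volume_L", "sediment_area_m2", "biomass_sfdw_g"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_incubation_table(
    path: str | Path,
    blank_correct: bool = False,
) -> list[IncubationSeries]:
    """Read a long-format incubation CSV into validated series.

    Expected columns: vessel_id, time_h, analyte, concentration_uM and an
    optional blank_uM column subtracted when ``blank_correct`` is set
    (default: no correction).  Unknown analytes and non-monotonic times are
    rejected with errors naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, SERIES_COLUMNS, path)
    bad = set(df["analyte"].astype(str)) - {a.value for a in Analyte}
    if bad:
        raise SchemaError(f"{path}: unknown analyte(s) {sorted(bad)}")
    conc = df["concentration_uM"].astype(float)
    if blank_correct and "blank_uM" in df.columns:
        conc = conc - df["blank_uM"].fillna(0.0).astype(float)
    df = df.assign(_conc=conc)
    out: list[IncubationSeries] = []
    for (vessel, analyte), grp in df.groupby(["vessel_id", "analyte"], sort=True):
        grp = grp.sort_index()  # preserve file order; monotonicity is validated
        times = grp["time_h"].astype(float).tolist()
        if len(set(times)) != len(times):
            raise ValidationError(
                f"{path}: duplicated time for vessel {vessel}/{analyte}"
            )
        out.append(
            IncubationSeries(
                vessel_id=str(vessel),
                analyte=Analyte(analyte),
                times=tuple(times),
                concentrations=tuple(grp["_conc"].tolist()),
            )
        )
    return out


def write_incubation_table(series: Iterable[IncubationSeries], path: str | Path) -> None:
    """Write series to long CSV; a read round-trips text-representable values."""
    rows = [
        {
            "vessel_id": s.vessel_id,
            "time_h": t,
            "analyte": s.analyte.value,
            "concentration_uM": c,
        }
        for s in series
        for t, c in zip(s.times, s.concentrations)
    ]
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Convenience converter: wide table (one column per analyte) → tidy long."""
    _require_columns(df, ["vessel_id", "time_h"], "<wide frame>")
    value_cols = [c for c in df.columns if c in {a.value for a in Analyte}]
    if not value_cols:
        raise SchemaError("wide table has no recognized analyte columns")
    long = df.melt(
        id_vars=["vessel_id", "time_h"],
        value_vars=value_cols,
        var_name="analyte",
        value_name="concentration_uM",
    ).dropna(subset=["concentration_uM"])
    return long[SERIES_COLUMNS]


def read_geometry_table(path: str | Path) -> dict[str, VesselGeometry]:
    """Read per-vessel geometry CSV keyed by vessel_id."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ["vessel_id", "kind", "water_volume_L"], path)
    out: dict[str, VesselGeometry] = {}
    for _, row in df.iterrows():
        area = row.get("sediment_area_m2")
        area = None if area is None or (isinstance(area, float) and math.isnan(area)) else float(area)
        out[str(row["vessel_id"])] = VesselGeometry(
            kind=VesselKind(str(row["kind"])),
            water_volume_l=float(row["water_volume_L"]),
            sediment_area_m2=area,
            biomass_sfdw_g=float(row.get("biomass_sfdw_g", 0.0) or 0.0),
        )
    return out


def write_geometry_table(geoms: Mapping[str, VesselGeometry], path: str | Path) -> None:
    rows = [
        {
            "vessel_id": vid,
            "kind": g.kind.value,
            "water_volume_L": g.water_volume_l,
            "sediment_area_m2": g.sediment_area_m2,
            "biomass_sfdw_g": g.biomass_sfdw_g,
        }
        for vid, g in geoms.items()
    ]
    pd.DataFrame(rows, columns=GEOMETRY_COLUMNS).to_csv(path, index=False)


def read_tracer_spec(path: str | Path) -> TracerSpec:
    """Read a tracer YAML/JSON file: label, added_concentration_um, epsilon."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: tracer spec must be a mapping")
    try:
        return TracerSpec(
            label=TracerLabel(data["label"]),
            added_concentration_um=float(data["added_concentration_um"]),
            epsilon=float(data["epsilon"]),
        )
    except KeyError as e:
        raise SchemaError(f"{path}: missing tracer key {e}") from e
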