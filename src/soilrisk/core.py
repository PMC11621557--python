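"""Domain types, parameter registries, and sample-table I/O.

The pipeline's sole measured input is a georeferenced soil-survey table of
per-site heavy-metal concentrations (mg/kg).  Everything else — geochemical
background values, age-stratified exposure profiles, and route-specific
toxicity values (reference doses and cancer slope factors) — is a registry
of literature constants, shipped with defaults and overridable through a
flat dotted-key config file (see :mod:`soilrisk.config`).

Units throughout: concentrations mg/kg, doses mg/kg/day, RfD mg/kg/day,
CSF (mg/kg/day)^-1, SA cm^2, AF mg/cm^2, PEF m^3/kg.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, ValidationError

__all__ = [
    "DEFAULT_PANEL",
    "ROUTES",
    "AGE_GROUPS",
    "SampleTable",
    "ReferenceSet",
    "ExposureProfile",
    "ToxicityRecord",
    "read_sample_table",
    "write_sample_table",
    "load_defaults",
    "DEFAULT_ABS_BY_METAL",
]

#: Metal panel with both a background value and at least one toxicity entry.
DEFAULT_PANEL = ("As", "Cd", "Cr", "Cu", "Fe", "Ni", "Pb", "Zn")

ROUTES = ("oral", "dermal", "inhalation")
AGE_GROUPS = ("adult", "teenager", "child")

_META_COLS = ("site_id", "lat", "lon", "season")


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Georeferenced per-site metal concentrations.

    Parameters
    ----------
    data
        One row per sample site with columns ``site_id``, ``lat``, ``lon``,
        optional ``season``, then one column per panel metal (mg/kg).
        Missing concentrations are ``NaN`` — never silently zero.
    panel
        Ordered tuple of metal column names.
    """

    data: pd.DataFrame
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        df = self.data
        for col in ("site_id", "lat", "lon"):
            if col not in df.columns:
                raise SchemaError(f"mandatory column {col!r} missing")
        for metal in self.panel:
            if metal not in df.columns:
                raise SchemaError(f"panel metal {metal!r} missing from table")
        if "season" not in df.columns:
            df = df.assign(season=pd.NA)
            object.__setattr__(self, "data", df)
        lat, lon = df["lat"].to_numpy(float), df["lon"].to_numpy(float)
        if np.any(np.abs(lat) > 90):
            raise ValidationError("latitude outside [-90, 90]")
        if np.any(np.abs(lon) > 180):
            raise ValidationError("longitude outside [-180, 180]")
        key = df["season"].astype("string").fillna("") + "\x1f" + df["site_id"].astype(str)
        if key.duplicated().any():
            dup = df.loc[key.duplicated(), "site_id"].iloc[0]
            raise ValidationError(f"duplicate site_id {dup!r} within a season")
        for metal in self.panel:
            conc = pd.to_numeric(df[metal], errors="coerce")
            neg = conc < 0
            if neg.any():
                site = df.loc[neg, "site_id"].iloc[0]
                raise ValidationError(
                    f"negative concentration for metal {metal!r} at site {site!r}"
                )
            df[metal] = conc

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def site_ids(self) -> list[str]:
        return self.data["site_id"].astype(str).tolist()

    def concentrations(self, metal: str) -> pd.Series:
        """Per-site concentration of one metal (NaN where unmeasured)."""
        if metal not in self.panel:
            raise KeyError(f"metal {metal!r} not in panel {self.panel}")
        return self.data.set_index("site_id")[metal]


def read_sample_table(path: str | Path, panel=DEFAULT_PANEL) -> SampleTable:
    """Read and validate a sample CSV (``site_id,lat,lon[,season],<metal>...``).

    Columns that are neither site metadata nor panel metals are rejected at
    read time so that silent typos in metal names cannot drop data.
    Empty cells become explicit missing values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = [c for c in df.columns if c not in _META_COLS and c not in panel]
    if unknown:
        raise SchemaError(f"unknown column(s) {unknown} — not in panel {tuple(panel)}")
    present = [m for m in panel if m in df.columns]
    if not present:
        raise SchemaError("no panel metal column present in file")
    return SampleTable(df, tuple(present))


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    """Write a sample CSV that :func:`read_sample_table` round-trips exactly."""
    cols = ["site_id", "lat", "lon", "season", *table.panel]
    table.data.loc[:, cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSet:
    """Per-metal geochemical background values Bx (mg/kg); all > 0."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        for metal, v in self.values.items():
            if not v > 0:
                raise ValidationError(f"background for {metal!r} must be > 0, got {v}")

    def __getitem__(self, metal: str) -> float:
        try:
            return self.values[metal]
        except KeyError:
            raise ConfigurationError(f"no background value configured for metal {metal!r}")

    def __contains__(self, metal: str) -> bool:
        return metal in self.values


@dataclass
class ExposureProfile:
    """One age group's exposure parameters.

    ``AT_days`` is an independent knob (defaults to ED*365 so the exposure
    window equals the averaging window; a lifetime averaging time for cancer
    endpoints is a config change).  Fields may carry numpy arrays of equal
    length, which lets Monte Carlo draws flow through the deterministic dose
    equations unchanged.
    """

    age_group: str
    IR_ingestion: float      # mg soil/day
    IR_inhalation: float     # m^3/day
    EF: float                # days/year
    ED: float                # years
    BW: float                # kg
    AT_days: float           # days
    SA: float                # cm^2 exposed skin
    AF: float                # mg/cm^2 soil-to-skin adherence
    ABS: float               # dermal absorption fraction, (0, 1]
    PEF: Optional[float] = 1.36e9  # m^3/kg particle emission factor

    def __post_init__(self) -> None:
        for name in ("IR_ingestion", "IR_inhalation", "EF", "ED", "BW", "AT_days", "SA", "AF"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValidationError(f"profile {self.age_group!r}: {name} must be > 0")
        a = np.asarray(self.ABS)
        if np.any(a <= 0) or np.any(a > 1):
            raise ValidationError(f"profile {self.age_group!r}: ABS must be in (0, 1]")
        if self.PEF is not None and np.any(np.asarray(self.PEF) <= 0):
            raise ValidationError(f"profile {self.age_group!r}: PEF must be > 0")


@dataclass(frozen=True)
class ToxicityRecord:
    """Route-specific reference doses and cancer slope factors for one metal.

    A ``None`` field means the route is not assessed for that endpoint;
    requesting it raises :class:`ConfigurationError` rather than silently
    skipping.
    """

    metal: str
    RfD_ing: Optional[float] = None
    RfD_derm: Optional[float] = None
    RfD_inh: Optional[float] = None
    CSF_ing: Optional[float] = None
    CSF_derm: Optional[float] = None
    CSF_inh: Optional[float] = None

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "metal":
                continue
            v = getattr(self, f.name)
            if v is not None and not v > 0:
                raise ValidationError(f"{self.metal}: {f.name} must be > 0 if present")

    _RFD = {"oral": "RfD_ing", "dermal": "RfD_derm", "inhalation": "RfD_inh"}
    _CSF = {"oral": "CSF_ing", "dermal": "CSF_derm", "inhalation": "CSF_inh"}

    def rfd(self, route: str) -> float:
        v = getattr(self, self._RFD[route])
        if v is None:
            raise ConfigurationError(f"no RfD for {self.metal} via {route}")
        return v

    def csf(self, route: str) -> float:
        v = getattr(self, self._CSF[route])
        if v is None:
            raise ConfigurationError(f"no CSF for {self.metal} via {route}")
        return v

    def has_rfd(self, route: str) -> bool:
        return getattr(self, self._RFD[route]) is not None

    def has_csf(self, route: str) -> bool:
        return getattr(self, self._CSF[route]) is not None


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

_DEFAULT_REFERENCES = {
    "As": 5.0, "Cd": 0.3, "Cr": 75.0, "Cu": 20.0,
    "Fe": 50_000.0, "Ni": 30.0, "Pb": 20.0, "Zn": 50.0,
}

# Adherence factor and dermal absorption fraction are USEPA-conventional
# defaults (the standard residential soil-contact values), not
# site-specific measurements; override via config where local data exist.
_DEFAULT_EXPOSURE = {
    "adult": dict(IR_ingestion=100.0, IR_inhalation=20.0, EF=365.0, ED=35.0,
                  BW=70.0, SA=6600.0, AF=0.07, ABS=0.001),
    "teenager": dict(IR_ingestion=150.0, IR_inhalation=15.0, EF=365.0, ED=15.0,
                     BW=35.0, SA=5000.0, AF=0.2, ABS=0.001),
    "child": dict(IR_ingestion=200.0, IR_inhalation=10.0, EF=365.0, ED=3.0,
                  BW=15.0, SA=2800.0, AF=0.2, ABS=0.001),
}

#: Arsenic is the one panel metal with an established dermal absorption
#: fraction well above the generic soil default.
DEFAULT_ABS_BY_METAL = {"As": 0.03}

_DEFAULT_TOXICITY = {
    "As": ToxicityRecord("As", RfD_ing=3e-4, RfD_derm=1.23e-4,
                         CSF_ing=1.5, CSF_derm=1.5, CSF_inh=15.1),
    "Cd": ToxicityRecord("Cd", RfD_ing=1e-4, RfD_derm=1e-5,
                         CSF_ing=0.38, CSF_derm=6.3, CSF_inh=6.3),
    "Fe": ToxicityRecord("Fe", RfD_ing=0.7, RfD_derm=0.7),
    "Hg": ToxicityRecord("Hg", RfD_ing=3e-4, RfD_derm=2.1e-5),
    "Ni": ToxicityRecord("Ni", RfD_ing=140e-3, RfD_derm=1.8e-3,
                         CSF_ing=0.84, CSF_derm=0.84, CSF_inh=0.84),
    "Pb": ToxicityRecord("Pb", RfD_ing=3.5e-4, RfD_derm=5.25e-4,
                         CSF_ing=0.0085, CSF_derm=0.042),
    "Zn": ToxicityRecord("Zn", RfD_ing=0.3),
}


def _default_profiles() -> dict[str, ExposureProfile]:
    out = {}
    for age, p in _DEFAULT_EXPOSURE.items():
        out[age] = ExposureProfile(age_group=age, AT_days=p["ED"] * 365.0, **p)
    return out


def load_defaults(which: str):
    """Return a default registry: ``references``, ``exposure`` or ``toxicity``.

    ``references`` -> :class:`ReferenceSet`;
    ``exposure``   -> mapping age group -> :class:`ExposureProfile`;
    ``toxicity``   -> mapping metal -> :class:`ToxicityRecord`.
    """
    if which == "references":
        return ReferenceSet(dict(_DEFAULT_REFERENCES))
    if which == "exposure":
        return _default_profiles()
    if which == "toxicity":
        return dict(_DEFAULT_TOXICITY)
    raise ConfigurationError(
        f"unknown registry {which!r}; expected references, exposure or toxicity"
    )
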