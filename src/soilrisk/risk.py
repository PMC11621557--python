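"""Non-carcinogenic (HQ/HI) and carcinogenic (CR) health risk.

HQ = DI / RfD per route; HI = sum of HQs over metals within a route and age
group (HQ or HI above 1 flags non-cancer concern).  CR = DI * CSF, an
incremental lifetime cancer probability banded at 1e-6 (negligible) and
1e-4 (unacceptable).  Metals lacking an RfD or CSF for a route are reported
"not assessed" (NaN), never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import (
    ROUTES,
    DEFAULT_ABS_BY_METAL,
    ExposureProfile,
    SampleTable,
    ToxicityRecord,
)
from .dose import dose_dermal, dose_ingestion, dose_inhalation
from .errors import ValidationError

__all__ = [
    "RiskThresholds",
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "cr_band",
    "risk_pipeline",
    "RiskTable",
]

NOT_ASSESSED = "not assessed"


@dataclass(frozen=True)
class RiskThresholds:
    hq_limit: float = 1.0
    hi_limit: float = 1.0
    cr_negligible: float = 1e-6
    cr_unacceptable: float = 1e-4

    def __post_init__(self) -> None:
        if not self.cr_negligible < self.cr_unacceptable:
            raise ValidationError("cr_negligible must be < cr_unacceptable")


def hazard_quotient(daily_intake, rfd: float):
    """HQ = daily intake / reference dose (both mg/kg/day)."""
    if rfd is None or not rfd > 0:
        raise ValidationError(f"RfD must be > 0, got {rfd}")
    return daily_intake / rfd


def hazard_index(hqs: Sequence[float]) -> float:
    """HI = sum of hazard quotients; always >= max(hqs)."""
    hqs = np.asarray(list(hqs), dtype=float)
    if hqs.size == 0:
        raise ValidationError("hazard_index requires a non-empty HQ list")
    if np.any(hqs < 0):
        raise ValidationError("hazard quotients must be >= 0")
    return float(np.sum(hqs))


def cancer_risk(daily_intake, csf: float):
    """CR = daily intake * cancer slope factor (dimensionless probability)."""
    if csf is None or not csf > 0:
        raise ValidationError(f"CSF must be > 0, got {csf}")
    return daily_intake * csf


def cr_band(cr: float, thresholds: RiskThresholds = RiskThresholds()) -> str:
    """Band a cancer risk: negligible (<= 1e-6), acceptable, unacceptable (> 1e-4)."""
    if cr < 0 or not np.isfinite(cr):
        raise ValidationError(f"cancer risk must be finite and >= 0, got {cr}")
    if cr <= thresholds.cr_negligible:
        return "negligible"
    if cr <= thresholds.cr_unacceptable:
        return "acceptable"
    return "unacceptable"


_DOSE_FN = {"oral": dose_ingestion, "dermal": dose_dermal, "inhalation": dose_inhalation}


@dataclass
class RiskTable:
    """Long-format risk results.

    ``records``: one row per (site, metal, route, age group) with
    ``daily_intake``, ``hq``, ``cr`` (NaN where not assessed) and ``cr_band``;
    ``hi``: one row per (site, route, age group) with the hazard index over
    assessed metals and an ``hi_exceeds`` flag.
    """

    records: pd.DataFrame
    hi: pd.DataFrame
    thresholds: RiskThresholds = RiskThresholds()

    def write_csv(self, records_path, hi_path) -> None:
        self.records.to_csv(records_path, index=False)
        self.hi.to_csv(hi_path, index=False)


def risk_pipeline(
    samples: SampleTable,
    profiles: dict[str, ExposureProfile],
    toxicity: dict[str, ToxicityRecord],
    refs=None,
    *,
    routes: Sequence[str] = ROUTES,
    age_groups: Sequence[str] | None = None,
    abs_by_metal: dict[str, float] | None = None,
    thresholds: RiskThresholds = RiskThresholds(),
) -> RiskTable:
    """Evaluate doses, HQ, CR and HI over sites x metals x routes x age groups.

    A toxicity record missing the value for one route — or a panel metal
    with no record at all — yields NaN for that cell with band
    "not assessed"; doses are still reported.  Missing concentrations
    propagate as missing rows, never zeros.  ``refs`` is accepted for interface symmetry
    with the index pipeline but is not needed for risk.
    """
    if abs_by_metal is None:
        abs_by_metal = dict(DEFAULT_ABS_BY_METAL)
    age_groups = tuple(age_groups or profiles.keys())
    for age in age_groups:
        if age not in profiles:
            raise ValidationError(f"no exposure profile for age group {age!r}")

    rows = []
    for metal in samples.panel:
        # a panel metal with no toxicity record at all still gets its doses;
        # HQ/CR come out "not assessed" rather than silently dropped
        tox = toxicity.get(metal) or ToxicityRecord(metal)
        conc = samples.concentrations(metal)
        for age in age_groups:
            base = profiles[age]
            prof = (
                replace(base, ABS=abs_by_metal[metal])
                if metal in abs_by_metal
                else base
            )
            for route in routes:
                dose_fn = _DOSE_FN[route]
                for sid, c in conc.items():
                    if pd.isna(c):
                        rows.append((str(sid), metal, route, age,
                                     np.nan, np.nan, np.nan, NOT_ASSESSED))
                        continue
                    di = dose_fn(float(c), prof)
                    hq = di / tox.rfd(route) if tox.has_rfd(route) else np.nan
                    if tox.has_csf(route):
                        cr = di * tox.csf(route)
                        band = cr_band(cr, thresholds)
                    else:
                        cr, band = np.nan, NOT_ASSESSED
                    rows.append((str(sid), metal, route, age, di, hq, cr, band))

    records = pd.DataFrame(
        rows,
        columns=["site_id", "metal", "route", "age_group",
                 "daily_intake", "hq", "cr", "cr_band"],
    )
    hi = (
        records.dropna(subset=["hq"])
        .groupby(["site_id", "route", "age_group"], as_index=False)["hq"]
        .sum()
        .rename(columns={"hq": "hi"})
    )
    hi["hi_exceeds"] = hi["hi"] > thresholds.hi_limit
    return RiskTable(records, hi, thresholds)
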