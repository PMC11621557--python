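"""Probabilistic risk via Monte Carlo uncertainty propagation.

Input parameters (metal concentrations, ingestion rate, body weight, ...)
are described by parametric distributions — log-normal, gamma, normal or
constant — and propagated jointly through the *same* dose and risk
equations the deterministic pipeline uses, the draws riding through the
:class:`~soilrisk.core.ExposureProfile` fields as numpy arrays.  The
resulting CR and HQ distributions are summarised by mean, sd and
percentiles (default 5th/50th/95th, linear interpolation between order
statistics so cross-language reimplementations agree).

Distribution parameters can be fitted from a measured sample table
(:func:`fit_concentration_distribution`) or supplied explicitly; inputs
are sampled independently (no correlation structure is imposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
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
    "DistributionSpec",
    "SimulationConfig",
    "SimulationSummary",
    "fit_concentration_distribution",
    "specs_from_samples",
    "run_simulation",
    "DEFAULT_FAMILIES",
]

_FAMILIES = ("lognormal", "gamma", "normal", "constant")

#: Families used when fitting concentrations from a sample table.  Nickel is
#: conventionally right-skewed but lighter-tailed than the log-normal metals.
DEFAULT_FAMILIES = {"As": "lognormal", "Cd": "lognormal", "Ni": "gamma"}
_FALLBACK_FAMILY = "lognormal"


@dataclass(frozen=True)
class DistributionSpec:
    """One input parameter's sampling law.

    params by family — lognormal: ``mu``, ``sigma`` (log-space, sigma >= 0);
    gamma: ``shape``, ``scale``; normal: ``mean``, ``sd`` (negative draws
    rejected and resampled); constant: ``value``.
    """

    family: str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        p = self.params
        need = {
            "lognormal": {"mu", "sigma"},
            "gamma": {"shape", "scale"},
            "normal": {"mean", "sd"},
            "constant": {"value"},
        }[self.family]
        if set(p) != need:
            raise ValidationError(
                f"{self.family} spec needs params {sorted(need)}, got {sorted(p)}"
            )
        if self.family == "lognormal" and p["sigma"] < 0:
            raise ValidationError("lognormal sigma must be >= 0")
        if self.family == "gamma" and (p["shape"] <= 0 or p["scale"] <= 0):
            raise ValidationError("gamma shape and scale must be > 0")
        if self.family == "normal" and p["sd"] < 0:
            raise ValidationError("normal sd must be >= 0")

    @classmethod
    def constant(cls, value: float) -> "DistributionSpec":
        return cls("constant", {"value": float(value)})

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` nonnegative values (negatives resampled, capped at 1000*n redraws)."""
        p = self.params
        if self.family == "constant":
            return np.full(n, p["value"], dtype=float)
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], n)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], n)
        draws = rng.normal(p["mean"], p["sd"], n)
        redrawn = 0
        while True:
            neg = draws < 0
            bad = int(neg.sum())
            if bad == 0:
                return draws
            redrawn += bad
            if redrawn > 1000 * n:
                raise ValidationError(
                    f"nonnegativity resampling cap exceeded for {self}; "
                    "distribution mass is overwhelmingly negative"
                )
            draws[neg] = rng.normal(p["mean"], p["sd"], bad)


def fit_concentration_distribution(values, family: str) -> DistributionSpec:
    """Fit a distribution to measured concentrations.

    lognormal: mean/sd of log-values; gamma: method of moments
    (shape = m^2/v, scale = v/m); normal: sample mean/sd.  Sample moments
    use ddof=1.  Log-normal and gamma require >= 3 strictly positive values.
    """
    x = np.asarray([v for v in values if not pd.isna(v)], dtype=float)
    if family in ("lognormal", "gamma"):
        if x.size < 3:
            raise ValidationError(f"{family} fit requires >= 3 values, got {x.size}")
        if np.any(x <= 0):
            raise ValidationError(f"{family} fit requires strictly positive values")
    if family == "lognormal":
        logs = np.log(x)
        return DistributionSpec(
            "lognormal", {"mu": float(np.mean(logs)), "sigma": float(np.std(logs, ddof=1))}
        )
    if family == "gamma":
        m, v = float(np.mean(x)), float(np.var(x, ddof=1))
        if v == 0:
            raise ValidationError("gamma fit undefined for zero-variance data")
        return DistributionSpec("gamma", {"shape": m * m / v, "scale": v / m})
    if family == "normal":
        if x.size < 2:
            raise ValidationError("normal fit requires >= 2 values")
        return DistributionSpec(
            "normal", {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
        )
    raise ValidationError(f"cannot fit family {family!r}")


def specs_from_samples(
    samples: SampleTable, families: dict[str, str] | None = None
) -> dict[str, DistributionSpec]:
    """Fit one concentration spec per panel metal from a sample table."""
    families = {**DEFAULT_FAMILIES, **(families or {})}
    out = {}
    for metal in samples.panel:
        vals = samples.concentrations(metal).dropna()
        out[metal] = fit_concentration_distribution(
            vals, families.get(metal, _FALLBACK_FAMILY)
        )
    return out


@dataclass
class SimulationConfig:
    """Monte Carlo settings: iteration count, seed, percentiles and which
    non-concentration inputs are stochastic.

    ``inputs`` maps dotted parameter keys to specs, e.g.
    ``{"exposure.adult.BW": DistributionSpec("normal", {"mean": 70, "sd": 10})}``
    or ``"toxicity.As.CSF_ing"``; everything unlisted stays at its
    deterministic registry value.
    """

    n_iter: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)
    inputs: dict[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")
        for q in self.percentiles:
            if not 0 < q < 100:
                raise ValidationError(f"percentile {q} outside (0, 100)")


@dataclass
class SimulationSummary:
    """Summary statistics per (metal, route, age group, quantity).

    ``table`` columns: metal, route, age_group, quantity (cr|hq), stat
    (mean, sd, p<q>...), value.  ``draws`` optionally retains the full
    vectors keyed by (metal, route, age_group, quantity).
    """

    table: pd.DataFrame
    n_iter: int
    seed: int
    draws: dict[tuple, np.ndarray] | None = None

    def value(self, metal: str, route: str, age_group: str, quantity: str, stat: str) -> float:
        t = self.table
        m = (
            (t.metal == metal) & (t.route == route)
            & (t.age_group == age_group) & (t.quantity == quantity) & (t.stat == stat)
        )
        sel = t.loc[m, "value"]
        if sel.empty:
            raise KeyError((metal, route, age_group, quantity, stat))
        return float(sel.iloc[0])

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _stat_name(q: float) -> str:
    return f"p{int(q)}" if float(q).is_integer() else f"p{q}"


_DOSE_FN = {"oral": dose_ingestion, "dermal": dose_dermal, "inhalation": dose_inhalation}


def run_simulation(
    conc,
    profiles: dict[str, ExposureProfile],
    toxicity: dict[str, ToxicityRecord],
    cfg: SimulationConfig,
    *,
    routes: Sequence[str] = ROUTES,
    age_groups: Sequence[str] | None = None,
    abs_by_metal: dict[str, float] | None = None,
    keep_draws: bool = False,
) -> SimulationSummary:
    """Propagate joint parameter draws through the dose/risk equations.

    ``conc`` is either a mapping metal -> :class:`DistributionSpec` or a
    :class:`~soilrisk.core.SampleTable` (concentration laws then fitted per
    metal).  The summary is a pure function of (specs, profiles, toxicity,
    n_iter, seed): identical seeds give identical results.
    """
    if isinstance(conc, SampleTable):
        conc_specs = specs_from_samples(conc)
    else:
        conc_specs = dict(conc)
    if abs_by_metal is None:
        abs_by_metal = dict(DEFAULT_ABS_BY_METAL)
    age_groups = tuple(age_groups or profiles.keys())
    n = cfg.n_iter
    rng = np.random.default_rng(cfg.seed)

    # fixed sampling order (sorted keys) so results depend only on the seed
    conc_draws = {m: conc_specs[m].sample(n, rng) for m in sorted(conc_specs)}
    param_draws = {k: cfg.inputs[k].sample(n, rng) for k in sorted(cfg.inputs)}

    profile_fields = (
        "IR_ingestion", "IR_inhalation", "EF", "ED", "BW",
        "AT_days", "SA", "AF", "ABS", "PEF",
    )
    rows, draws = [], {}
    for metal in sorted(conc_specs):
        tox = toxicity.get(metal) or ToxicityRecord(metal)
        cdraw = conc_draws[metal]
        for age in age_groups:
            base = profiles[age]
            overrides = {
                f: param_draws[f"exposure.{age}.{f}"]
                for f in profile_fields
                if f"exposure.{age}.{f}" in param_draws
            }
            if metal in abs_by_metal and "ABS" not in overrides:
                overrides["ABS"] = abs_by_metal[metal]
            prof = replace(base, **overrides) if overrides else base
            for route in routes:
                di = _DOSE_FN[route](cdraw, prof)
                for quantity, fieldmap in (("hq", tox._RFD), ("cr", tox._CSF)):
                    key = f"toxicity.{metal}.{fieldmap[route]}"
                    if key in param_draws:
                        coef = param_draws[key]
                    else:
                        coef = getattr(tox, fieldmap[route])
                        if coef is None:
                            continue  # not assessed for this route
                    vec = di / coef if quantity == "hq" else di * coef
                    vec = np.asarray(vec, dtype=float)
                    stats = [("mean", float(np.mean(vec))),
                             ("sd", float(np.std(vec, ddof=1)) if n > 1 else 0.0)]
                    qs = np.percentile(vec, cfg.percentiles)  # linear (type-7)
                    stats += [(_stat_name(q), float(v))
                              for q, v in zip(cfg.percentiles, qs)]
                    for stat, value in stats:
                        rows.append((metal, route, age, quantity, stat, value))
                    if keep_draws:
                        draws[(metal, route, age, quantity)] = vec

    table = pd.DataFrame(
        rows, columns=["metal", "route", "age_group", "quantity", "stat", "value"]
    )
    return SimulationSummary(table, n_iter=n, seed=cfg.seed,
                             draws=draws if keep_draws else None)
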