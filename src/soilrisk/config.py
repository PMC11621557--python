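"""Flat dotted-key configuration.

Every registry default has a stable dotted key, e.g.::

    references.As: 7.2
    exposure.adult.BW: 65
    exposure.adult.AT_days: 25550      # lifetime averaging for cancer endpoints
    toxicity.As.CSF_ing: 1.5
    abs_by_metal.As: 0.03
    mc.n_iter: 10000
    idw.power: 2

Files are YAML; both flat ``a.b.c: v`` keys and nested mappings are
accepted and normalised to the flat form.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .core import (
    ExposureProfile,
    ReferenceSet,
    ToxicityRecord,
    load_defaults,
)
from .errors import ConfigurationError

__all__ = ["load_config", "flatten", "build_registries"]


def flatten(mapping: dict, prefix: str = "") -> dict[str, object]:
    """Collapse nested mappings into single-level dotted keys."""
    out: dict[str, object] = {}
    for key, value in mapping.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(flatten(value, prefix=dotted + "."))
        else:
            out[dotted] = value
    return out


def load_config(path: str | Path) -> dict[str, object]:
    """Read a YAML config file into a flat dotted-key dict."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    return flatten(raw)


def build_registries(cfg: dict[str, object] | None = None):
    """Materialise (references, profiles, toxicity, abs_by_metal) with overrides applied.

    ``cfg`` is a flat dotted-key dict as produced by :func:`load_config`;
    unknown keys under the registry prefixes raise
    :class:`~soilrisk.errors.ConfigurationError` so typos do not silently
    leave a default in place.
    """
    cfg = dict(cfg or {})
    refs = load_defaults("references")
    profiles = load_defaults("exposure")
    toxicity = load_defaults("toxicity")
    from .core import DEFAULT_ABS_BY_METAL
    abs_by_metal = dict(DEFAULT_ABS_BY_METAL)

    ref_values = dict(refs.values)
    prof_kwargs = {
        age: {f.name: getattr(p, f.name) for f in dataclasses.fields(p)}
        for age, p in profiles.items()
    }
    tox_kwargs = {
        metal: {f.name: getattr(r, f.name) for f in dataclasses.fields(r)}
        for metal, r in toxicity.items()
    }

    profile_fields = {f.name for f in dataclasses.fields(ExposureProfile)} - {"age_group"}
    tox_fields = {f.name for f in dataclasses.fields(ToxicityRecord)} - {"metal"}

    for key, value in cfg.items():
        parts = key.split(".")
        head = parts[0]
        if head == "references":
            ref_values[parts[1]] = float(value)
        elif head == "exposure":
            age, name = parts[1], parts[2]
            if age not in prof_kwargs:
                raise ConfigurationError(f"unknown age group {age!r} in key {key!r}")
            if name not in profile_fields:
                raise ConfigurationError(f"unknown exposure field {name!r} in key {key!r}")
            prof_kwargs[age][name] = float(value)
        elif head == "toxicity":
            metal, name = parts[1], parts[2]
            if name not in tox_fields:
                raise ConfigurationError(f"unknown toxicity field {name!r} in key {key!r}")
            tox_kwargs.setdefault(metal, {"metal": metal})[name] = (
                None if value is None else float(value)
            )
            tox_kwargs[metal]["metal"] = metal
        elif head == "abs_by_metal":
            abs_by_metal[parts[1]] = float(value)
        else:
            # other namespaces (mc., idw., synth.) are consumed elsewhere
            continue

    refs = ReferenceSet(ref_values)
    profiles = {age: ExposureProfile(**kw) for age, kw in prof_kwargs.items()}
    toxicity = {metal: ToxicityRecord(**kw) for metal, kw in tox_kwargs.items()}
    return refs, profiles, toxicity, abs_by_metal
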