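"""Environmental contamination indices.

Three classical sediment/soil pollution measures, each comparing a measured
concentration Cx (mg/kg) with a geochemical background Bx (mg/kg):

* geo-accumulation index  Igeo = log2(Cx / (1.5 * Bx)), the factor 1.5
  absorbing natural background variation; classified on a 0-6 scale,
* contamination factor    CF = Cx / Bx, classified low/moderate/
  considerable/very high,
* pollution load index    PLI = geometric mean of a site's CFs across the
  metal panel; PLI > 1 flags metal pollution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import ReferenceSet, SampleTable
from .errors import ConfigurationError, UndefinedIndexError, ValidationError

__all__ = [
    "igeo",
    "contamination_factor",
    "pollution_load_index",
    "classify",
    "igeo_class",
    "index_table",
    "IndexTable",
    "IGEO_LABELS",
]

IGEO_LABELS = {
    0: "Practically unpolluted",
    1: "Unpolluted to moderately polluted",
    2: "Moderately polluted",
    3: "Moderately to strongly polluted",
    4: "Strongly polluted",
    5: "Strongly to very strongly polluted",
    6: "Very strongly polluted",
}

_CF_BINS = (
    (1.0, "Low contamination"),
    (3.0, "Moderate contamination"),
    (6.0, "Considerable contamination"),
    (math.inf, "Very high contamination"),
)


def igeo(conc: float, background: float) -> float:
    """Geo-accumulation index log2(conc / (1.5 * background)).

    Defined only for a strictly positive concentration; a zero or negative
    concentration raises :class:`UndefinedIndexError` (distinct from the
    :class:`ValidationError` raised for a nonpositive background).
    """
    if not background > 0:
        raise ValidationError(f"background must be > 0, got {background}")
    if not conc > 0:
        raise UndefinedIndexError(f"Igeo undefined for concentration {conc} <= 0")
    return math.log2(conc / (1.5 * background))


def contamination_factor(conc: float, reference: float) -> float:
    """Contamination factor conc / reference (both mg/kg)."""
    if not reference > 0:
        raise ValidationError(f"reference must be > 0, got {reference}")
    if conc < 0:
        raise ValidationError(f"concentration must be >= 0, got {conc}")
    return conc / reference


def pollution_load_index(cfs: Sequence[float]) -> float:
    """Geometric mean of contamination factors; permutation invariant.

    Computed as exp(mean(log cf)) for numerical stability at large panels.
    """
    cfs = np.asarray(list(cfs), dtype=float)
    if cfs.size == 0:
        raise ValidationError("PLI requires at least one contamination factor")
    if np.any(cfs <= 0) or not np.all(np.isfinite(cfs)):
        raise UndefinedIndexError("PLI undefined for nonpositive or non-finite CF")
    return float(np.exp(np.mean(np.log(cfs))))


def igeo_class(value: float) -> int:
    """Integer pollution class 0-6 for an Igeo value (bins (k-1, k] -> k; <= 0 -> 0)."""
    if not np.isfinite(value):
        raise ValidationError(f"non-finite Igeo value {value}")
    if value <= 0:
        return 0
    if value > 5:
        return 6
    return int(math.ceil(value))


def classify(index_value: float, scheme: str) -> str:
    """Classification label for an index value under ``igeo``, ``cf`` or ``pli``."""
    if not np.isfinite(index_value):
        raise ValidationError(f"non-finite index value {index_value}")
    if scheme == "igeo":
        return IGEO_LABELS[igeo_class(index_value)]
    if scheme == "cf":
        for upper, label in _CF_BINS:
            if index_value < upper:
                return label
        return _CF_BINS[-1][1]
    if scheme == "pli":
        return "Metal pollution exists" if index_value > 1 else "No metal pollution"
    raise ValidationError(f"unknown classification scheme {scheme!r}")


@dataclass
class IndexTable:
    """Per-site pollution indices in long format.

    ``per_metal``: columns ``site_id, metal, igeo, igeo_class, cf, cf_class``
    (NaN igeo / empty class where the concentration is missing or zero);
    ``pli``: columns ``site_id, pli, pli_status``.
    """

    per_metal: pd.DataFrame
    pli: pd.DataFrame

    def write_csv(self, per_metal_path, pli_path) -> None:
        self.per_metal.to_csv(per_metal_path, index=False)
        self.pli.to_csv(pli_path, index=False)


def index_table(samples: SampleTable, refs: ReferenceSet) -> IndexTable:
    """Compute Igeo, CF (per site x metal) and PLI (per site).

    A site's PLI is the geometric mean over the metals actually measured
    there (n reduced for missing values).  If any measured CF is exactly
    zero the geometric mean degenerates, so the PLI is reported missing
    with a warning rather than as 0.
    """
    for metal in samples.panel:
        if metal not in refs:
            raise ConfigurationError(f"no background value configured for metal {metal!r}")

    rows, pli_rows = [], []
    for _, site in samples.data.iterrows():
        sid = str(site["site_id"])
        cfs = []
        zero_cf = False
        for metal in samples.panel:
            conc = site[metal]
            if pd.isna(conc):
                rows.append((sid, metal, np.nan, pd.NA, np.nan, pd.NA))
                continue
            cf = contamination_factor(float(conc), refs[metal])
            if cf > 0:
                ig = igeo(float(conc), refs[metal])
                rows.append((sid, metal, ig, igeo_class(ig), cf, classify(cf, "cf")))
                cfs.append(cf)
            else:
                zero_cf = True
                rows.append((sid, metal, np.nan, pd.NA, cf, classify(cf, "cf")))
        if zero_cf or not cfs:
            warnings.warn(
                f"site {sid}: PLI undefined (zero or no measured CF); reported missing",
                stacklevel=2,
            )
            pli_rows.append((sid, np.nan, pd.NA))
        else:
            p = pollution_load_index(cfs)
            pli_rows.append((sid, p, classify(p, "pli")))

    per_metal = pd.DataFrame(
        rows, columns=["site_id", "metal", "igeo", "igeo_class", "cf", "cf_class"]
    )
    pli = pd.DataFrame(pli_rows, columns=["site_id", "pli", "pli_status"])
    return IndexTable(per_metal, pli)
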