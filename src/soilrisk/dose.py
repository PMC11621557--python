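"""Average daily intake of a soil contaminant by exposure route.

Three soil-contact pathways, each an USEPA-style chronic daily intake in
mg of metal per kg body weight per day for a receptor described by an
:class:`~soilrisk.core.ExposureProfile`:

ingestion   Cs * IR_ing * EF * ED / (BW * AT) * 1e-6
dermal      Cs * SA * AF * ABS * EF * ED / (BW * AT) * 1e-6
inhalation  Cs * IR_inh * EF * ED / (BW * AT * PEF)

The 1e-6 converts mg of soil to kg of soil; the inhalation route has no
such factor because the particle emission factor PEF (m^3/kg) already
performs the soil-to-air medium conversion.  All three are linear and
homogeneous in the concentration Cs, and every profile field may carry an
array of Monte Carlo draws — the same code path serves both deterministic
and probabilistic evaluation.
"""

from __future__ import annotations

import numpy as np

from .core import ExposureProfile
from .errors import ConfigurationError, ValidationError

__all__ = ["dose_ingestion", "dose_dermal", "dose_inhalation"]


def _check_conc(conc) -> None:
    if np.any(np.asarray(conc) < 0):
        raise ValidationError("concentration must be >= 0")


def dose_ingestion(conc, p: ExposureProfile):
    """Daily intake via incidental soil ingestion (mg/kg/day)."""
    _check_conc(conc)
    return conc * p.IR_ingestion * p.EF * p.ED / (p.BW * p.AT_days) * 1e-6


def dose_dermal(conc, p: ExposureProfile):
    """Daily intake via dermal absorption from adhered soil (mg/kg/day)."""
    _check_conc(conc)
    return conc * p.SA * p.AF * p.ABS * p.EF * p.ED / (p.BW * p.AT_days) * 1e-6


def dose_inhalation(conc, p: ExposureProfile):
    """Daily intake via inhalation of resuspended soil dust (mg/kg/day)."""
    _check_conc(conc)
    if p.PEF is None:
        raise ConfigurationError("PEF (particle emission factor) is not configured")
    return conc * p.IR_inhalation * p.EF * p.ED / (p.BW * p.AT_days * p.PEF)
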