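"""Plate-reader and invasion assay normalisations.

Three ratio-to-control indices, all invariant under a common rescaling of
treated and control readouts:

* MTT viability percent: 100 * mean treated OD570 / mean control OD570.
* Resazurin (PrestoBlue) spheroid health index: OD570 referenced to the
  600 nm wavelength, then normalised by spheroid size; higher is healthier.
* Transwell invasion index: mean invaded-cell count per field over the
  unirradiated control (1.0 = control; also reported as a percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "AssayResult",
    "viability_percent",
    "presto_health_index",
    "invasion_index",
    "SIZE_METRICS",
]

#: How a measured diameter (µm) enters the PrestoBlue size normalisation.
SIZE_METRICS = ("area", "diameter", "volume")


@dataclass(frozen=True)
class AssayResult:
    """A ratio-to-control index with its delta-method standard deviation."""

    value: float
    sd: float
    n_treated: int
    n_control: int


def _mean_sd(values, what: str) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise InputError(f"at least one {what} value required")
    if np.any(arr < 0):
        raise InputError(f"{what} values must be non-negative")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def _ratio_to_control(treated, control, what: str) -> AssayResult:
    mt, sdt, nt = _mean_sd(treated, f"treated {what}")
    mc, sdc, nc = _mean_sd(control, f"control {what}")
    if mc <= 0:
        raise InputError(f"control {what} mean must be positive")
    ratio = mt / mc
    # delta method on the ratio of two independent means
    rel = 0.0
    if mt > 0:
        rel = (sdt / math.sqrt(nt) / mt) ** 2 + (sdc / math.sqrt(nc) / mc) ** 2
    return AssayResult(value=ratio, sd=ratio * math.sqrt(rel), n_treated=nt, n_control=nc)


def viability_percent(treated_od570, control_od570) -> AssayResult:
    """MTT viability as a percent of the unirradiated control."""
    r = _ratio_to_control(treated_od570, control_od570, "OD570")
    return AssayResult(
        value=100.0 * r.value, sd=100.0 * r.sd, n_treated=r.n_treated,
        n_control=r.n_control,
    )


def presto_health_index(
    od570: float, od600_reference: float, size_metric: float
) -> float:
    """Size-normalised resazurin health index: (OD570/OD600) / size.

    ``size_metric`` is whatever size proxy the caller chose (projected area
    by default upstream); halving the metabolic signal or doubling the size
    halves the index.
    """
    if not (od600_reference > 0):
        raise InputError(f"OD600 reference must be positive, got {od600_reference!r}")
    if not (size_metric > 0):
        raise InputError(f"size metric must be positive, got {size_metric!r}")
    if od570 < 0:
        raise InputError(f"OD570 must be non-negative, got {od570!r}")
    return (od570 / od600_reference) / size_metric


def size_metric_from_diameter(diameter_um: float, kind: str = "area") -> float:
    """Size proxy from a measured diameter: projected area (default),
    diameter itself, or volume (sphere)."""
    if not (diameter_um > 0):
        raise InputError(f"diameter must be positive, got {diameter_um!r}")
    if kind == "diameter":
        return diameter_um
    if kind == "area":
        return math.pi * (diameter_um / 2.0) ** 2
    if kind == "volume":
        return (math.pi / 6.0) * diameter_um**3
    raise InputError(f"size metric kind must be one of {SIZE_METRICS}, got {kind!r}")


def invasion_index(treated_fields, control_fields) -> AssayResult:
    """Invasion relative to the unirradiated control (control = 1.0).

    ``value`` is the ratio form; multiply by 100 for the percent form.
    """
    return _ratio_to_control(treated_fields, control_fields, "invaded-cell count")
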