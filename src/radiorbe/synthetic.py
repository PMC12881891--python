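"""Synthetic raw-data generators with known ground truth.

The study's raw measurements (replicate colony counts, longitudinal spheroid
diameters, plate-reader optical densities, invaded-cell counts) are not
deposited; these generators emulate them so that every pipeline stage is
testable end to end against a known truth. Presets parameterise the
generators from the published summary values: per-modality LQ parameter
pairs reconstructed from the printed (D10, alpha/beta) or (SF2, alpha/beta)
summaries, control plating efficiencies, the published seeding plan, and the
per-dose spheroid growth slopes.

Noise models
------------
* Colony counts are Poisson with mean ``n_seeded * PE * SF(dose)`` — the
  classical clonogenic counting model — with an optional negative-binomial
  overdispersion knob for robustness studies.
* Spheroid diameters follow a per-spheroid linear trajectory
  ``baseline + slope * t`` on the 0-120 h grid at 24 h intervals, with a
  Gaussian baseline across spheroids and Gaussian measurement noise (default
  SD 5 µm, about 1% of a 500 µm spheroid) on every observation.
* Plate readouts carry log-normal multiplicative noise around the condition's
  true relative level.

All generators are deterministic given their scenario's ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .lq import (
    LQParams,
    d_iso,
    params_from_d10_ratio,
    params_from_sf2_ratio,
    params_from_two_survival_points,
    sf_at_dose,
)

__all__ = [
    "ClonogenicScenario",
    "SpheroidScenario",
    "AssayScenario",
    "gen_clonogenic_counts",
    "gen_spheroid_tracks",
    "gen_assay_plate",
    "scenario_presets",
    "default_seeding_plan",
    "CELL_LINES",
    "MODALITIES",
    "CONTROL_MODALITY",
]

CELL_LINES = ("T98G", "U2-OS", "Saos-2")
MODALITIES = ("XRT", "PRT", "CIRT")
#: Modality label used for unirradiated (0 Gy) spheroid/assay controls.
CONTROL_MODALITY = "CTRL"

# Published seeding plan: cells plated per dose, per modality and cell line.
_SEEDING = {
    ("U2-OS", "XRT"): {0: 500, 0.5: 600, 1: 600, 2: 900, 4: 5000, 6: 11000},
    ("Saos-2", "XRT"): {0: 500, 0.5: 750, 1: 600, 2: 1000, 4: 5500, 6: 12000},
    ("T98G", "XRT"): {0: 250, 0.5: 300, 1: 350, 2: 650, 4: 900, 6: 1250},
    ("U2-OS", "PRT"): {0: 500, 0.5: 600, 1: 600, 2: 900, 4: 5000, 6: 11000},
    ("Saos-2", "PRT"): {0: 500, 0.5: 750, 1: 600, 2: 1000, 4: 5500, 6: 12000},
    ("T98G", "PRT"): {0: 250, 0.5: 300, 1: 350, 2: 650, 4: 900, 6: 1250},
    ("U2-OS", "CIRT"): {0: 500, 0.5: 1200, 1: 1200, 2: 1800, 4: 8000, 6: 17000},
    ("Saos-2", "CIRT"): {0: 500, 0.5: 1500, 1: 1600, 2: 2000, 4: 9000, 6: 20000},
    ("T98G", "CIRT"): {0: 250, 0.5: 600, 1: 700, 2: 1300, 4: 1800, 6: 2500},
}

# Control (unirradiated) plating efficiencies.
_PE = {"T98G": 0.37, "U2-OS": 0.35, "Saos-2": 0.34}

# Published 2D summary pairs. Photons: (D10, alpha/beta) where both were
# printed, else (SF2, alpha/beta). Protons: (SF2, alpha/beta). Carbon ions:
# SF2 plus the D10 implied by the published carbon-vs-photon RBE.
_PHOTON_D10_RATIO = {"U2-OS": (7.49, 6.28), "Saos-2": (6.70, 4.89)}
_PHOTON_SF2_RATIO = {"T98G": (0.62, 6.98)}
_PROTON_SF2_RATIO = {"T98G": (0.45, 10.19), "U2-OS": (0.57, 10.44), "Saos-2": (0.56, 9.35)}
_CARBON_SF2 = {"T98G": 0.16, "U2-OS": 0.28, "Saos-2": 0.24}
_CARBON_RBE = {"T98G": 2.4, "U2-OS": 2.2, "Saos-2": 2.1}

# Published spheroid growth slopes (µm/h) per irradiated condition. Where a
# source stated only the 2 and 6 Gy endpoints of a range, the 4 Gy entry is
# their midpoint (marked with a comment).
_SPHEROID_SLOPES = {
    ("T98G", "XRT"): {2: -0.225, 4: -0.3226, 6: -0.3913},
    ("T98G", "PRT"): {2: -0.2579, 4: -0.37595, 6: -0.4940},  # 4 Gy: midpoint
    ("T98G", "CIRT"): {2: -0.2952, 4: -0.4623, 6: -0.5881},
    ("Saos-2", "XRT"): {2: -0.3651, 4: -0.7262, 6: -0.1095},
    ("Saos-2", "PRT"): {2: -0.0496, 4: -0.07875, 6: -0.1079},  # 4 Gy: midpoint
    ("Saos-2", "CIRT"): {2: -0.0519, 4: -0.8095, 6: -0.1492},
    ("U2-OS", "XRT"): {2: -0.0059, 4: -0.0072, 6: -0.0085},  # 4 Gy: midpoint
    ("U2-OS", "PRT"): {2: -0.0289, 4: -0.06305, 6: -0.0972},  # 4 Gy: midpoint
    ("U2-OS", "CIRT"): {2: -0.0190, 4: -0.0839, 6: -0.1488},  # 4 Gy: midpoint
}

# Control spheroids: diameter increment at 120 h relative to baseline (%).
_CONTROL_INCREMENT = {"T98G": 30.0, "Saos-2": 28.0, "U2-OS": 46.0}

#: Default baseline spheroid diameter (µm) used to convert the published
#: percent increments into control slopes on the 0-120 h grid.
DEFAULT_BASELINE_UM = 500.0

# Published 5-day monolayer MTT viabilities (%) — the subset quoted numerically.
_VIABILITY_5D = {
    ("T98G", "XRT", 2): 90.6, ("T98G", "XRT", 6): 80.0,
    ("T98G", "CIRT", 2): 71.4, ("T98G", "CIRT", 6): 56.6,
    ("U2-OS", "XRT", 2): 89.8, ("U2-OS", "XRT", 6): 72.9,
    ("U2-OS", "CIRT", 2): 75.0, ("U2-OS", "CIRT", 6): 55.4,
}

# Published 2D invasion indices relative to control (control = 1.0).
_INVASION = {
    ("T98G", "XRT", 2): 1.06, ("T98G", "XRT", 4): 1.10, ("T98G", "XRT", 6): 1.14,
    ("T98G", "PRT", 2): 0.88, ("T98G", "PRT", 4): 0.77, ("T98G", "PRT", 6): 0.76,
    ("T98G", "CIRT", 2): 0.79, ("T98G", "CIRT", 4): 0.69, ("T98G", "CIRT", 6): 0.53,
    ("Saos-2", "XRT", 2): 1.03, ("Saos-2", "XRT", 4): 1.12, ("Saos-2", "XRT", 6): 1.16,
    ("Saos-2", "PRT", 2): 0.93, ("Saos-2", "PRT", 4): 0.86, ("Saos-2", "PRT", 6): 0.78,
    ("Saos-2", "CIRT", 2): 0.91, ("Saos-2", "CIRT", 4): 0.76, ("Saos-2", "CIRT", 6): 0.71,
    ("U2-OS", "XRT", 2): 1.11, ("U2-OS", "XRT", 4): 1.19, ("U2-OS", "XRT", 6): 1.25,
    ("U2-OS", "PRT", 2): 1.09, ("U2-OS", "PRT", 4): 1.05, ("U2-OS", "PRT", 6): 1.01,
    ("U2-OS", "CIRT", 2): 1.00, ("U2-OS", "CIRT", 4): 0.94, ("U2-OS", "CIRT", 6): 0.89,
}


def default_seeding_plan(cell_line: str | None = None) -> pd.DataFrame:
    """The published per-dose seeding plan as a tidy table.

    Columns: cell_line, modality, dose_gy, n_seeded. Optionally restricted to
    one cell line.
    """
    rows = [
        {"cell_line": cl, "modality": mod, "dose_gy": float(d), "n_seeded": n}
        for (cl, mod), plan in _SEEDING.items()
        for d, n in plan.items()
        if cell_line is None or cl == cell_line
    ]
    if not rows:
        raise InputError(f"unknown cell line {cell_line!r}; choose from {CELL_LINES}")
    return pd.DataFrame(rows).sort_values(
        ["cell_line", "modality", "dose_gy"], ignore_index=True
    )


def _preset_lq_params() -> dict[tuple[str, str], LQParams]:
    params: dict[tuple[str, str], LQParams] = {}
    for cl, (d10, ratio) in _PHOTON_D10_RATIO.items():
        params[(cl, "XRT")] = params_from_d10_ratio(d10, ratio)
    for cl, (sf2, ratio) in _PHOTON_SF2_RATIO.items():
        params[(cl, "XRT")] = params_from_sf2_ratio(sf2, ratio)
    for cl, (sf2, ratio) in _PROTON_SF2_RATIO.items():
        params[(cl, "PRT")] = params_from_sf2_ratio(sf2, ratio)
    for cl in CELL_LINES:
        photon_d10 = d_iso(params[(cl, "XRT")], 0.10)
        carbon_d10 = photon_d10 / _CARBON_RBE[cl]
        sf2 = _CARBON_SF2[cl]
        try:
            params[(cl, "CIRT")] = params_from_two_survival_points(
                2.0, sf2, carbon_d10, 0.10
            )
        except InputError:
            # the two printed summaries are mutually inconsistent with any
            # beta >= 0; fall back to the purely linear high-LET limit that
            # preserves the RBE-defining D10
            params[(cl, "CIRT")] = LQParams(alpha=math.log(10.0) / carbon_d10, beta=0.0)
    return params


@dataclass
class ClonogenicScenario:
    """Ground truth for one cell line's clonogenic experiment.

    ``params_by_modality`` maps modality label to the true LQ curve;
    ``seeding`` defaults to the published plan for the cell line.
    ``dispersion`` switches colony counts from Poisson to negative binomial
    with variance ``m + m^2/dispersion`` (smaller = more overdispersed).
    """

    cell_line: str
    params_by_modality: dict[str, LQParams]
    pe_control: float
    seeding: pd.DataFrame | None = None
    n_replicates: int = 3
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pe_control <= 1.0):
            raise InputError(f"PE must be in (0, 1], got {self.pe_control!r}")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")
        if self.seeding is None:
            self.seeding = default_seeding_plan(self.cell_line)


@dataclass
class SpheroidScenario:
    """Ground truth for one cell line's spheroid growth experiment.

    ``slopes_by_condition`` maps (modality, dose_gy) to the true linear
    growth slope in µm/h; the unirradiated control grows at
    ``control_slope``. ``n_spheroids`` spheroids are simulated per condition
    on the ``times_h`` grid (default 0-120 h at 24 h intervals).
    """

    cell_line: str
    control_slope: float
    slopes_by_condition: dict[tuple[str, float], float]
    baseline_mean_um: float = DEFAULT_BASELINE_UM
    baseline_sd_um: float = 20.0
    times_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0, 120.0)
    noise_sd_um: float = 5.0
    n_spheroids: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sd_um < 0 or self.noise_sd_um < 0:
            raise InputError("noise SDs must be >= 0")
        if self.n_spheroids < 1:
            raise InputError("n_spheroids must be >= 1")


@dataclass
class AssayScenario:
    """Ground truth for a ratio-to-control assay plate.

    ``levels_by_condition`` maps (modality, dose_gy) to the true level
    relative to control (the (CTRL, 0) entry, level 1.0, is added if
    absent). ``cv`` is the multiplicative coefficient of variation of
    well/field readouts.
    """

    assay: str  # "mtt" | "presto" | "invasion"
    cell_line: str
    levels_by_condition: dict[tuple[str, float], float]
    cv: float = 0.05
    n_wells: int = 5
    base_value: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("mtt", "presto", "invasion"):
            raise InputError(f"unknown assay {self.assay!r}")
        if self.cv < 0:
            raise InputError("cv must be >= 0")
        if (CONTROL_MODALITY, 0.0) not in self.levels_by_condition:
            self.levels_by_condition = {
                (CONTROL_MODALITY, 0.0): 1.0,
                **self.levels_by_condition,
            }


def gen_clonogenic_counts(scenario: ClonogenicScenario) -> pd.DataFrame:
    """Simulate replicate colony counts for every seeded condition.

    Counts are Poisson (or negative-binomial, see scenario) with mean
    ``n_seeded * PE * SF(dose)`` under the scenario's per-modality LQ
    parameters. Output matches the ``colonies.csv`` schema.
    """
    rng = np.random.default_rng(scenario.seed)
    rows = []
    for modality in sorted(scenario.params_by_modality):
        params = scenario.params_by_modality[modality]
        plan = scenario.seeding[scenario.seeding["modality"] == modality]
        for _, r in plan.sort_values("dose_gy").iterrows():
            mean = r["n_seeded"] * scenario.pe_control * sf_at_dose(
                params, r["dose_gy"]
            )
            if scenario.dispersion is None:
                counts = rng.poisson(mean, size=scenario.n_replicates)
            else:
                k = scenario.dispersion
                counts = rng.negative_binomial(
                    n=k, p=k / (k + mean), size=scenario.n_replicates
                )
            for rep, c in enumerate(counts, start=1):
                rows.append(
                    {
                        "cell_line": scenario.cell_line,
                        "modality": modality,
                        "dose_gy": float(r["dose_gy"]),
                        "n_seeded": int(r["n_seeded"]),
                        "replicate": rep,
                        "colonies": int(c),
                    }
                )
    return pd.DataFrame(rows)


def gen_spheroid_tracks(scenario: SpheroidScenario) -> pd.DataFrame:
    """Simulate longitudinal spheroid diameters, long form.

    Each spheroid draws a Gaussian baseline, grows (or shrinks) linearly at
    its condition's true slope, and every observation — including the
    baseline — carries Gaussian measurement noise. The control condition is
    emitted with modality ``CTRL`` at dose 0.
    """
    rng = np.random.default_rng(scenario.seed)
    conditions = [((CONTROL_MODALITY, 0.0), scenario.control_slope)]
    conditions += sorted(scenario.slopes_by_condition.items())
    times = np.asarray(scenario.times_h, dtype=float)
    rows = []
    for (modality, dose), slope in conditions:
        for i in range(scenario.n_spheroids):
            baseline = rng.normal(scenario.baseline_mean_um, scenario.baseline_sd_um)
            noise = (
                rng.normal(0.0, scenario.noise_sd_um, size=times.size)
                if scenario.noise_sd_um > 0
                else np.zeros(times.size)
            )
            diam = baseline + slope * times + noise
            sid = f"{scenario.cell_line}_{modality}_{dose:g}Gy_{i + 1:02d}"
            for t, dm in zip(times, diam):
                rows.append(
                    {
                        "spheroid_id": sid,
                        "cell_line": scenario.cell_line,
                        "modality": modality,
                        "dose_gy": float(dose),
                        "time_h": float(t),
                        "diameter_um": float(dm),
                    }
                )
    return pd.DataFrame(rows)


def gen_assay_plate(scenario: AssayScenario) -> pd.DataFrame:
    """Simulate well/field readouts with log-normal multiplicative noise.

    MTT emits OD570; PrestoBlue emits OD570 with a fixed OD600 reference and
    a size metric; invasion emits integer invaded-cell counts (Poisson-
    rounded around the noisy level). Output matches the ``assays.csv``
    schema.
    """
    rng = np.random.default_rng(scenario.seed)
    sigma = math.sqrt(math.log(1.0 + scenario.cv**2))
    rows = []
    for (modality, dose), level in sorted(scenario.levels_by_condition.items()):
        noisy = level * rng.lognormal(-0.5 * sigma**2, sigma, size=scenario.n_wells)
        for well, v in enumerate(noisy, start=1):
            row = {
                "assay": scenario.assay,
                "condition": f"{scenario.cell_line}_{modality}_{dose:g}Gy",
                "cell_line": scenario.cell_line,
                "modality": modality,
                "dose_gy": float(dose),
                "well_or_field": well,
                "od570": np.nan,
                "od600": np.nan,
                "count": np.nan,
                "size_metric": np.nan,
            }
            if scenario.assay == "mtt":
                row["od570"] = scenario.base_value * v
            elif scenario.assay == "presto":
                row["od570"] = scenario.base_value * v
                row["od600"] = 0.6
                row["size_metric"] = 1.0
            else:  # invasion: counts per field
                row["count"] = int(rng.poisson(100.0 * scenario.base_value * v))
            rows.append(row)
    return pd.DataFrame(rows)


def scenario_presets() -> dict:
    """Preset bundle parameterised from the published summary values.

    Returns a dict with the reconstructed LQ parameter pairs per
    (cell_line, modality), control plating efficiencies, the seeding plan,
    the per-condition spheroid slopes, control growth (slope and percent
    increment at 120 h for a 500 µm baseline), and the published 5-day
    viability / invasion tables usable as true assay levels.
    """
    control_growth = {
        cl: {
            "increment_percent": inc,
            "slope_um_per_h": DEFAULT_BASELINE_UM * (inc / 100.0) / 120.0,
        }
        for cl, inc in _CONTROL_INCREMENT.items()
    }
    return {
        "lq_params": _preset_lq_params(),
        "plating_efficiency": dict(_PE),
        "seeding": default_seeding_plan(),
        "spheroid_slopes": {
            (cl, mod, float(d)): s
            for (cl, mod), per_dose in _SPHEROID_SLOPES.items()
            for d, s in per_dose.items()
        },
        "control_growth": control_growth,
        "viability_5d_percent": {
            (cl, mod, float(d)): v for (cl, mod, d), v in _VIABILITY_5D.items()
        },
        "invasion_relative": {
            (cl, mod, float(d)): v for (cl, mod, d), v in _INVASION.items()
        },
    }


def preset_clonogenic_scenario(cell_line: str, seed: int = 0) -> ClonogenicScenario:
    """Published-value clonogenic scenario for one cell line."""
    presets = scenario_presets()
    return ClonogenicScenario(
        cell_line=cell_line,
        params_by_modality={
            mod: p for (cl, mod), p in presets["lq_params"].items() if cl == cell_line
        },
        pe_control=presets["plating_efficiency"][cell_line],
        seed=seed,
    )


def preset_spheroid_scenario(cell_line: str, seed: int = 0) -> SpheroidScenario:
    """Published-value spheroid scenario for one cell line."""
    presets = scenario_presets()
    return SpheroidScenario(
        cell_line=cell_line,
        control_slope=presets["control_growth"][cell_line]["slope_um_per_h"],
        slopes_by_condition={
            (mod, d): s
            for (cl, mod, d), s in presets["spheroid_slopes"].items()
            if cl == cell_line
        },
        seed=seed,
    )


def preset_assay_scenarios(cell_line: str, seed: int = 0) -> list[AssayScenario]:
    """Published-value MTT and invasion scenarios for one cell line."""
    presets = scenario_presets()
    out = []
    mtt_levels = {
        (mod, d): v / 100.0
        for (cl, mod, d), v in presets["viability_5d_percent"].items()
        if cl == cell_line
    }
    if mtt_levels:
        out.append(
            AssayScenario(
                assay="mtt", cell_line=cell_line, levels_by_condition=mtt_levels,
                n_wells=6, seed=seed,
            )
        )
    inv_levels = {
        (mod, d): v
        for (cl, mod, d), v in presets["invasion_relative"].items()
        if cl == cell_line
    }
    if inv_levels:
        out.append(
            AssayScenario(
                assay="invasion", cell_line=cell_line,
                levels_by_condition=inv_levels, n_wells=5, seed=seed + 1,
            )
        )
    return out
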