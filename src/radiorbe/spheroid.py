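"""Spheroid growth pipeline: longitudinal diameters -> growth rates -> 3D RBE.

Stage 2 of the analysis. A :class:`SpheroidTrack` holds one spheroid's
diameter time series (µm vs hours, baseline at time 0 before irradiation).
Per-spheroid growth rates are estimated either as the endpoint difference

    (final diameter - initial diameter) / elapsed time

or as the ordinary-least-squares slope of diameter on time; the two coincide
exactly on linear tracks and on any 2-point track. Per-condition summaries
average per-spheroid slopes (not a pooled regression), so the spread across
spheroids yields an SD.

Radiation effect is expressed as growth inhibition relative to the
unirradiated control,

    inhibition = 1 - rate_irradiated / rate_control,

which is 0 for no effect, 1 for complete growth arrest, and exceeds 1 when
spheroids shrink. Per-modality (dose, inhibition) points form a monotone
piecewise-linear :class:`DoseEffectCurve`; the 3D RBE at an effect level is
the ratio of the reference-modality dose to the test-modality dose producing
that same inhibition, found by inverse interpolation. Non-monotone curves are
flagged, never silently repaired; extrapolation beyond the measured dose
range is off by default and flagged whenever used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UnattainableEffectError, ValidationError

__all__ = [
    "SpheroidTrack",
    "GrowthSummary",
    "DoseEffectCurve",
    "RBE3DResult",
    "growth_rate_endpoint",
    "growth_rate_regression",
    "growth_increment_percent",
    "aggregate_condition",
    "growth_inhibition",
    "dose_effect_curve",
    "rbe_3d",
    "rbe_3d_sweep",
    "tracks_from_table",
    "analyze_spheroids",
    "SPHEROID_COLUMNS",
]

#: Required columns of the long-form spheroid-diameter table.
SPHEROID_COLUMNS = [
    "spheroid_id", "cell_line", "modality", "dose_gy", "time_h", "diameter_um",
]

SLOPE_METHODS = ("regression", "endpoint")


@dataclass(frozen=True)
class SpheroidTrack:
    """One spheroid's diameter time series.

    ``times_h`` must be strictly increasing starting at the pre-irradiation
    baseline (0 h) with at least two observations; diameters are in µm and
    must be positive.
    """

    spheroid_id: str
    cell_line: str
    modality: str
    dose_gy: float
    times_h: np.ndarray
    diameters_um: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        d = np.asarray(self.diameters_um, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "diameters_um", d)
        if t.shape != d.shape or t.ndim != 1 or t.size < 2:
            raise InputError(
                "a track needs matching 1-d time/diameter arrays with >= 2 points"
            )
        if not np.all(np.diff(t) > 0):
            raise InputError("observation times must be strictly increasing")
        if t[0] != 0.0:
            raise InputError(
                f"first observation must be the time-0 baseline, got t0={t[0]}"
            )
        if np.any(d <= 0):
            raise InputError("diameters must be positive")


@dataclass(frozen=True)
class GrowthSummary:
    """Per-condition growth-rate summary across spheroids.

    ``slope_um_per_h`` is the mean per-spheroid slope under the tagged
    ``method``; ``slope_sd`` the across-spheroid SD (0 for a single track).
    """

    cell_line: str
    modality: str
    dose_gy: float
    method: str
    slope_um_per_h: float
    slope_sd: float
    intercept_um: float
    r_squared: float
    increment_percent: float
    n_spheroids: int


@dataclass(frozen=True)
class RBE3DResult:
    """Iso-effect dose ratio between two dose-effect curves.

    ``extrapolation_flag`` is set when either dose had to be read outside the
    measured dose range of its curve.
    """

    reference_modality: str
    test_modality: str
    effect_level: float
    dose_reference: float
    dose_test: float
    rbe: float
    extrapolation_flag: bool = False


class DoseEffectCurve:
    """Monotone piecewise-linear dose -> growth-inhibition mapping.

    Always anchored at (0 Gy, inhibition 0) — the control inhibits itself by
    definition. ``monotone`` reports whether the measured inhibitions are
    non-decreasing in dose; inverse interpolation refuses non-monotone
    curves unless they were monotonised (pooled-adjacent-violators averaging,
    opt-in and recorded in ``monotonised``).
    """

    def __init__(
        self,
        modality: str,
        doses_gy,
        inhibitions,
        monotonised: bool = False,
    ) -> None:
        d = np.asarray(doses_gy, dtype=float)
        y = np.asarray(inhibitions, dtype=float)
        if d.shape != y.shape or d.ndim != 1 or d.size < 1:
            raise InputError("doses and inhibitions must be matching 1-d arrays")
        order = np.argsort(d)
        d, y = d[order], y[order]
        if np.any(np.diff(d) <= 0):
            raise InputError("doses must be distinct")
        if d[0] != 0.0:
            d = np.concatenate([[0.0], d])
            y = np.concatenate([[0.0], y])
        elif y[0] != 0.0:
            raise InputError("inhibition at dose 0 must be 0 by definition")
        self.modality = str(modality)
        self.doses_gy = d
        self.inhibitions = y
        self.monotonised = bool(monotonised)

    @property
    def monotone(self) -> bool:
        return bool(np.all(np.diff(self.inhibitions) >= 0))

    @property
    def max_effect(self) -> float:
        return float(np.max(self.inhibitions))

    def monotonise(self) -> "DoseEffectCurve":
        """Pooled-adjacent-violators (isotonic) repair of the inhibitions."""
        y = self.inhibitions.copy()
        # classic PAVA over the dose-ordered values, equal weights
        n = len(y)
        vals = list(y)
        wts = [1.0] * n
        blocks = [[i] for i in range(n)]
        i = 0
        while i < len(vals) - 1:
            if vals[i] > vals[i + 1]:
                merged = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / (
                    wts[i] + wts[i + 1]
                )
                vals[i] = merged
                wts[i] += wts[i + 1]
                blocks[i].extend(blocks[i + 1])
                del vals[i + 1], wts[i + 1], blocks[i + 1]
                i = max(i - 1, 0)
            else:
                i += 1
        out = np.empty(n)
        for v, idxs in zip(vals, blocks):
            out[list(idxs)] = v
        out[0] = 0.0  # the dose-0 anchor stays exact
        return DoseEffectCurve(self.modality, self.doses_gy, out, monotonised=True)

    def effect_at_dose(self, dose: float, extrapolate: bool = False) -> float:
        if dose < 0:
            raise InputError("dose must be >= 0")
        if dose > self.doses_gy[-1] and not extrapolate:
            raise UnattainableEffectError(
                f"dose {dose} Gy beyond measured range of {self.modality} "
                f"(max {self.doses_gy[-1]} Gy) and extrapolation is disabled"
            )
        # linear continuation of the last segment when extrapolating
        if dose > self.doses_gy[-1]:
            d0, d1 = self.doses_gy[-2:]
            y0, y1 = self.inhibitions[-2:]
            return float(y1 + (dose - d1) * (y1 - y0) / (d1 - d0))
        return float(np.interp(dose, self.doses_gy, self.inhibitions))

    def dose_at_effect(self, level: float, extrapolate: bool = False) -> tuple[float, bool]:
        """Inverse interpolation: smallest dose reaching ``level``.

        Returns ``(dose, extrapolated)``. Requires a monotone curve.
        """
        if level < 0:
            raise InputError("effect level must be >= 0")
        if not self.monotone:
            raise ValidationError(
                f"{self.modality} dose-effect curve is not monotone; "
                "monotonise() explicitly before inverse interpolation"
            )
        if level == 0.0:
            return 0.0, False
        if level > self.max_effect:
            if not extrapolate:
                raise UnattainableEffectError(
                    f"effect level {level} exceeds the maximum measured "
                    f"inhibition {self.max_effect:.4g} of {self.modality} and "
                    "extrapolation is disabled"
                )
            d0, d1 = self.doses_gy[-2:]
            y0, y1 = self.inhibitions[-2:]
            if y1 <= y0:
                raise UnattainableEffectError(
                    f"{self.modality} curve is flat at its upper end; level "
                    f"{level} cannot be extrapolated"
                )
            return float(d1 + (level - y1) * (d1 - d0) / (y1 - y0)), True
        # np.interp needs strictly-increasing x; walk segments for flat runs
        idx = int(np.searchsorted(self.inhibitions, level, side="left"))
        y0, y1 = self.inhibitions[idx - 1], self.inhibitions[idx]
        d0, d1 = self.doses_gy[idx - 1], self.doses_gy[idx]
        if y1 == y0:
            return float(d0), False
        return float(d0 + (level - y0) * (d1 - d0) / (y1 - y0)), False


def growth_rate_endpoint(track: SpheroidTrack) -> float:
    """Endpoint growth rate, µm/h: diameter change over elapsed time."""
    dt = track.times_h[-1] - track.times_h[0]
    if dt <= 0:
        raise InputError("zero observation interval")
    return float((track.diameters_um[-1] - track.diameters_um[0]) / dt)


def growth_rate_regression(track: SpheroidTrack) -> tuple[float, float, float]:
    """OLS slope of diameter on time: (slope µm/h, intercept µm, R^2).

    A perfectly flat track has zero slope and, by convention, R^2 = 1 (the
    line reproduces every observation exactly).
    """
    t, d = track.times_h, track.diameters_um
    if t.size == 2:
        slope = growth_rate_endpoint(track)
        return slope, float(d[0]), 1.0
    res = stats.linregress(t, d)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    return float(res.slope), float(res.intercept), r2


def growth_increment_percent(track: SpheroidTrack) -> float:
    """Diameter change at the final time point relative to baseline, percent."""
    d0, d1 = track.diameters_um[0], track.diameters_um[-1]
    return float(100.0 * (d1 - d0) / d0)


def aggregate_condition(
    tracks: list[SpheroidTrack], method: str = "regression"
) -> GrowthSummary:
    """Average per-spheroid growth rates within one (cell line, modality, dose).

    Per-spheroid slopes are computed first and then averaged, so ``slope_sd``
    is the biological spread across spheroids; mixing conditions raises
    :class:`InputError`.
    """
    if not tracks:
        raise InputError("at least one track required")
    if method not in SLOPE_METHODS:
        raise InputError(f"method must be one of {SLOPE_METHODS}, got {method!r}")
    keys = {(t.cell_line, t.modality, t.dose_gy) for t in tracks}
    if len(keys) > 1:
        raise InputError(f"tracks mix conditions: {sorted(keys)}")
    if method == "endpoint":
        slopes = [growth_rate_endpoint(t) for t in tracks]
        intercepts = [float(t.diameters_um[0]) for t in tracks]
        r2s = [1.0] * len(tracks)
    else:
        fits = [growth_rate_regression(t) for t in tracks]
        slopes = [f[0] for f in fits]
        intercepts = [f[1] for f in fits]
        r2s = [f[2] for f in fits]
    slopes_arr = np.asarray(slopes)
    cell_line, modality, dose = next(iter(keys))
    return GrowthSummary(
        cell_line=cell_line,
        modality=modality,
        dose_gy=float(dose),
        method=method,
        slope_um_per_h=float(slopes_arr.mean()),
        slope_sd=float(slopes_arr.std(ddof=1)) if len(slopes) > 1 else 0.0,
        intercept_um=float(np.mean(intercepts)),
        r_squared=float(np.mean(r2s)),
        increment_percent=float(
            np.mean([growth_increment_percent(t) for t in tracks])
        ),
        n_spheroids=len(tracks),
    )


def growth_inhibition(rate_irradiated: float, rate_control: float) -> float:
    """Growth inhibition relative to control: 1 - irradiated/control rate.

    Values above 1 indicate net shrinkage. The control must be growing
    (positive rate) for the normalisation to be meaningful.
    """
    if not (rate_control > 0.0):
        raise InputError(
            f"control growth rate must be positive, got {rate_control!r}"
        )
    return 1.0 - rate_irradiated / rate_control


def dose_effect_curve(
    summaries: list[GrowthSummary],
    control: GrowthSummary,
    monotonise: bool = False,
) -> DoseEffectCurve:
    """Assemble per-dose inhibitions (plus the (0, 0) anchor) into a curve.

    ``control`` is the 0 Gy summary of the same cell line and modality arm.
    A non-monotone result is returned flagged (``curve.monotone`` False)
    unless ``monotonise=True`` requests the isotonic repair.
    """
    if not summaries:
        raise InputError("at least one irradiated-dose summary required")
    if control.dose_gy != 0.0:
        raise InputError(f"control summary must be at 0 Gy, got {control.dose_gy}")
    modalities = {s.modality for s in summaries}
    if len(modalities) > 1:
        raise InputError(f"summaries mix modalities: {sorted(modalities)}")
    doses = [s.dose_gy for s in summaries]
    inhib = [
        growth_inhibition(s.slope_um_per_h, control.slope_um_per_h)
        for s in summaries
    ]
    curve = DoseEffectCurve(next(iter(modalities)), doses, inhib)
    if monotonise and not curve.monotone:
        curve = curve.monotonise()
    return curve


def rbe_3d(
    reference: DoseEffectCurve,
    test: DoseEffectCurve,
    effect_level: float,
    extrapolate: bool = False,
) -> RBE3DResult:
    """3D RBE: reference dose over test dose at equal growth inhibition."""
    if not (effect_level > 0.0):
        raise InputError(f"effect_level must be > 0, got {effect_level!r}")
    dose_ref, ex_ref = reference.dose_at_effect(effect_level, extrapolate=extrapolate)
    dose_test, ex_test = test.dose_at_effect(effect_level, extrapolate=extrapolate)
    if dose_test <= 0.0:
        raise UnattainableEffectError(
            f"test curve {test.modality!r} reaches level {effect_level} at "
            "zero dose; iso-effect ratio undefined"
        )
    return RBE3DResult(
        reference_modality=reference.modality,
        test_modality=test.modality,
        effect_level=effect_level,
        dose_reference=dose_ref,
        dose_test=dose_test,
        rbe=dose_ref / dose_test,
        extrapolation_flag=ex_ref or ex_test,
    )


def rbe_3d_sweep(
    reference: DoseEffectCurve,
    test: DoseEffectCurve,
    n_levels: int = 21,
) -> pd.DataFrame:
    """RBE over a grid of effect levels spanning the common attainable range.

    The grid covers (0, min(max effect of the two curves)] exclusive of 0;
    one row per level with the interpolated doses and the ratio.
    """
    top = min(reference.max_effect, test.max_effect)
    if top <= 0:
        raise UnattainableEffectError(
            "curves share no positive attainable effect range"
        )
    levels = np.linspace(0.0, top, n_levels + 1)[1:]
    rows = []
    for lv in levels:
        r = rbe_3d(reference, test, float(lv))
        rows.append(
            {
                "effect_level": r.effect_level,
                "dose_reference_gy": r.dose_reference,
                "dose_test_gy": r.dose_test,
                "rbe": r.rbe,
                "reference_modality": r.reference_modality,
                "test_modality": r.test_modality,
            }
        )
    return pd.DataFrame(rows)


def tracks_from_table(table: pd.DataFrame) -> list[SpheroidTrack]:
    """Long-form (spheroid_id, ..., time_h, diameter_um) table -> tracks."""
    missing = [c for c in SPHEROID_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"spheroid table is missing columns: {missing}")
    if len(table) == 0:
        raise ValidationError("spheroid table is empty")
    tracks = []
    keys = ["spheroid_id", "cell_line", "modality", "dose_gy"]
    for (sid, cl, mod, dose), grp in table.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        tracks.append(
            SpheroidTrack(
                spheroid_id=str(sid),
                cell_line=str(cl),
                modality=str(mod),
                dose_gy=float(dose),
                times_h=grp["time_h"].to_numpy(dtype=float),
                diameters_um=grp["diameter_um"].to_numpy(dtype=float),
            )
        )
    return tracks


def analyze_spheroids(
    table: pd.DataFrame,
    method: str = "regression",
    reference_modality: str = "XRT",
    control_modality: str = "CTRL",
    monotonise: bool = False,
    sweep_levels: int = 21,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """End-to-end stage 2: spheroid table -> (summaries, dose-effect, RBE sweep).

    Unirradiated controls are the ``dose == 0`` tracks; their modality label
    is ``control_modality`` when present, otherwise each modality's own 0 Gy
    arm. Returns three tidy tables: per-condition growth summaries, the
    per-modality dose-effect points, and the RBE level sweep of every
    non-reference modality against ``reference_modality``.
    """
    tracks = tracks_from_table(table)
    by_cond: dict[tuple[str, str, float], list[SpheroidTrack]] = {}
    for t in tracks:
        by_cond.setdefault((t.cell_line, t.modality, t.dose_gy), []).append(t)
    summaries = {
        key: aggregate_condition(ts, method=method) for key, ts in by_cond.items()
    }
    summary_df = pd.DataFrame(
        [
            {
                "cell_line": s.cell_line,
                "modality": s.modality,
                "dose_gy": s.dose_gy,
                "method": s.method,
                "slope_um_per_h": s.slope_um_per_h,
                "slope_sd": s.slope_sd,
                "intercept_um": s.intercept_um,
                "r_squared": s.r_squared,
                "increment_percent": s.increment_percent,
                "n_spheroids": s.n_spheroids,
            }
            for s in sorted(
                summaries.values(), key=lambda s: (s.cell_line, s.modality, s.dose_gy)
            )
        ]
    )

    cell_lines = sorted({cl for cl, _, _ in summaries})
    curve_rows, sweep_frames = [], []
    for cl in cell_lines:
        def control_for(modality: str) -> GrowthSummary | None:
            return summaries.get((cl, control_modality, 0.0)) or summaries.get(
                (cl, modality, 0.0)
            )

        modalities = sorted(
            {m for c, m, d in summaries if c == cl and m != control_modality and d > 0}
        )
        curves: dict[str, DoseEffectCurve] = {}
        for mod in modalities:
            ctrl = control_for(mod)
            if ctrl is None:
                raise ValidationError(
                    f"no 0 Gy control tracks for cell line {cl!r} (modality {mod!r})"
                )
            per_dose = [
                s
                for (c, m, d), s in summaries.items()
                if c == cl and m == mod and d > 0
            ]
            curve = dose_effect_curve(per_dose, ctrl, monotonise=monotonise)
            curves[mod] = curve
            for d, y in zip(curve.doses_gy, curve.inhibitions):
                curve_rows.append(
                    {
                        "cell_line": cl,
                        "modality": mod,
                        "dose_gy": d,
                        "inhibition": y,
                        "monotone": curve.monotone,
                        "monotonised": curve.monotonised,
                    }
                )
        if reference_modality in curves:
            ref = curves[reference_modality]
            for mod, curve in curves.items():
                if mod == reference_modality:
                    continue
                if not (ref.monotone and curve.monotone):
                    continue  # flagged in dose_effect table; no silent repair
                sw = rbe_3d_sweep(ref, curve, n_levels=sweep_levels)
                sw.insert(0, "cell_line", cl)
                sweep_frames.append(sw)
    dose_effect_df = pd.DataFrame(curve_rows)
    rbe_df = (
        pd.concat(sweep_frames, ignore_index=True)
        if sweep_frames
        else pd.DataFrame(
            columns=[
                "cell_line", "effect_level", "dose_reference_gy",
                "dose_test_gy", "rbe", "reference_modality", "test_modality",
            ]
        )
    )
    return summary_df, dose_effect_df, rbe_df
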