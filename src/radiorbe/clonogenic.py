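"""Clonogenic survival pipeline: colony counts -> surviving fractions -> LQ fits.

Stage 1 of the analysis. Input is a long-form table of replicate colony
counts per (cell_line, modality, dose, n_seeded); output is a table of
surviving fractions with standard errors, one fitted LQ curve per
(cell_line, modality), and a summary table of D10 / SF2 / alpha-beta ratio /
RBE against a reference modality.

Conventions
-----------
* Plating efficiency (PE) is the mean replicate colony count divided by the
  number of cells seeded; the surviving fraction (SF) is treated PE over the
  unirradiated (0 Gy) control PE of the same cell line and modality.
* The LQ model is linear in (D, D^2) on the log-survival scale with no
  intercept (SF(0) = 1 by construction), so the fit is a bounded weighted
  linear least squares: minimise sum w_i * (ln SF_i + alpha*D_i + beta*D_i^2)^2
  subject to alpha >= 0, beta >= 0.
* Standard errors of SF are propagated by the delta method from the replicate
  spread of treated counts and of the control PE.
* A dose at which every replicate yields zero colonies has no defined log
  survival; the point is excluded from the fit and flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import lsq_linear

from .errors import InsufficientDataError, InputError, ValidationError
from .lq import LQMetrics, LQParams, d_iso, metrics_from_params, rbe_at_effect

__all__ = [
    "PlatingEfficiency",
    "SurvivalCurveFit",
    "plating_efficiency",
    "surviving_fraction",
    "build_survival_points",
    "fit_lq",
    "survival_summary",
    "analyze_colonies",
    "COLONY_COLUMNS",
]

#: Required columns of the long-form colony-count table.
COLONY_COLUMNS = ["cell_line", "modality", "dose_gy", "n_seeded", "replicate", "colonies"]

WEIGHTING_SCHEMES = ("gls", "poisson", "delta", "unweighted")


@dataclass(frozen=True)
class PlatingEfficiency:
    """Mean colony-forming fraction of one plating condition.

    ``degenerate`` is set when every replicate produced zero colonies, in
    which case ``pe = 0`` and no log-scale quantity is defined downstream.
    """

    pe: float
    replicate_sd: float
    n_replicates: int
    degenerate: bool = False


@dataclass
class SurvivalCurveFit:
    """A fitted LQ survival curve with its uncertainty and derived metrics."""

    params: LQParams
    covariance: np.ndarray  # 2x2, order (alpha, beta)
    metrics: LQMetrics
    points: pd.DataFrame
    weighting: str
    rss: float
    dof: int
    at_bound: tuple[bool, bool] = (False, False)
    convergence_warning: bool = False
    label: tuple[str, str] | None = None  # (cell_line, modality)

    @property
    def alpha_se(self) -> float:
        return float(math.sqrt(max(self.covariance[0, 0], 0.0)))

    @property
    def beta_se(self) -> float:
        return float(math.sqrt(max(self.covariance[1, 1], 0.0)))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """Normal-approximation confidence intervals for (alpha, beta)."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        est = np.array([self.params.alpha, self.params.beta])
        se = np.array([self.alpha_se, self.beta_se])
        return np.column_stack([est - z * se, est + z * se])


def plating_efficiency(colonies, n_seeded: int) -> PlatingEfficiency:
    """Plating efficiency: mean replicate colony count over cells seeded.

    Also returns the replicate standard deviation (ddof=1; zero for a single
    replicate) so downstream error propagation can use the observed spread.
    """
    counts = np.asarray(colonies, dtype=float)
    if counts.size < 1:
        raise InputError("at least one replicate colony count required")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise InputError(f"colony counts must be non-negative integers, got {colonies!r}")
    if n_seeded < 1:
        raise InputError(f"n_seeded must be >= 1, got {n_seeded!r}")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return PlatingEfficiency(
        pe=mean / n_seeded,
        replicate_sd=sd,
        n_replicates=int(counts.size),
        degenerate=(mean == 0.0),
    )


def surviving_fraction(pe_treated: float, pe_control: float) -> float:
    """Surviving fraction: treated PE divided by control PE (fraction scale)."""
    if not (pe_control > 0.0):
        raise InputError(
            f"control plating efficiency must be positive, got {pe_control!r}"
        )
    if pe_treated < 0.0:
        raise InputError(f"treated plating efficiency must be >= 0, got {pe_treated!r}")
    return pe_treated / pe_control


def _validate_colony_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLONY_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"colony table is missing columns: {missing}")
    if len(records) == 0:
        raise ValidationError("colony table is empty")
    dup = records.duplicated(subset=["cell_line", "modality", "dose_gy", "replicate"])
    if dup.any():
        keys = records.loc[dup, ["cell_line", "modality", "dose_gy", "replicate"]]
        raise ValidationError(
            f"duplicate (cell_line, modality, dose, replicate) rows: "
            f"{keys.to_records(index=False).tolist()}"
        )
    return records


def build_survival_points(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate colony counts into per-dose surviving fractions.

    For each (cell_line, modality) the 0 Gy rows define the control PE; each
    treated dose is joined to that control. The returned table has one row
    per (cell_line, modality, dose) — including the dose-0 anchor at
    ``sf = 1`` exactly — with columns ``sf``, ``se`` (delta-method standard
    error), ``n_replicates``, ``total_colonies`` and ``zero_count``.

    Raises :class:`ValidationError` when a (cell_line, modality) group lacks
    its unirradiated control, listing the missing keys.
    """
    records = _validate_colony_table(records)
    grouped = (
        records.groupby(["cell_line", "modality", "dose_gy"], sort=True)
        .agg(
            n_seeded=("n_seeded", "first"),
            mean_colonies=("colonies", "mean"),
            sd_colonies=("colonies", lambda c: c.std(ddof=1) if len(c) > 1 else 0.0),
            total_colonies=("colonies", "sum"),
            n_replicates=("colonies", "size"),
        )
        .reset_index()
    )
    missing_controls = []
    rows = []
    for (cell_line, modality), grp in grouped.groupby(["cell_line", "modality"]):
        ctrl = grp[grp["dose_gy"] == 0.0]
        if len(ctrl) == 0:
            missing_controls.append((cell_line, modality))
            continue
        ctrl = ctrl.iloc[0]
        pe_c = ctrl["mean_colonies"] / ctrl["n_seeded"]
        if pe_c <= 0:
            raise ValidationError(
                f"control PE is zero for ({cell_line}, {modality}); "
                "surviving fractions undefined"
            )
        # relative SE of the control mean, shared by every dose in the group
        rel_se_c = (
            ctrl["sd_colonies"] / math.sqrt(ctrl["n_replicates"])
        ) / ctrl["mean_colonies"]
        for _, row in grp.iterrows():
            dose = row["dose_gy"]
            if dose == 0.0:
                sf, se, zero = 1.0, 0.0, False
            else:
                pe_t = row["mean_colonies"] / row["n_seeded"]
                sf = surviving_fraction(pe_t, pe_c)
                zero = row["mean_colonies"] == 0.0
                if zero:
                    se = 0.0
                else:
                    rel_se_t = (
                        row["sd_colonies"] / math.sqrt(row["n_replicates"])
                    ) / row["mean_colonies"]
                    se = sf * math.sqrt(rel_se_t**2 + rel_se_c**2)
            rows.append(
                {
                    "cell_line": cell_line,
                    "modality": modality,
                    "dose_gy": dose,
                    "sf": sf,
                    "se": se,
                    "n_replicates": int(row["n_replicates"]),
                    "total_colonies": int(row["total_colonies"]),
                    "control_total_colonies": int(ctrl["total_colonies"]),
                    "zero_count": zero,
                }
            )
    if missing_controls:
        raise ValidationError(
            f"missing 0 Gy control rows for: {missing_controls}"
        )
    return pd.DataFrame(rows)


def _fit_weights(pts: pd.DataFrame, weighting: str) -> np.ndarray:
    """Weights for the log-survival regression (1/Var[ln SF])."""
    if weighting == "unweighted":
        return np.ones(len(pts))
    if weighting == "delta":
        # Var(ln SF) ~ (se/sf)^2 from the replicate-spread delta method
        rel = (pts["se"] / pts["sf"]).to_numpy(dtype=float)
        if np.any(rel <= 0):
            # noiseless or single-replicate input: no spread to weight by
            return np.ones(len(pts))
        return 1.0 / rel**2
    if weighting == "poisson":
        # model-based: Var(ln SF) ~ 1/sum(treated counts) + 1/sum(control counts)
        var = (
            1.0 / pts["total_colonies"].to_numpy(dtype=float)
            + 1.0 / pts["control_total_colonies"].to_numpy(dtype=float)
        )
        return 1.0 / var
    raise InputError(
        f"unknown weighting {weighting!r}; choose one of {WEIGHTING_SCHEMES}"
    )


def fit_lq(points: pd.DataFrame, weighting: str = "gls") -> SurvivalCurveFit:
    """Fit the LQ model to one modality's surviving fractions.

    Bounded (alpha >= 0, beta >= 0) least squares of -ln SF on (D, D^2) with
    no intercept: the dose-0 anchor is exact by construction and zero-count
    points are excluded (their log survival is undefined).

    ``weighting`` selects the error model:

    * ``"gls"`` (default) — generalised least squares under the Poisson
      counting model. Because every dose shares the same 0 Gy control, log
      survivals are correlated: ``Cov(ln SF_i, ln SF_j) = delta_ij / T_i +
      1 / T_c`` with ``T`` the summed colony counts. The full covariance is
      inverted exactly, which is what makes the nominal confidence intervals
      calibrated.
    * ``"poisson"`` — diagonal approximation of the same model.
    * ``"delta"`` — weights 1/se^2 from the replicate-spread delta method.
    * ``"unweighted"`` — OLS with residual-rescaled covariance.

    The parameter covariance is the known-variance form ``(X' W X)^-1``
    except for ``"unweighted"``.
    """
    required = {"dose_gy", "sf"}
    if not required.issubset(points.columns):
        raise ValidationError(
            f"points table needs columns {sorted(required)}, got {list(points.columns)}"
        )
    usable = points[(points["dose_gy"] > 0) & (points["sf"] > 0)].copy()
    if "zero_count" in usable.columns:
        usable = usable[~usable["zero_count"].astype(bool)]
    n_doses = usable["dose_gy"].nunique()
    if n_doses < 3:
        raise InsufficientDataError(
            f"LQ fit needs >= 3 distinct positive doses with nonzero survival, "
            f"got {n_doses}"
        )
    count_cols = {"total_colonies", "control_total_colonies"}
    needs = {"delta": {"se"}, "poisson": count_cols, "gls": count_cols}
    if weighting in needs and not needs[weighting].issubset(points.columns):
        # hand-built points without uncertainty columns: fall back gracefully
        weighting = "unweighted"

    d = usable["dose_gy"].to_numpy(dtype=float)
    y = -np.log(usable["sf"].to_numpy(dtype=float))
    x = np.column_stack([d, d * d])

    if weighting == "gls":
        t_treated = usable["total_colonies"].to_numpy(dtype=float)
        t_control = float(usable["control_total_colonies"].iloc[0])
        sigma = np.full((len(d), len(d)), 1.0 / t_control)
        sigma[np.diag_indices_from(sigma)] += 1.0 / t_treated
        sigma_inv = np.linalg.inv(sigma)
        whitener = np.linalg.cholesky(sigma_inv).T
        res = lsq_linear(whitener @ x, whitener @ y, bounds=(0.0, np.inf))
        xtwx = x.T @ sigma_inv @ x
        resid = y - x @ res.x
        rss = float(resid @ sigma_inv @ resid)
    else:
        w = _fit_weights(usable, weighting)
        sw = np.sqrt(w)
        res = lsq_linear(x * sw[:, None], y * sw, bounds=(0.0, np.inf))
        xtwx = x.T @ (w[:, None] * x)
        resid = y - x @ res.x
        rss = float(np.sum(w * resid**2))

    alpha, beta = (float(v) for v in res.x)
    # snap bound-pinned coefficients to exact zero so downstream metrics
    # report an explicit undefined alpha/beta ratio instead of 1e16-type noise
    at_bound = (alpha <= 1e-12, beta <= 1e-12)
    alpha = 0.0 if at_bound[0] else alpha
    beta = 0.0 if at_bound[1] else beta
    dof = len(d) - 2

    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    if weighting == "unweighted" and dof > 0:
        cov = cov * (rss / dof)

    convergence_warning = all(at_bound) and rss > 1e-10
    if convergence_warning:
        warnings.warn(
            "LQ fit pinned both coefficients at the zero bound with "
            "non-trivial residuals; survival data may be increasing in dose",
            stacklevel=2,
        )
    params = LQParams(alpha=max(alpha, 0.0), beta=max(beta, 0.0))
    return SurvivalCurveFit(
        params=params,
        covariance=cov,
        metrics=metrics_from_params(params),
        points=points.reset_index(drop=True),
        weighting=weighting,
        rss=rss,
        dof=dof,
        at_bound=at_bound,
        convergence_warning=convergence_warning,
    )


def survival_summary(
    fits: dict[tuple[str, str], SurvivalCurveFit],
    reference_modality: str = "XRT",
    effect_level: float = 0.10,
    include_reference_rbe: bool = True,
) -> pd.DataFrame:
    """Summary table of D10 / SF2 / alpha-beta ratio / RBE per curve.

    ``fits`` is keyed by (cell_line, modality). RBE compares each modality to
    ``reference_modality`` within the same cell line at the configured
    survival level (default: the D10 level). The reference's RBE against
    itself is 1.0 and is included or omitted per ``include_reference_rbe``.
    """
    cell_lines = sorted({cl for cl, _ in fits})
    missing_ref = [
        cl for cl in cell_lines if (cl, reference_modality) not in fits
    ]
    if missing_ref:
        raise ValidationError(
            f"reference modality {reference_modality!r} not fitted for cell "
            f"lines: {missing_ref}"
        )
    rows = []
    for (cell_line, modality), fit in sorted(fits.items()):
        ref_fit = fits[(cell_line, reference_modality)]
        m = fit.metrics
        if modality == reference_modality and not include_reference_rbe:
            rbe = np.nan
        else:
            rbe = rbe_at_effect(
                ref_fit.params,
                fit.params,
                survival_level=effect_level,
                reference_label=reference_modality,
                test_label=modality,
            ).rbe
        rows.append(
            {
                "cell_line": cell_line,
                "modality": modality,
                "alpha": fit.params.alpha,
                "beta": fit.params.beta,
                "alpha_se": fit.alpha_se,
                "beta_se": fit.beta_se,
                "d10_gy": m.d10,
                "sf2": m.sf2,
                "alpha_beta_ratio": m.alpha_beta_ratio,
                "rbe": rbe,
                "rbe_effect_level": effect_level,
                "reference_modality": reference_modality,
            }
        )
    return pd.DataFrame(rows)


def analyze_colonies(
    records: pd.DataFrame,
    reference_modality: str = "XRT",
    weighting: str = "poisson",
    effect_level: float = 0.10,
) -> tuple[pd.DataFrame, dict[tuple[str, str], SurvivalCurveFit], pd.DataFrame]:
    """End-to-end stage 1: colony table -> (points, fits, summary)."""
    points = build_survival_points(records)
    fits: dict[tuple[str, str], SurvivalCurveFit] = {}
    for (cell_line, modality), grp in points.groupby(["cell_line", "modality"]):
        fit = fit_lq(grp, weighting=weighting)
        fit.label = (str(cell_line), str(modality))
        fits[(str(cell_line), str(modality))] = fit
    summary = survival_summary(
        fits, reference_modality=reference_modality, effect_level=effect_level
    )
    return points, fits, summary
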