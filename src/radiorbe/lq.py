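"""Closed-form linear-quadratic (LQ) survival mathematics.

The LQ model describes the clonogenically surviving fraction after a single
acute absorbed dose ``D`` (Gy) as

.. math::

    \\mathrm{SF}(D) = \\exp(-\\alpha D - \\beta D^2)

with a linear kill coefficient ``alpha`` (Gy^-1) and a quadratic coefficient
``beta`` (Gy^-2). Everything a clonogenic report quotes derives from this pair:

* ``D10`` — the dose reducing survival to 10%, the positive root of
  ``beta*D**2 + alpha*D + ln(0.10) = 0``;
* ``SF2`` — the surviving fraction at 2 Gy, a conventional intrinsic
  radiosensitivity marker;
* the ``alpha/beta`` ratio (Gy) — the dose at which linear and quadratic kill
  contribute equally;
* RBE — the ratio of reference-radiation dose to test-radiation dose
  producing the same survival level (by convention the 10% level).

This module also provides the inverse reconstructions: given a printed
``(D10, alpha/beta)`` or ``(SF2, alpha/beta)`` summary pair, recover the
unique non-negative ``(alpha, beta)`` consistent with it. Survival is held as
a fraction in ``(0, 1]`` throughout; percent scales are a presentation concern
left to reporting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, UnattainableEffectError

__all__ = [
    "LQParams",
    "LQMetrics",
    "RBEResult",
    "sf_at_dose",
    "d_iso",
    "params_from_d10_ratio",
    "params_from_sf2_ratio",
    "params_from_two_survival_points",
    "metrics_from_params",
    "rbe_at_effect",
]

_LN10 = math.log(10.0)

#: Below this, beta is treated as exactly zero so that the quadratic-root
#: formula never divides by a vanishing denominator.
BETA_LINEAR_THRESHOLD = 1e-12


@dataclass(frozen=True)
class LQParams:
    """The (alpha, beta) pair defining one LQ survival curve.

    Parameters
    ----------
    alpha : float
        Linear kill coefficient, Gy^-1. Must be >= 0.
    beta : float
        Quadratic kill coefficient, Gy^-2. Must be >= 0.

    ``alpha = beta = 0`` is permitted and represents an explicit "no-kill"
    curve (survival 1 at every dose); iso-effect queries on it below
    survival 1 raise :class:`UnattainableEffectError`.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        # `not >= 0` also rejects NaN
        if not (self.alpha >= 0.0) or not (self.beta >= 0.0):
            raise InputError(
                f"LQ coefficients must be non-negative, got "
                f"alpha={self.alpha!r}, beta={self.beta!r}"
            )

    @property
    def has_kill(self) -> bool:
        """True when the curve actually decreases (alpha > 0 or beta > 0)."""
        return self.alpha > 0.0 or self.beta > 0.0

    @property
    def alpha_beta_ratio(self) -> float | None:
        """alpha/beta in Gy, or ``None`` when beta = 0 (purely linear kill)."""
        if self.beta > 0.0:
            return self.alpha / self.beta
        return None


@dataclass(frozen=True)
class LQMetrics:
    """Derived summary metrics of one LQ curve.

    ``d10`` is ``None`` for a no-kill curve (the 10% level is unattainable);
    ``alpha_beta_ratio`` is ``None`` when beta = 0 — an explicit "undefined"
    flag rather than an infinity sentinel.
    """

    d10: float | None
    sf2: float
    alpha_beta_ratio: float | None


@dataclass(frozen=True)
class RBEResult:
    """Iso-effect relative biological effectiveness of a test modality.

    ``rbe = dose_reference / dose_test`` at the stated survival level:
    values above 1 mean the test radiation needs less dose than the
    reference to produce the same kill.
    """

    reference_label: str
    test_label: str
    effect_level: float
    dose_reference: float
    dose_test: float
    rbe: float


def sf_at_dose(params: LQParams, dose):
    """Surviving fraction at ``dose`` Gy.

    ``dose`` may be a scalar or array-like; negative doses raise
    :class:`InputError`. Returns a float for scalar input, else an ndarray.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0.0) or np.any(np.isnan(d)):
        raise InputError(f"dose must be non-negative, got {dose!r}")
    sf = np.exp(-(params.alpha * d + params.beta * d * d))
    if np.isscalar(dose) or d.ndim == 0:
        return float(sf)
    return sf


def d_iso(params: LQParams, survival_level: float) -> float:
    """Dose (Gy) at which survival equals ``survival_level``.

    Solves ``beta*D**2 + alpha*D + ln(S) = 0`` for its positive root using
    the cancellation-free conjugate form ``-2*ln(S) / (alpha +
    sqrt(alpha**2 - 4*beta*ln S))`` (algebraically identical to the textbook
    quadratic root but stable as beta -> 0), falling back to
    ``-ln(S)/alpha`` when beta is numerically zero.

    Raises
    ------
    InputError
        If ``survival_level`` is outside ``(0, 1]``.
    UnattainableEffectError
        If the curve has no kill but a level below 1 is requested.
    """
    if not (0.0 < survival_level <= 1.0):
        raise InputError(
            f"survival_level must be in (0, 1], got {survival_level!r}"
        )
    if survival_level == 1.0:
        return 0.0
    if not params.has_kill:
        raise UnattainableEffectError(
            f"no-kill curve (alpha=beta=0) never reaches survival "
            f"{survival_level}"
        )
    ln_s = math.log(survival_level)
    if params.beta < BETA_LINEAR_THRESHOLD:
        return -ln_s / params.alpha
    disc = params.alpha * params.alpha - 4.0 * params.beta * ln_s
    return -2.0 * ln_s / (params.alpha + math.sqrt(disc))


def params_from_d10_ratio(d10: float, ratio: float) -> LQParams:
    """Reconstruct ``(alpha, beta)`` from a printed ``(D10, alpha/beta)`` pair.

    Substituting ``alpha = ratio*beta`` into ``SF(D10) = 0.10`` gives
    ``beta = ln(10) / (D10 * (ratio + D10))``.
    """
    if not (d10 > 0.0) or not (ratio > 0.0):
        raise InputError(f"d10 and ratio must be positive, got ({d10!r}, {ratio!r})")
    beta = _LN10 / (d10 * (ratio + d10))
    return LQParams(alpha=ratio * beta, beta=beta)


def params_from_sf2_ratio(sf2: float, ratio: float) -> LQParams:
    """Reconstruct ``(alpha, beta)`` from a printed ``(SF2, alpha/beta)`` pair.

    Substituting ``alpha = ratio*beta`` into ``SF(2) = SF2`` gives
    ``beta = -ln(SF2) / (2*ratio + 4)``. ``sf2 = 1`` yields the explicit
    no-kill curve.
    """
    if not (0.0 < sf2 <= 1.0):
        raise InputError(f"sf2 must be in (0, 1], got {sf2!r}")
    if not (ratio > 0.0):
        raise InputError(f"ratio must be positive, got {ratio!r}")
    beta = -math.log(sf2) / (2.0 * ratio + 4.0)
    return LQParams(alpha=ratio * beta, beta=beta)


def params_from_two_survival_points(
    dose1: float, sf1: float, dose2: float, sf2: float
) -> LQParams:
    """Exact ``(alpha, beta)`` through two (dose, survival) constraints.

    Solves the linear system ``alpha*d + beta*d**2 = -ln(sf)`` at the two
    points. Raises :class:`InputError` when the points are not consistent
    with any non-negative coefficient pair (e.g. survival falling slower
    than linearly on the log scale).
    """
    if dose1 <= 0 or dose2 <= 0 or dose1 == dose2:
        raise InputError("two distinct positive doses required")
    if not (0.0 < sf1 <= 1.0) or not (0.0 < sf2 <= 1.0):
        raise InputError("survival fractions must be in (0, 1]")
    a = np.array([[dose1, dose1 ** 2], [dose2, dose2 ** 2]], dtype=float)
    b = np.array([-math.log(sf1), -math.log(sf2)], dtype=float)
    alpha, beta = np.linalg.solve(a, b)
    if alpha < 0.0 or beta < 0.0:
        raise InputError(
            f"points ({dose1}, {sf1}) and ({dose2}, {sf2}) imply a negative "
            f"LQ coefficient (alpha={alpha:.4g}, beta={beta:.4g})"
        )
    return LQParams(alpha=float(alpha), beta=float(beta))


def metrics_from_params(params: LQParams) -> LQMetrics:
    """Summarise a curve as (D10, SF2, alpha/beta)."""
    d10 = d_iso(params, 0.10) if params.has_kill else None
    return LQMetrics(
        d10=d10,
        sf2=sf_at_dose(params, 2.0),
        alpha_beta_ratio=params.alpha_beta_ratio,
    )


def rbe_at_effect(
    reference: LQParams,
    test: LQParams,
    survival_level: float = 0.10,
    reference_label: str = "reference",
    test_label: str = "test",
) -> RBEResult:
    """Iso-effect RBE: reference dose over test dose at equal survival.

    The default level is survival 0.10, i.e. the ratio of the two D10 values.
    A curve that cannot reach the level raises
    :class:`UnattainableEffectError` naming the offending curve.
    """
    if not (0.0 < survival_level < 1.0):
        raise InputError(
            f"survival_level must be in (0, 1) for an iso-effect ratio, "
            f"got {survival_level!r}"
        )
    try:
        dose_ref = d_iso(reference, survival_level)
    except UnattainableEffectError as exc:
        raise UnattainableEffectError(
            f"reference curve {reference_label!r}: {exc}"
        ) from exc
    try:
        dose_test = d_iso(test, survival_level)
    except UnattainableEffectError as exc:
        raise UnattainableEffectError(f"test curve {test_label!r}: {exc}") from exc
    return RBEResult(
        reference_label=reference_label,
        test_label=test_label,
        effect_level=survival_level,
        dose_reference=dose_ref,
        dose_test=dose_test,
        rbe=dose_ref / dose_test,
    )
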