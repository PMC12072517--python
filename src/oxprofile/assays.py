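"""Closed-form assay computations.

Plate-level arithmetic shared by the study's biochemical endpoints: kinetic
ALT activity from NADH consumption at 340 nm, creatinine clearance, 4-parameter
logistic (4PL) immunoassay calibration and inversion, protein normalization,
fold changes, and diet-to-dose / interspecies dose conversions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "AltAssayConfig",
    "AbsorbanceSeries",
    "ClearanceInputs",
    "Curve4PL",
    "QuantificationLimitError",
    "FitConvergenceError",
    "alt_activity",
    "creatinine_clearance",
    "evaluate_4pl",
    "fit_4pl",
    "invert_4pl",
    "normalize_to_protein",
    "fold_change",
    "FoldChange",
    "diet_to_dose",
    "human_equivalent_dose",
]


class QuantificationLimitError(ValueError):
    """Response outside the invertible range of a calibration curve."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last parameter state."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


@dataclass(frozen=True)
class AltAssayConfig:
    """Constants of the kinetic ALT assay.

    ``extinction_coeff`` is the adjusted NADH extinction coefficient
    (mM^-1), ``total_volume`` the total well volume (mL: sample + substrate
    + cofactor + initiator), ``sample_volume`` the plasma volume (mL), and
    ``window_min`` the kinetic read window used by the two-point form.
    """

    extinction_coeff: float = 4.11  # mM^-1
    total_volume: float = 0.21  # mL
    sample_volume: float = 0.02  # mL
    window_min: float = 5.0

    def __post_init__(self):
        if min(self.extinction_coeff, self.total_volume, self.sample_volume, self.window_min) <= 0:
            raise ValueError("all ALT assay constants must be positive")
        if self.total_volume <= self.sample_volume:
            raise ValueError("total_volume must exceed sample_volume")


@dataclass(frozen=True)
class AbsorbanceSeries:
    """A340 kinetic read: times in minutes, one absorbance per time."""

    times: tuple
    a340: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        if t.size != a.size:
            raise ValueError("times and a340 must have equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 reads")


def alt_activity(
    series: AbsorbanceSeries,
    cfg: AltAssayConfig = AltAssayConfig(),
    method: Literal["two_point", "regression"] = "two_point",
) -> float:
    """ALT activity (U/mL) from an A340 kinetic read.

    One unit is 1 umol pyruvate generated per minute at 37 C. The canonical
    two-point form uses the absorbance drop between 0 and ``cfg.window_min``
    minutes::

        [((A_0 - A_5) / 5 min) * total_volume] / (extinction * sample_volume)

    ``method="regression"`` instead uses the least-squares slope of the whole
    read (non-canonical; useful when single reads are noisy). A negative
    result (absorbance rising) indicates assay failure and is returned with a
    warning rather than masked.
    """
    t = np.asarray(series.times, dtype=float)
    a = np.asarray(series.a340, dtype=float)
    if method == "two_point":
        if t[0] > 0 or t[-1] < cfg.window_min:
            raise ValueError(
                f"series must span 0..{cfg.window_min} min for the two-point form"
            )
        a0 = float(np.interp(0.0, t, a))
        a5 = float(np.interp(cfg.window_min, t, a))
        rate = (a0 - a5) / cfg.window_min  # absorbance decline per min
    elif method == "regression":
        slope = np.polyfit(t, a, 1)[0]
        rate = -slope
    else:
        raise ValueError(f"unknown method {method!r}")
    activity = (rate * cfg.total_volume) / (cfg.extinction_coeff * cfg.sample_volume)
    if activity < 0:
        warnings.warn(
            "A340 increased over the read window: negative ALT activity "
            "indicates assay failure",
            stacklevel=2,
        )
    return activity


@dataclass(frozen=True)
class ClearanceInputs:
    """Creatinine clearance inputs: concentrations in mg/dL, volume in uL,
    collection time in minutes (24 h default)."""

    urine_creatinine: float
    urine_volume: float
    plasma_creatinine: float
    collection_time: float = 1440.0

    def __post_init__(self):
        for name in ("urine_creatinine", "urine_volume", "collection_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plasma_creatinine <= 0:
            raise ValueError("plasma_creatinine must be positive (clearance undefined at 0)")


def creatinine_clearance(inputs: ClearanceInputs, per_hour: bool = False) -> float:
    """Creatinine clearance (Ucr * V) / (Pcr * t).

    The formula's native unit is volume per minute (uL/min with the default
    field units). ``per_hour=True`` applies a x60 presentation conversion,
    which is logged: some reports print uL/h despite the per-minute
    denominator, so the conversion is explicit rather than silent.
    """
    cl = (inputs.urine_creatinine * inputs.urine_volume) / (
        inputs.plasma_creatinine * inputs.collection_time
    )
    if per_hour:
        logger.info("creatinine clearance converted uL/min -> uL/h (x60)")
        cl *= 60.0
    return cl


@dataclass(frozen=True)
class Curve4PL:
    """Four-parameter logistic curve y = d + (a - d) / (1 + (x/c)^b).

    ``a`` is the zero-dose response, ``d`` the infinite-dose asymptote,
    ``c`` the inflection dose (EC50) and ``b`` the Hill slope.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("inflection dose c must be positive")
        if self.b == 0:
            raise ValueError("slope b must be nonzero")


def _4pl(x, a, b, c, d):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / c) ** b, np.where(b > 0, 0.0, np.inf))
    return d + (a - d) / (1.0 + ratio)


def evaluate_4pl(curve: Curve4PL, x) -> np.ndarray | float:
    """Response of a 4PL curve at dose(s) ``x`` (x = 0 maps to the a asymptote
    for positive slopes)."""
    y = _4pl(x, curve.a, curve.b, curve.c, curve.d)
    return float(y) if np.isscalar(x) else y


def fit_4pl(doses, responses, max_iter: int = 10000) -> Curve4PL:
    """Least-squares 4PL fit.

    Initialization: a = response at the lowest dose side (max response for a
    descending curve), d = the opposite extreme, c = geometric mean of the
    positive doses, b = 1. Requires >= 5 distinct dose levels. Degenerate
    (flat) responses raise :class:`FitConvergenceError` rather than returning
    an unidentifiable curve.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct dose levels to fit a 4PL curve")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("doses and responses must be finite")
    span = y.max() - y.min()
    if span <= 1e-12 * max(1.0, abs(y.max())):
        raise FitConvergenceError(
            "flat responses: 4PL parameters are unidentifiable",
            last_params=(y.mean(), 1.0, float(np.exp(np.mean(np.log(x[x > 0])))), y.mean()),
        )
    c0 = float(np.exp(np.mean(np.log(x[x > 0]))))
    # orient a to the low-dose end of the data; b = 1 then has the right sign
    a0 = float(y[np.argmin(x)])
    d0 = float(y[np.argmax(x)])
    p0 = (a0, 1.0, c0, d0)
    try:
        popt, _ = curve_fit(
            _4pl, x, y, p0=p0, maxfev=max_iter,
            bounds=([-np.inf, -50, 1e-12, -np.inf], [np.inf, 50, np.inf, np.inf]),
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"4PL fit did not converge: {exc}", last_params=p0) from exc
    a, b, c, d = map(float, popt)
    if b < 0:
        # the 4PL is invariant under (a, b, d) -> (d, -b, a); report the
        # canonical orientation with a as the zero-dose response
        a, b, d = d, -b, a
    return Curve4PL(a, b, c, d)


def invert_4pl(curve: Curve4PL, y: float) -> float:
    """Dose at which the 4PL curve attains response ``y``.

    Closed form x = c * ((a - d)/(y - d) - 1)^(1/b). ``y`` must lie strictly
    inside the open response range (min(a,d), max(a,d)); values at or beyond
    the asymptotes are outside the quantifiable range and raise
    :class:`QuantificationLimitError` naming the limits.
    """
    lo, hi = sorted((curve.a, curve.d))
    if not (lo < y < hi):
        raise QuantificationLimitError(
            f"response {y} outside quantification limits ({lo}, {hi})"
        )
    return curve.c * (((curve.a - curve.d) / (y - curve.d) - 1.0) ** (1.0 / curve.b))


def normalize_to_protein(value: float, protein_mg: float, unit: str = "") -> tuple[float, str]:
    """Normalize an assay value to total protein (per-mg-protein units).

    Returns ``(value / protein_mg, "<unit>/mg protein")``.
    """
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    out_unit = f"{unit}/mg protein" if unit else "per mg protein"
    return value / protein_mg, out_unit


class FoldChange(NamedTuple):
    fold: float
    direction: str  # "higher" | "lower" | "equal": first argument vs second


def fold_change(numerator_mean: float, denominator_mean: float) -> FoldChange:
    """Max-over-min fold change between two positive group means.

    The direction flag states whether the first mean is higher or lower than
    the second, so ``fold_change(x, y)`` equals ``fold_change(y, x)`` with the
    direction flipped.
    """
    if numerator_mean <= 0 or denominator_mean <= 0:
        raise ValueError("fold change requires positive means")
    if numerator_mean == denominator_mean:
        return FoldChange(1.0, "equal")
    if numerator_mean > denominator_mean:
        return FoldChange(numerator_mean / denominator_mean, "higher")
    return FoldChange(denominator_mean / numerator_mean, "lower")


def diet_to_dose(diet_conc: float, food_intake: float, body_weight: float) -> float:
    """Daily dose (mg/kg body weight/day) from dietary concentration.

    ``diet_conc`` in mg per kg diet, ``food_intake`` in g/day, ``body_weight``
    in g; the gram units cancel.
    """
    if diet_conc < 0 or food_intake < 0:
        raise ValueError("diet concentration and intake must be non-negative")
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    return diet_conc * food_intake / body_weight


def human_equivalent_dose(animal_dose: float, factor: float = 0.081) -> float:
    """Human equivalent dose by body-surface-area scaling (mouse factor 0.081)."""
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    return animal_dose * factor
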