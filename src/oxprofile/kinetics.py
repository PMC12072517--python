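"""First-order capillary-efflux kinetics.

Brain capillaries loaded with a fluorescent tracer lose luminal signal over
time; the leakage rate constant k (min^-1) of the first-order decay
F(t) = f_inf + (f0 - f_inf) * exp(-k t) is the barrier-integrity readout.
Also computes transporter-specific luminal signal as a total-minus-inhibited
difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "KineticTrace",
    "EffluxFit",
    "PgpSignal",
    "fit_first_order",
    "group_rate_table",
    "pgp_specific_signal",
]


@dataclass(frozen=True)
class KineticTrace:
    """Luminal fluorescence time series for one capillary.

    Times in minutes (strictly increasing, starting at 0), fluorescence in
    arbitrary units on the 8-bit imaging scale [0, 255].
    """

    capillary_id: str
    times: tuple
    fluorescence: tuple
    group: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.size < 4:
            raise ValueError("a kinetic trace needs >= 4 time points")
        if t.size != f.size:
            raise ValueError("times and fluorescence must have equal length")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if f.min() < 0 or f.max() > 255:
            raise ValueError("fluorescence must lie in [0, 255] a.u.")


@dataclass(frozen=True)
class EffluxFit:
    """Fitted first-order efflux parameters for one trace."""

    k: float  # min^-1
    f0: float  # a.u.
    f_inf: float  # a.u.
    k_se: float  # min^-1
    r_squared: float
    n_points: int
    boundary: bool = False  # True when k was pinned at the k >= 0 boundary
    capillary_id: str = ""
    group: str = ""


@dataclass(frozen=True)
class PgpSignal:
    """Transporter-specific luminal signal = total - inhibited."""

    total_luminal: float
    inhibited_luminal: float
    specific: float = field(init=False)

    def __post_init__(self):
        for name in ("total_luminal", "inhibited_luminal"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name} must lie in [0, 255] a.u.")
        object.__setattr__(self, "specific", self.total_luminal - self.inhibited_luminal)


def _decay_free(t, k, f0, f_inf):
    return f_inf + (f0 - f_inf) * np.exp(-k * t)


def _decay_zero(t, k, f0):
    return f0 * np.exp(-k * t)


def _loglinear_init(t, f):
    """Log-linear slope of -ln F(t) for positive signal; robust k starting point."""
    mask = f > 0
    if mask.sum() < 2:
        return 0.1, max(float(f[0]), 1e-6)
    slope, intercept = np.polyfit(t[mask], np.log(f[mask]), 1)
    return max(-slope, 1e-6), float(np.exp(intercept))


def fit_first_order(trace: KineticTrace, plateau_mode: str = "fixed_zero") -> EffluxFit:
    """Fit F(t) = f_inf + (f0 - f_inf) exp(-k t) to a luminal trace.

    ``plateau_mode="fixed_zero"`` pins f_inf at 0 (pure first-order efflux);
    ``"free"`` estimates the plateau, bounded to [0, f0]. The fit is bounded
    (k >= 0) and started from the log-linear initialization, which avoids the
    k = 0 local minimum for decaying traces. A best fit at the k = 0 boundary
    (non-decaying trace) is returned with ``boundary=True`` rather than as an
    error. k_se comes from the curvature of the least-squares objective.
    """
    if plateau_mode not in ("fixed_zero", "free"):
        raise ValueError("plateau_mode must be 'fixed_zero' or 'free'")
    t = np.asarray(trace.times, dtype=float)
    f = np.asarray(trace.fluorescence, dtype=float)
    k0, f00 = _loglinear_init(t, f)
    f00 = min(max(f00, 1e-6), 255.0)

    def _try(p0, model, lower, upper):
        return curve_fit(model, t, f, p0=p0, bounds=(lower, upper), maxfev=20000)

    try:
        if plateau_mode == "fixed_zero":
            popt, pcov = _try([k0, f00], _decay_zero, [0.0, 0.0], [np.inf, 255.0 * 10])
            k, f0 = popt
            f_inf = 0.0
            k_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
            fitted = _decay_zero(t, *popt)
        else:
            finf0 = max(float(f.min()), 0.0)
            popt, pcov = _try(
                [k0, f00, finf0], _decay_free, [0.0, 0.0, 0.0], [np.inf, 255.0 * 10, 255.0]
            )
            k, f0, f_inf = popt
            k_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
            fitted = _decay_free(t, *popt)
    except RuntimeError as exc:
        raise RuntimeError(f"efflux fit failed for {trace.capillary_id!r}: {exc}") from exc

    rss = float(np.sum((f - fitted) ** 2))
    tss = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    boundary = bool(k <= 1e-6)  # below any rate resolvable on the assay's time scale
    if boundary:
        k = 0.0
    return EffluxFit(
        k=float(k),
        f0=float(f0),
        f_inf=float(f_inf),
        k_se=k_se,
        r_squared=r2,
        n_points=int(t.size),
        boundary=boundary,
        capillary_id=trace.capillary_id,
        group=trace.group,
    )


def group_rate_table(fits: list[EffluxFit], reference: str | None = None) -> pd.DataFrame:
    """Per-group mean +/- SEM of fitted rate constants.

    Capillary fits are the replicate unit. Returns one row per group with
    columns n, k_mean, k_sem and, when a reference group is given (default:
    group of the first fit), k_ratio_vs_reference. Empty groups are simply
    absent; groups with a single fit get NaN SEM with a warning.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = {}
    for fit in fits:
        rows.setdefault(fit.group, []).append(fit.k)
    reference = reference if reference is not None else fits[0].group
    records = []
    for group, ks in rows.items():
        ks = np.asarray(ks, dtype=float)
        if ks.size < 2:
            warnings.warn(f"group {group!r} has a single fit; SEM undefined", stacklevel=2)
        sem = float(ks.std(ddof=1) / np.sqrt(ks.size)) if ks.size > 1 else np.nan
        records.append(
            {"group": group, "n": int(ks.size), "k_mean": float(ks.mean()), "k_sem": sem}
        )
    table = pd.DataFrame.from_records(records).set_index("group")
    if reference not in table.index:
        raise ValueError(f"reference group {reference!r} has no fits")
    table["k_ratio_vs_reference"] = table["k_mean"] / table.loc[reference, "k_mean"]
    return table


def pgp_specific_signal(total: float, inhibited: float) -> PgpSignal:
    """Inhibitor-sensitive (transporter-specific) luminal signal.

    ``specific = total - inhibited``. A negative value (inhibited exceeds
    total) is physically suspect and emitted with a warning, not an error.
    """
    sig = PgpSignal(total_luminal=total, inhibited_luminal=inhibited)
    if sig.specific < 0:
        warnings.warn(
            "inhibited luminal signal exceeds total: negative specific signal",
            stacklevel=2,
        )
    return sig
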