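"""Synthetic study-data generator.

Emulates the raw data of a three-group mouse treatment study (healthy
reference, disease model, treated disease model; n = 15 per group): seven
protein-normalized biochemical endpoints with group-specific means/SDs and a
planted inter-endpoint correlation structure, technical replicates, luminal
fluorescence decay traces, 4PL standard-curve plates, and Y-maze sessions.
Every generator is deterministic under a fixed seed.

The default group means and SEM-derived SDs mirror a published three-group
study summary (n = 15 per group; SD = SEM * sqrt(15)); the planted correlation
matrices are single-factor constructions (always positive semi-definite) in
which oxidative-stress endpoints load positively and clearance negatively,
most strongly in the disease group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oxprofile.assays import Curve4PL, evaluate_4pl
from oxprofile.kinetics import KineticTrace
from oxprofile.ymaze import ArmEvent, YMazeSession

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ENDPOINTS",
    "DEFAULT_GROUPS",
    "ENDPOINT_UNITS",
    "TRACE_PRESETS",
    "StudyDesign",
    "GroupModel",
    "TraceModel",
    "default_group_models",
    "generate_endpoint_table",
    "generate_trace",
    "generate_standard_curve",
    "generate_ymaze_cohort",
]

DEFAULT_GROUPS = ("WT", "5xFAD", "5xFAD+NAC")

DEFAULT_ENDPOINTS = (
    "renal P-gp",
    "renal MDA",
    "brain MDA",
    "renal 4-HNE",
    "brain 4-HNE",
    "creatinine clearance",
    "plasma ALT",
)

ENDPOINT_UNITS = {
    "renal P-gp": "a.u.",
    "renal MDA": "ug/mg protein",
    "brain MDA": "ug/mg protein",
    "renal 4-HNE": "mg/mg protein",
    "brain 4-HNE": "mg/mg protein",
    "creatinine clearance": "uL/h",
    "plasma ALT": "U/mL",
}

# group -> endpoint -> (mean, SEM at n=15), in the units above
_GROUP_SUMMARIES = {
    "WT": {
        "renal P-gp": (8.0, 0.8),
        "renal MDA": (28.6, 2.4),
        "brain MDA": (5.9, 0.5),
        "renal 4-HNE": (2.8, 0.3),
        "brain 4-HNE": (0.1, 0.01),
        "creatinine clearance": (0.036, 0.004),
        "plasma ALT": (12.3, 1.2),
    },
    "5xFAD": {
        "renal P-gp": (11.1, 1.0),
        "renal MDA": (30.8, 0.03),
        "brain MDA": (10.1, 0.9),
        "renal 4-HNE": (3.6, 0.3),
        "brain 4-HNE": (0.3, 0.03),
        "creatinine clearance": (0.016, 0.002),
        "plasma ALT": (13.6, 1.3),
    },
    "5xFAD+NAC": {
        "renal P-gp": (7.7, 0.6),
        "renal MDA": (27.2, 2.2),
        "brain MDA": (6.2, 0.5),
        "renal 4-HNE": (2.3, 0.2),
        "brain 4-HNE": (0.1, 0.01),
        "creatinine clearance": (0.037, 0.005),
        "plasma ALT": (10.9, 1.1),
    },
}

# single-factor loadings per group (order = DEFAULT_ENDPOINTS): oxidative
# markers co-vary, clearance anti-correlates, strongest in the disease group
_FACTOR_LOADINGS = {
    "WT": (0.10, 0.30, 0.30, 0.30, 0.30, -0.10, 0.10),
    "5xFAD": (0.20, 0.60, 0.60, 0.70, 0.70, -0.50, 0.20),
    "5xFAD+NAC": (0.15, 0.40, 0.40, 0.40, 0.40, -0.20, 0.15),
}

#: First-order leakage rate presets (min^-1) for trace simulation.
TRACE_PRESETS = {"WT": 0.08, "5xFAD": 0.26, "5xFAD+NAC": 0.18, "mannitol": 0.58}


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the simulated study: an ordered (reference, disease, treated)
    group triple, subjects per group, endpoint panel, technical replicates."""

    groups: tuple = DEFAULT_GROUPS
    n_subjects: int = 15
    endpoints: tuple = DEFAULT_ENDPOINTS
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.groups) != 3:
            raise ValueError("design requires exactly 3 groups (reference, disease, treated)")
        if self.n_subjects < 4:
            raise ValueError("need n >= 4 subjects per group (Fisher z requires n > 3)")
        if len(set(self.endpoints)) != len(self.endpoints):
            raise ValueError("endpoint names must be unique")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 technical replicate")


def _factor_correlation(loadings) -> np.ndarray:
    lam = np.asarray(loadings, dtype=float)
    r = np.outer(lam, lam)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass(frozen=True)
class GroupModel:
    """Subject-level distribution of one group.

    Subjects are multivariate Gaussian with the given per-endpoint means/SDs
    and target correlation matrix (must be PSD); technical replicates add
    independent Gaussian noise with sd = ``replicate_noise_frac`` x subject sd.
    """

    means: tuple
    sds: tuple
    correlation: np.ndarray
    replicate_noise_frac: float = 0.2

    def __post_init__(self):
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        r = np.asarray(self.correlation, dtype=float)
        p = m.size
        if s.size != p or r.shape != (p, p):
            raise ValueError("means, sds and correlation dimensions must agree")
        if np.any(s <= 0):
            raise ValueError("sds must be positive")
        if not np.allclose(r, r.T):
            raise ValueError("target correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("target correlation matrix must have unit diagonal")
        eigs = np.linalg.eigvalsh(r)
        if eigs[0] < -1e-10:
            raise ValueError(
                f"target correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {eigs[0]:.3e})"
            )
        if self.replicate_noise_frac < 0:
            raise ValueError("replicate noise fraction must be >= 0")
        object.__setattr__(self, "correlation", r)

    def factor(self) -> np.ndarray:
        """A matrix L with L L^T = correlation (eigendecomposition; tolerant
        of a semidefinite target)."""
        w, v = np.linalg.eigh(self.correlation)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def default_group_models(design: StudyDesign = StudyDesign()) -> dict[str, GroupModel]:
    """Group models matching the shipped study summaries and planted
    single-factor correlation structure (only for the default panel)."""
    models = {}
    for group in design.groups:
        if group not in _GROUP_SUMMARIES:
            raise KeyError(f"no default summary for group {group!r}")
        summ = _GROUP_SUMMARIES[group]
        means, sds = [], []
        for ep in design.endpoints:
            mean, sem = summ[ep]
            means.append(mean)
            sds.append(sem * np.sqrt(15))
        models[group] = GroupModel(
            means=tuple(means),
            sds=tuple(sds),
            correlation=_factor_correlation(
                [_FACTOR_LOADINGS[group][DEFAULT_ENDPOINTS.index(ep)] for ep in design.endpoints]
            ),
        )
    return models


def generate_endpoint_table(
    design: StudyDesign, models: dict[str, GroupModel] | None = None
) -> pd.DataFrame:
    """Long-format endpoint measurements with technical replicates.

    Columns: group, subject, replicate, endpoint, value, unit. Subjects are
    drawn from each group's multivariate Gaussian (population correlation =
    target, by construction through a factorization of the target matrix);
    replicates add independent noise. Negative values are truncated at zero
    (physical concentrations) with the truncation count logged. Deterministic
    under ``design.seed``.
    """
    models = models if models is not None else default_group_models(design)
    rng = np.random.default_rng(design.seed)
    p = len(design.endpoints)
    n, reps = design.n_subjects, design.n_replicates
    units = [ENDPOINT_UNITS.get(ep, "") for ep in design.endpoints]
    frames = []
    n_truncated = 0
    for group in design.groups:
        model = models[group]
        L = model.factor()
        z = rng.standard_normal((n, p))
        subjects = np.asarray(model.means) + (z @ L.T) * np.asarray(model.sds)
        rep_sd = model.replicate_noise_frac * np.asarray(model.sds)
        if model.replicate_noise_frac > 0:
            noise = rng.normal(0.0, 1.0, size=(n, reps, p)) * rep_sd
        else:
            noise = np.zeros((n, reps, p))
        values = subjects[:, None, :] + noise  # (subject, replicate, endpoint)
        n_truncated += int(np.sum(values < 0))
        values = np.maximum(values, 0.0)
        subject_ids = np.array([f"{group}-{si + 1:02d}" for si in range(n)])
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "subject": np.repeat(subject_ids, reps * p),
                    "replicate": np.tile(np.repeat(np.arange(1, reps + 1), p), n),
                    "endpoint": np.tile(np.asarray(design.endpoints, dtype=object), n * reps),
                    "value": values.ravel(),
                    "unit": np.tile(np.asarray(units, dtype=object), n * reps),
                }
            )
        )
    if n_truncated:
        logger.info("truncated %d negative generated values at 0", n_truncated)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TraceModel:
    """First-order luminal decay: F(t) = f_inf + (f0 - f_inf) exp(-k t) plus
    Gaussian noise, clipped to the 8-bit imaging range [0, 255]."""

    k_true: float  # min^-1
    f0: float = 200.0  # a.u.
    f_inf: float = 0.0  # a.u.
    n_timepoints: int = 13
    interval_min: float = 2.0
    noise_sd: float = 5.0  # a.u.

    def __post_init__(self):
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")
        if not (0 <= self.f_inf < self.f0 <= 255):
            raise ValueError("require 0 <= f_inf < f0 <= 255")
        if self.n_timepoints < 4:
            raise ValueError("need >= 4 time points")
        if self.interval_min <= 0 or self.noise_sd < 0:
            raise ValueError("interval must be positive and noise sd >= 0")


def generate_trace(
    model: TraceModel, seed: int, capillary_id: str = "cap-1", group: str = ""
) -> KineticTrace:
    """One simulated luminal fluorescence trace."""
    rng = np.random.default_rng(seed)
    t = np.arange(model.n_timepoints) * model.interval_min
    f = model.f_inf + (model.f0 - model.f_inf) * np.exp(-model.k_true * t)
    if model.noise_sd > 0:
        f = f + rng.normal(0.0, model.noise_sd, size=t.size)
    f = np.clip(f, 0.0, 255.0)
    return KineticTrace(
        capillary_id=capillary_id, times=tuple(t), fluorescence=tuple(f), group=group
    )


def generate_standard_curve(
    curve: Curve4PL,
    levels,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_blanks: int = 2,
) -> pd.DataFrame:
    """Simulated calibration plate: standards at the given dose levels plus
    blank wells, absorbances following the 4PL curve with additive noise.

    Columns: well, role (standard | blank), dose, absorbance.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(levels, dtype=float)
    rows = []
    for i, x in enumerate(levels):
        y = evaluate_4pl(curve, float(x)) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append((f"S{i + 1}", "standard", float(x), float(y)))
    for i in range(n_blanks):
        y = evaluate_4pl(curve, 0.0) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append((f"B{i + 1}", "blank", 0.0, float(y)))
    return pd.DataFrame(rows, columns=["well", "role", "dose", "absorbance"])


def generate_ymaze_cohort(
    n_mice: int,
    p_novel_first: float,
    arm_preference_weights: dict[str, float] | None = None,
    seed: int = 0,
    group: str = "",
    mean_entries: int = 15,
    mean_dwell_s: float = 10.0,
) -> list[YMazeSession]:
    """Simulated retrieval-trial sessions for one group.

    The first arm entry is novel with probability ``p_novel_first``; otherwise
    (and for all subsequent entries) arms are drawn from the preference
    weights, renormalized to exclude the arm the mouse currently occupies.
    Dwell times are gamma-distributed (positive) and events are laid out
    sequentially with short center-zone transits.
    """
    if not (0 <= p_novel_first <= 1):
        raise ValueError("p_novel_first must lie in [0, 1]")
    weights = arm_preference_weights or {"start": 1 / 3, "sample": 1 / 3, "novel": 1 / 3}
    arms = list(weights)
    w = np.asarray([weights[a] for a in arms], dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("arm preference weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    sessions = []
    for mi in range(n_mice):
        if rng.random() < p_novel_first:
            first = "novel"
        else:
            others = [a for a in arms if a != "novel"]
            wo = np.asarray([weights[a] for a in others])
            first = others[rng.choice(len(others), p=wo / wo.sum())]
        sequence = [first]
        n_entries = max(1, rng.poisson(mean_entries))
        while len(sequence) < n_entries:
            current = sequence[-1]
            others = [a for a in arms if a != current]
            wo = np.asarray([weights[a] for a in others])
            sequence.append(others[rng.choice(len(others), p=wo / wo.sum())])
        t = 0.0
        events = []
        for arm in sequence:
            dwell = rng.gamma(shape=2.0, scale=mean_dwell_s / 2.0)
            events.append(ArmEvent(arm=arm, entry_time=t, exit_time=t + dwell))
            t += dwell + rng.gamma(shape=2.0, scale=1.0)  # center-zone transit
        sessions.append(
            YMazeSession(
                mouse_id=f"{group or 'm'}-{mi + 1:02d}",
                group=group,
                trial="retrieval",
                events=tuple(events),
            )
        )
    return sessions
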