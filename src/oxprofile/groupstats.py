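"""Replicate-aware group statistics.

Technical replicates are averaged to the subject level before testing (exact
for balanced designs; imbalance is detected and warned about). Fixed-effects
linear models are solved by normal equations; per-effect statistics are
likelihood-ratio chi-squares from Gaussian deviance differences, with
Benjamini–Hochberg control of the false discovery rate and Welch-type pairwise
contrasts of group (marginal) means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["aggregate_replicates", "anova", "bh_adjust", "pairwise_emm", "ContrastResult"]


def aggregate_replicates(
    table: pd.DataFrame,
    value_col: str = "value",
    keys: tuple[str, ...] = ("group", "subject", "endpoint"),
) -> pd.DataFrame:
    """Average technical replicates to one value per subject x endpoint.

    Missing values are dropped (count logged). The output keeps the grouping
    keys, the replicate count ``n_replicates``, and the per-subject mean in
    ``value_col``. Unbalanced replicate counts are allowed but warned about,
    since the mean-then-model shortcut is exactly equivalent to a mixed model
    only under balance.
    """
    missing = table[value_col].isna().sum()
    if missing:
        logger.info("dropping %d missing %s values before aggregation", missing, value_col)
    clean = table.dropna(subset=[value_col])
    keys = [k for k in keys if k in clean.columns]
    extra = [c for c in ("unit",) if c in clean.columns]
    agg = (
        clean.groupby(list(keys), sort=False, observed=True)
        .agg(**{value_col: (value_col, "mean"), "n_replicates": (value_col, "count")},
             **{c: (c, "first") for c in extra})
        .reset_index()
    )
    if agg["n_replicates"].nunique() > 1:
        warnings.warn(
            "unbalanced technical replicate counts; replicate-mean aggregation "
            "is only exactly equivalent to a mixed model under balance",
            stacklevel=2,
        )
    return agg


def _design_matrix(df: pd.DataFrame, factors: list[str], interaction: bool):
    """Full-rank treatment-coded design matrix; returns (X, column labels,
    mapping effect -> column indices)."""
    n = len(df)
    cols = [np.ones(n)]
    labels = ["Intercept"]
    effect_cols: dict[str, list[int]] = {}
    dummies = {}
    for f in factors:
        d = pd.get_dummies(df[f].astype("category"), prefix=f, drop_first=True, dtype=float)
        dummies[f] = d
        effect_cols[f] = list(range(len(labels), len(labels) + d.shape[1]))
        cols.extend(d[c].to_numpy() for c in d.columns)
        labels.extend(d.columns)
    if interaction:
        if len(factors) != 2:
            raise ValueError("interaction requires exactly two factors")
        f1, f2 = factors
        name = f"{f1}:{f2}"
        effect_cols[name] = []
        for c1 in dummies[f1].columns:
            for c2 in dummies[f2].columns:
                effect_cols[name].append(len(labels))
                cols.append(dummies[f1][c1].to_numpy() * dummies[f2][c2].to_numpy())
                labels.append(f"{c1}:{c2}")
    X = np.column_stack(cols)
    return X, labels, effect_cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova(
    table: pd.DataFrame,
    response: str = "value",
    factors: list[str] | tuple[str, ...] = ("group",),
    interaction: bool = False,
    bh_m: int | None = None,
) -> pd.DataFrame:
    """Fixed-effects ANOVA with likelihood-ratio chi-square per effect.

    The full linear model (treatment coding) is fit by least squares; each
    effect's statistic is the Gaussian deviance difference
    ``chi2 = n * ln(RSS_reduced / RSS_full)`` from refitting without that
    effect's columns, with df = number of columns dropped. The omnibus row
    compares the full model with the intercept-only model. Per-effect R^2 is
    the incremental (RSS_reduced - RSS_full) / TSS. p-values get a
    Benjamini–Hochberg adjustment across the effect rows (override the family
    size with ``bh_m``). This is a fixed-effects approximation to a
    mixed-model analysis; feed it subject-level (replicate-aggregated) data.

    Raises on rank-deficient designs, naming the aliased columns.
    """
    factors = list(factors)
    df = table.dropna(subset=[response] + factors)
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    y = df[response].to_numpy(dtype=float)
    n = y.size
    X, labels, effect_cols = _design_matrix(df, factors, interaction)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by rank-revealing QR on the column order
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(labels[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    rss_full = _rss(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    # guard against log(0) on perfect fits
    rss_full = max(rss_full, 1e-300)
    rows = []
    for effect, idx in effect_cols.items():
        keep = [j for j in range(X.shape[1]) if j not in idx]
        rss_red = max(_rss(X[:, keep], y), 1e-300)
        chi2 = n * np.log(rss_red / rss_full)
        df_eff = len(idx)
        rows.append(
            {
                "effect": effect,
                "chi_square": max(chi2, 0.0),
                "df": df_eff,
                "p": float(sps.chi2.sf(max(chi2, 0.0), df_eff)),
                "r_squared": max((rss_red - rss_full) / tss, 0.0) if tss > 0 else 0.0,
            }
        )
    k_omni = X.shape[1] - 1
    chi2_omni = n * np.log(max(tss, 1e-300) / rss_full)
    rows.append(
        {
            "effect": "omnibus",
            "chi_square": max(chi2_omni, 0.0),
            "df": k_omni,
            "p": float(sps.chi2.sf(max(chi2_omni, 0.0), k_omni)),
            "r_squared": 1.0 - rss_full / tss if tss > 0 else 0.0,
        }
    )
    out = pd.DataFrame(rows).set_index("effect")
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy(), m=bh_m)
    return out


def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} (p_(j) * m / j)`` over the ascending order,
    capped at 1, returned in the original order. ``m`` defaults to the number
    of p-values; a larger family size (e.g. a study-wide fixed m) may be
    supplied, never a smaller one.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of p-values {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


@dataclass(frozen=True)
class ContrastResult:
    """Welch contrast of two group means."""

    group_a: str
    group_b: str
    difference: float  # mean_a - mean_b
    se: float
    dof: float
    p: float
    p_adjusted: float
    effect_size: float  # standardized difference (Cohen's d, pooled SD)


def pairwise_emm(
    table: pd.DataFrame,
    response: str = "value",
    group_col: str = "group",
    bh_m: int | None = None,
) -> list[ContrastResult]:
    """All pairwise contrasts of group means with Welch standard errors.

    For a one-factor design the estimated marginal means are the group means
    of the subject-level data. Each unordered pair gets a Welch t-test (unequal
    variances, Welch–Satterthwaite df) and a pooled-SD standardized difference;
    p-values are BH-adjusted across the pairs (``bh_m`` overrides the family
    size). Degenerate (zero-variance) comparisons raise.
    """
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    stats = {}
    for g in groups:
        v = table.loc[table[group_col] == g, response].dropna().to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")
        stats[g] = (v.mean(), v.var(ddof=1), v.size)
    raw = []
    for a, b in combinations(groups, 2):
        ma, va, na = stats[a]
        mb, vb, nb = stats[b]
        se2 = va / na + vb / nb
        if se2 <= 0:
            raise ValueError(f"degenerate (zero) variance in contrast {a!r} vs {b!r}")
        se = np.sqrt(se2)
        dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        tstat = (ma - mb) / se
        p = 2 * sps.t.sf(abs(tstat), dof)
        pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
        d = (ma - mb) / pooled if pooled > 0 else np.inf
        raw.append((a, b, ma - mb, se, dof, p, d))
    adj = bh_adjust([r[5] for r in raw], m=bh_m)
    return [
        ContrastResult(a, b, diff, se, dof, p, float(pa), d)
        for (a, b, diff, se, dof, p, d), pa in zip(raw, adj)
    ]
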