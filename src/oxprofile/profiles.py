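"""Multivariate correlation-profile comparison.

The study's bespoke analysis: within each treatment group, correlate every
pair of endpoints; compare whole correlation matrices between groups with a
Steiger-type chi-square on Fisher-z differences; summarize between-group
dissimilarity as Euclidean distance in z space rendered as an unrooted
neighbor-joining tree; and classify the treatment's effect on every endpoint
pair as correction / exacerbation / overcorrection with a graded score whose
sum is the study-level treatment score.

Conventions. For endpoint pair (i, j) write z_g = atanh(r_g) within group g,
with groups reference (healthy), disease (untreated model) and treated.
The disease shift is dz_dis = z_dis - z_ref and the residual shift under
treatment is dz_trt = z_trt - z_ref. The grand difference
``dz_dis - dz_trt = z_dis - z_trt`` is positive when treatment moved the
coefficient back toward (or beyond) the reference; its back-transform
tanh(grand difference) is thresholded at 0.1 / 0.3 / 0.5 into none / small /
moderate / large extents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.tree import nj

from oxprofile.groupstats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationProfile",
    "SteigerComparison",
    "ProfileDistances",
    "EffectClassification",
    "ProfileReport",
    "SCORE_GRID",
    "correlation_matrix",
    "fisher_z",
    "inverse_fisher",
    "steiger_matrix_test",
    "steiger_all_pairs",
    "profile_distances",
    "classify_effect",
    "profile_report",
]

#: Score for each (direction, extent) cell. Corrections score positively,
#: exacerbations negatively, overcorrections at half credit.
SCORE_GRID = {
    ("exacerbation", "large"): -3.0,
    ("exacerbation", "moderate"): -2.0,
    ("exacerbation", "small"): -1.0,
    ("no_effect", "none"): 0.0,
    ("correction", "small"): 1.0,
    ("correction", "moderate"): 2.0,
    ("correction", "large"): 3.0,
    ("overcorrection", "small"): 0.5,
    ("overcorrection", "moderate"): 1.0,
    ("overcorrection", "large"): 1.5,
}


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-group p x p correlation matrix with its sample size."""

    group: str
    endpoints: tuple
    r: np.ndarray
    n: int
    method: str = "pearson"

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        p = len(self.endpoints)
        if r.shape != (p, p):
            raise ValueError("correlation matrix shape must match endpoint count")
        if not np.allclose(r, r.T, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        finite = r[np.isfinite(r)]
        if np.any(np.abs(finite) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n <= 3:
            raise ValueError("Fisher z requires n > 3 subjects")
        object.__setattr__(self, "r", r)

    def pair_r(self) -> pd.Series:
        """Upper-triangle correlations indexed by endpoint pair."""
        idx, vals = [], []
        for i, j in combinations(range(len(self.endpoints)), 2):
            idx.append((self.endpoints[i], self.endpoints[j]))
            vals.append(self.r[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx), name=self.group)


def correlation_matrix(
    table: pd.DataFrame,
    group: str,
    method: str = "pearson",
    value_col: str = "value",
) -> CorrelationProfile:
    """Correlation profile of one group from a subject-level long table.

    ``table`` must be subject-level (technical replicates already averaged)
    with columns group / subject / endpoint / value. Correlations use
    pairwise-complete observations; a constant endpoint yields NaN entries,
    which are logged and skipped by the downstream comparisons.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no rows for group {group!r}")
    wide = sub.pivot_table(index="subject", columns="endpoint", values=value_col,
                           aggfunc="mean", sort=False)
    n = wide.dropna().shape[0]
    if n < 4:
        raise ValueError(f"group {group!r} has {n} complete subjects; need >= 4")
    r = wide.corr(method=method, min_periods=4)
    n_nan = int(np.isnan(r.to_numpy()[np.triu_indices(r.shape[0], 1)]).sum())
    if n_nan:
        logger.warning("group %s: %d undefined correlations (constant endpoint?)", group, n_nan)
        np.fill_diagonal(r.values, 1.0)
    return CorrelationProfile(
        group=group, endpoints=tuple(r.columns), r=r.to_numpy(), n=int(n), method=method
    )


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = atanh(r); var(z) ~ 1/(n-3).

    Raises on |r| = 1, where z is infinite — clip such correlations (e.g. to
    +/-0.9999) upstream if they are genuine.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr[np.isfinite(arr)]) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform; clip degenerate "
                         "correlations before transforming")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def inverse_fisher(z):
    """Back-transform tanh(z); inverse of :func:`fisher_z`."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


@dataclass(frozen=True)
class SteigerComparison:
    """Chi-square comparison of two correlation matrices."""

    group_a: str
    group_b: str
    chi_square: float
    df: int
    p_value: float
    p_adjusted: float = np.nan
    n_pairs_skipped: int = 0


def steiger_matrix_test(profile_a: CorrelationProfile, profile_b: CorrelationProfile) -> SteigerComparison:
    """Steiger-type test that two groups share a population correlation matrix.

    Each unique pair's Fisher-z difference is standardized by its asymptotic
    variance 1/(n_a - 3) + 1/(n_b - 3); the sum of squares is referred to a
    chi-square with df = p(p-1)/2 (between-group coefficients are
    independent). Pairs with undefined correlations in either matrix are
    skipped and df reduced accordingly.
    """
    if profile_a.endpoints != profile_b.endpoints:
        raise ValueError("profiles must share the same endpoints in the same order")
    iu = np.triu_indices(len(profile_a.endpoints), 1)
    ra, rb = profile_a.r[iu], profile_b.r[iu]
    ok = np.isfinite(ra) & np.isfinite(rb)
    skipped = int((~ok).sum())
    if skipped:
        logger.warning("steiger test %s vs %s: skipping %d undefined pairs",
                       profile_a.group, profile_b.group, skipped)
    za, zb = fisher_z(ra[ok]), fisher_z(rb[ok])
    var = 1.0 / (profile_a.n - 3) + 1.0 / (profile_b.n - 3)
    stat = float(np.sum((za - zb) ** 2) / var)
    df = int(ok.sum())
    return SteigerComparison(
        group_a=profile_a.group,
        group_b=profile_b.group,
        chi_square=stat,
        df=df,
        p_value=float(sps.chi2.sf(stat, df)),
        n_pairs_skipped=skipped,
    )


def steiger_all_pairs(profiles: list[CorrelationProfile], bh_m: int | None = None) -> list[SteigerComparison]:
    """All pairwise matrix comparisons, BH-adjusted across the family."""
    comps = [steiger_matrix_test(a, b) for a, b in combinations(profiles, 2)]
    adj = bh_adjust([c.p_value for c in comps], m=bh_m)
    return [
        SteigerComparison(c.group_a, c.group_b, c.chi_square, c.df, c.p_value,
                          float(pa), c.n_pairs_skipped)
        for c, pa in zip(comps, adj)
    ]


@dataclass(frozen=True)
class ProfileDistances:
    """Pairwise z-space Euclidean distances and their neighbor-joining tree."""

    labels: tuple
    distances: pd.DataFrame
    newick: str


def profile_distances(profiles: list[CorrelationProfile]) -> ProfileDistances:
    """Euclidean distances between groups in Fisher-z space, with an NJ tree.

    d(A, B) = sqrt(sum over unique pairs of (zA - zB)^2). The unrooted tree is
    built by neighbor joining (Saitou–Nei); negative branch lengths are
    clamped to zero, the standard NJ convention. Pairs undefined in any group
    are excluded from every distance so the metric stays comparable.
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 profiles for a neighbor-joining tree")
    endpoints = profiles[0].endpoints
    for p in profiles[1:]:
        if p.endpoints != endpoints:
            raise ValueError("profiles must share endpoints")
    iu = np.triu_indices(len(endpoints), 1)
    rs = np.vstack([p.r[iu] for p in profiles])
    ok = np.all(np.isfinite(rs), axis=0)
    z = fisher_z(rs[:, ok])
    labels = tuple(p.group for p in profiles)
    k = len(profiles)
    mat = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        d = float(np.sqrt(np.sum((z[i] - z[j]) ** 2)))
        mat[i, j] = mat[j, i] = d
    tree = nj(DistanceMatrix(mat, ids=list(labels)))
    newick = str(tree).strip()
    return ProfileDistances(
        labels=labels,
        distances=pd.DataFrame(mat, index=labels, columns=labels),
        newick=newick,
    )


def _extent_bin(magnitude: float) -> str:
    if magnitude <= 0.1:
        return "none"
    if magnitude <= 0.3:
        return "small"
    if magnitude <= 0.5:
        return "moderate"
    return "large"


@dataclass(frozen=True)
class EffectClassification:
    """Treatment-effect call for one endpoint pair."""

    pair: tuple
    r_ref: float
    r_dis: float
    r_trt: float
    z_ref: float = field(repr=False, default=np.nan)
    z_dis: float = field(repr=False, default=np.nan)
    z_trt: float = field(repr=False, default=np.nan)
    grand_diff_z: float = np.nan
    grand_diff_r: float = np.nan
    direction: str = "unclassifiable"
    extent: str = "none"
    score: float = 0.0


def classify_effect(
    r_ref: float,
    r_dis: float,
    r_trt: float,
    pair: tuple = ("i", "j"),
    overcorrection_mode: str = "crossing",
) -> EffectClassification:
    """Classify and score the treatment effect on one endpoint pair.

    With dz_dis = z_dis - z_ref (disease shift) and dz_trt = z_trt - z_ref
    (residual shift under treatment), the grand difference is
    dz_dis - dz_trt = z_dis - z_trt, back-transformed to the r scale for
    thresholding. Direction:

    - ``no_effect`` when |tanh(grand difference)| <= 0.1;
    - ``correction`` when the treated coefficient sits on the disease side of
      the reference (sign(dz_trt) * sign(dz_dis) >= 0) but closer to it
      (|dz_trt| < |dz_dis|);
    - ``exacerbation`` when it sits on the disease side at least as far away
      (|dz_trt| >= |dz_dis|);
    - ``overcorrection`` when the treated coefficient crossed to the opposite
      side of the reference (sign product < 0).

    Extent comes from |tanh(grand difference)| binned at 0.1/0.3/0.5, except
    for overcorrections, whose extent is the overshoot beyond the reference
    |tanh(dz_trt)|. A crossing counts as overcorrection only when the
    overshoot clears the same 0.1 dead band — a treated coefficient that
    lands within it is indistinguishable from the reference and is classified
    as a correction. ``overcorrection_mode="beyond_disease"`` selects the
    alternative reading in which a same-side shift past the disease value
    (|dz_trt| > |dz_dis|, beyond the dead band) counts as overcorrection
    rather than exacerbation, with extent from the overshoot past the disease
    value. Scores come from :data:`SCORE_GRID`.

    Missing inputs yield an ``unclassifiable`` record with score 0.
    """
    if overcorrection_mode not in ("crossing", "beyond_disease"):
        raise ValueError("overcorrection_mode must be 'crossing' or 'beyond_disease'")
    if any(not np.isfinite(v) for v in (r_ref, r_dis, r_trt)):
        return EffectClassification(pair=pair, r_ref=r_ref, r_dis=r_dis, r_trt=r_trt)
    z_ref, z_dis, z_trt = (fisher_z(v) for v in (r_ref, r_dis, r_trt))
    dz_dis = z_dis - z_ref
    dz_trt = z_trt - z_ref
    gd_z = dz_dis - dz_trt  # = z_dis - z_trt
    gd_r = inverse_fisher(gd_z)

    # overshoot must clear the same 0.1 dead band used for no-effect calls:
    # a treated coefficient statistically indistinguishable from the
    # reference is a correction, not an overcorrection
    crossed = (
        float(np.sign(dz_trt) * np.sign(dz_dis)) < 0
        and abs(inverse_fisher(dz_trt)) > 0.1
    )
    if abs(gd_r) <= 0.1:
        direction, extent = "no_effect", "none"
    elif crossed:
        direction = "overcorrection"
        extent = _extent_bin(abs(inverse_fisher(dz_trt)))
    elif (
        overcorrection_mode == "beyond_disease"
        and abs(dz_trt) > abs(dz_dis)
        and abs(inverse_fisher(dz_trt - dz_dis)) > 0.1
    ):
        direction = "overcorrection"
        extent = _extent_bin(abs(inverse_fisher(dz_trt - dz_dis)))
    elif abs(dz_trt) < abs(dz_dis):
        direction, extent = "correction", _extent_bin(abs(gd_r))
    else:
        direction, extent = "exacerbation", _extent_bin(abs(gd_r))

    return EffectClassification(
        pair=pair, r_ref=r_ref, r_dis=r_dis, r_trt=r_trt,
        z_ref=z_ref, z_dis=z_dis, z_trt=z_trt,
        grand_diff_z=gd_z, grand_diff_r=gd_r,
        direction=direction, extent=extent, score=SCORE_GRID[(direction, extent)],
    )


@dataclass(frozen=True)
class ProfileReport:
    """Pair-by-pair effect classifications with tallies and the overall score."""

    classifications: tuple
    counts: pd.DataFrame
    overall_score: float
    n_unclassifiable: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "endpoint_i": c.pair[0],
                    "endpoint_j": c.pair[1],
                    "r_ref": c.r_ref,
                    "r_dis": c.r_dis,
                    "r_trt": c.r_trt,
                    "grand_diff_r": c.grand_diff_r,
                    "direction": c.direction,
                    "extent": c.extent,
                    "score": c.score,
                }
                for c in self.classifications
            ]
        )


def profile_report(
    reference: CorrelationProfile,
    disease: CorrelationProfile,
    treated: CorrelationProfile,
    overcorrection_mode: str = "crossing",
) -> ProfileReport:
    """Classify every unique endpoint pair and total the treatment score.

    Pairs with undefined correlations in any group are counted as
    unclassifiable (score 0) rather than dropped silently; no-effect pairs
    remain in the tally.
    """
    for p in (disease, treated):
        if p.endpoints != reference.endpoints:
            raise ValueError("profiles must share endpoints")
    classifications = []
    for i, j in combinations(range(len(reference.endpoints)), 2):
        pair = (reference.endpoints[i], reference.endpoints[j])
        classifications.append(
            classify_effect(
                reference.r[i, j], disease.r[i, j], treated.r[i, j],
                pair=pair, overcorrection_mode=overcorrection_mode,
            )
        )
    tally = (
        pd.DataFrame(
            [(c.direction, c.extent) for c in classifications],
            columns=["direction", "extent"],
        )
        .value_counts()
        .rename("count")
        .reset_index()
    )
    n_unclass = sum(1 for c in classifications if c.direction == "unclassifiable")
    return ProfileReport(
        classifications=tuple(classifications),
        counts=tally,
        overall_score=float(sum(c.score for c in classifications)),
        n_unclassifiable=n_unclass,
    )
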