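import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

from oxprofile.profiles import (
    SCORE_GRID,
    CorrelationProfile,
    classify_effect,
    correlation_matrix,
    fisher_z,
    inverse_fisher,
    profile_distances,
    profile_report,
    steiger_all_pairs,
    steiger_matrix_test,
)


def _profile(r, group="g", n=28, endpoints=None):
    r = np.asarray(r, dtype=float)
    endpoints = endpoints or tuple(f"e{i}" for i in range(r.shape[0]))
    return CorrelationProfile(group=group, endpoints=tuple(endpoints), r=r, n=n)


def _corr2(r):
    return np.array([[1.0, r], [r, 1.0]])


def _random_profile(rng, p=4, n=30, group="g"):
    x = rng.standard_normal((n, p))
    return _profile(np.corrcoef(x, rowvar=False), group=group, n=n)


class TestCorrelationMatrix:
    @staticmethod
    def _table(values):
        rows = []
        for si, vals in enumerate(values):
            for ei, v in enumerate(vals):
                rows.append({"group": "g", "subject": f"s{si}", "endpoint": f"e{ei}",
                             "value": v})
        return pd.DataFrame(rows)

    def test_collinear_pair_r_is_one(self):
        vals = [[x, 2 * x + 1, 9 - x] for x in (1.0, 2.0, 4.0, 7.0, 8.0)]
        prof = correlation_matrix(self._table(vals), "g")
        assert prof.r[0, 1] == pytest.approx(1.0)
        assert prof.r[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_pairwise_formula(self):
        vals = [[1.0, 4.0, 2.0], [2.0, 2.0, 5.0], [4.0, 7.0, 3.0],
                [6.0, 1.0, 8.0], [9.0, 5.0, 4.0]]
        prof = correlation_matrix(self._table(vals), "g")
        x = np.asarray(vals)
        for i in range(3):
            for j in range(3):
                xi, xj = x[:, i], x[:, j]
                num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                den = np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                assert prof.r[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_independent_endpoints_near_zero(self, rng):
        n = 2000
        rows = []
        for ei in range(4):
            vals = rng.normal(0, 1, n)
            rows.append(pd.DataFrame({"group": "g", "subject": np.arange(n),
                                      "endpoint": f"e{ei}", "value": vals}))
        prof = correlation_matrix(pd.concat(rows), "g")
        assert np.max(np.abs(prof.r[np.triu_indices(4, 1)])) < 0.05

    def test_requires_four_subjects(self):
        vals = [[1.0, 2.0], [2.0, 3.0], [3.0, 4.0]]
        with pytest.raises(ValueError, match=">= 4"):
            correlation_matrix(self._table(vals), "g")


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert inverse_fisher(fisher_z(0.9)) == pytest.approx(0.9)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError, match="clip"):
            fisher_z(1.0)

    @given(st.floats(-0.999, 0.999))
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_round_trip_identity(self, r):
        assert inverse_fisher(fisher_z(r)) == pytest.approx(r, abs=1e-12)


class TestSteiger:
    def test_identical_matrices_null(self):
        prof = _profile(_corr2(0.4))
        res = steiger_matrix_test(prof, _profile(_corr2(0.4), group="h"))
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_closed_form_single_coefficient(self):
        res = steiger_matrix_test(
            _profile(_corr2(0.5), group="a", n=28), _profile(_corr2(0.0), group="b", n=28)
        )
        assert res.df == 1
        assert res.chi_square == pytest.approx(np.arctanh(0.5) ** 2 / (2 / 25), rel=1e-6)
        assert res.chi_square == pytest.approx(3.772, abs=2e-3)

    def test_df_counts_unique_pairs(self):
        p = 7
        prof_a = _profile(np.eye(p), group="a")
        prof_b = _profile(np.eye(p), group="b")
        assert steiger_matrix_test(prof_a, prof_b).df == p * (p - 1) // 2

    def test_mismatched_endpoints_rejected(self):
        a = _profile(_corr2(0.1), endpoints=("x", "y"))
        b = _profile(_corr2(0.1), endpoints=("x", "z"))
        with pytest.raises(ValueError, match="endpoints"):
            steiger_matrix_test(a, b)

    def test_invariant_under_endpoint_relabeling(self, rng):
        pa, pb = _random_profile(rng, group="a"), _random_profile(rng, group="b")
        perm = rng.permutation(4)
        pa_p = _profile(pa.r[np.ix_(perm, perm)], group="a",
                        endpoints=tuple(np.array(pa.endpoints)[perm]), n=pa.n)
        pb_p = _profile(pb.r[np.ix_(perm, perm)], group="b",
                        endpoints=tuple(np.array(pb.endpoints)[perm]), n=pb.n)
        assert steiger_matrix_test(pa, pb).chi_square == pytest.approx(
            steiger_matrix_test(pa_p, pb_p).chi_square, rel=1e-12
        )

    def test_bh_adjustment_across_pairs(self, rng):
        profs = [_random_profile(rng, group=g) for g in "abc"]
        comps = steiger_all_pairs(profs)
        assert len(comps) == 3
        assert all(c.p_adjusted >= c.p_value for c in comps)


class TestProfileDistances:
    def test_identical_profiles_zero_distance(self):
        profs = [_profile(_corr2(0.3), group=g) for g in "abc"]
        d = profile_distances(profs)
        assert np.allclose(d.distances.to_numpy(), 0.0)

    def test_three_leaf_closed_form(self, rng):
        # choose z-space correlations giving distances AB=2, AC=3, BC=4 is
        # impossible for 1 coefficient; instead verify on an arbitrary triple
        profs = [_random_profile(rng, group=g) for g in "abc"]
        d = profile_distances(profs)
        tree = TreeNode.read([d.newick])
        dm = d.distances
        for leaf in tree.tips():
            others = [t for t in tree.tips() if t.name != leaf.name]
            i, j = others[0].name, others[1].name
            expected = (dm.loc[leaf.name, i] + dm.loc[leaf.name, j] - dm.loc[i, j]) / 2
            assert leaf.length == pytest.approx(expected, abs=1e-10)

    def test_four_leaf_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distance matrix
        dist = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        from skbio import DistanceMatrix
        from skbio.tree import nj

        labels = ["A", "B", "C", "D"]
        mat = np.zeros((4, 4))
        for (a, b), v in dist.items():
            i, j = labels.index(a), labels.index(b)
            mat[i, j] = mat[j, i] = v
        tree = nj(DistanceMatrix(mat, ids=labels))
        for (a, b), v in dist.items():
            ta = tree.find(a)
            assert ta.distance(tree.find(b)) == pytest.approx(v, abs=1e-10)

    def test_metric_axioms_on_random_profiles(self, rng):
        profs = [_random_profile(rng, group=f"g{i}") for i in range(4)]
        d = profile_distances(profs[:3]).distances.to_numpy()
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert np.all(d[np.triu_indices(3, 1)] >= 0)
        # triangle inequality over the three groups
        assert d[0, 1] <= d[0, 2] + d[2, 1] + 1e-12
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12
        assert d[1, 2] <= d[1, 0] + d[0, 2] + 1e-12


class TestClassifyEffect:
    def test_full_restoration_is_large_correction(self):
        c = classify_effect(0.8, 0.0, 0.8)
        assert c.direction == "correction" and c.extent == "large" and c.score == 3.0
        assert c.grand_diff_r == pytest.approx(-0.8)

    def test_no_change_is_no_effect(self):
        c = classify_effect(0.4, 0.4, 0.4)
        assert c.direction == "no_effect" and c.score == 0.0

    def test_crossing_reference_is_overcorrection(self):
        c = classify_effect(0.0, 0.5, -0.4)
        assert c.direction == "overcorrection"
        # overshoot beyond reference: |tanh(z_trt - z_ref)| = 0.4 -> moderate
        assert c.extent == "moderate" and c.score == 1.0

    def test_beyond_disease_mode_reclassifies_same_side_overshoot(self):
        # treated moved past the disease value on the same side of reference
        c = classify_effect(0.5, 0.0, -0.4)
        assert c.direction == "exacerbation"
        c2 = classify_effect(0.5, 0.0, -0.4, overcorrection_mode="beyond_disease")
        assert c2.direction == "overcorrection"

    def test_worsening_is_exacerbation(self):
        c = classify_effect(0.0, 0.4, 0.7)
        assert c.direction == "exacerbation"
        # grand difference tanh(z(0.4) - z(0.7)) ~ -0.38 -> moderate
        assert c.extent == "moderate" and c.score == -2.0

    def test_grand_difference_antisymmetric_in_disease_treated_swap(self):
        a = classify_effect(0.2, 0.6, -0.1)
        b = classify_effect(0.2, -0.1, 0.6)
        assert a.grand_diff_z == pytest.approx(-b.grand_diff_z)

    def test_missing_input_unclassifiable(self):
        c = classify_effect(0.2, np.nan, 0.1)
        assert c.direction == "unclassifiable" and c.score == 0.0

    @given(
        st.floats(-0.98, 0.98), st.floats(-0.98, 0.98), st.floats(-0.98, 0.98),
        st.sampled_from(["crossing", "beyond_disease"]),
    )
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_exhaustive_and_uniquely_scored(self, r_ref, r_dis, r_trt, mode):
        c = classify_effect(r_ref, r_dis, r_trt, overcorrection_mode=mode)
        assert c.direction in {"no_effect", "correction", "exacerbation", "overcorrection"}
        assert (c.direction, c.extent) in SCORE_GRID
        assert c.score == SCORE_GRID[(c.direction, c.extent)]


class TestProfileReport:
    def test_seven_endpoints_give_21_pairs(self, rng):
        profs = [_random_profile(rng, p=7, group=g) for g in "abc"]
        rep = profile_report(*profs)
        assert len(rep.classifications) == 21
        assert rep.counts["count"].sum() == 21
        assert rep.overall_score == pytest.approx(
            sum(c.score for c in rep.classifications)
        )

    def test_planted_structure_recovered(self):
        from oxprofile.synthetic import GroupModel, StudyDesign, generate_endpoint_table

        p = 6

        def corr(pairs):
            r = np.eye(p)
            for (i, j), v in pairs.items():
                r[i, j] = r[j, i] = v
            return r

        # two large corrections on pairs (0,1) and (2,3); one small
        # exacerbation on (4,5); values sit several sampling SDs away from
        # every category boundary at this n
        ref = corr({(0, 1): 0.85, (2, 3): 0.85, (4, 5): 0.0})
        dis = corr({(0, 1): 0.0, (2, 3): 0.0, (4, 5): 0.15})
        trt = corr({(0, 1): 0.7, (2, 3): 0.7, (4, 5): 0.34})
        endpoints = tuple(f"e{i}" for i in range(p))
        design = StudyDesign(
            groups=("ref", "dis", "trt"), n_subjects=1000, n_replicates=1,
            endpoints=endpoints, seed=42,
        )
        # means well above 0 so physical truncation never bites
        models = {
            g: GroupModel((10.0,) * p, (1.0,) * p, r, replicate_noise_frac=0.0)
            for g, r in [("ref", ref), ("dis", dis), ("trt", trt)]
        }
        table = generate_endpoint_table(design, models)
        profs = {g: correlation_matrix(table, g) for g in ("ref", "dis", "trt")}
        rep = profile_report(profs["ref"], profs["dis"], profs["trt"])
        by_pair = {c.pair: c for c in rep.classifications}
        assert by_pair[("e0", "e1")].direction == "correction"
        assert by_pair[("e0", "e1")].extent == "large"
        assert by_pair[("e2", "e3")].direction == "correction"
        assert by_pair[("e2", "e3")].extent == "large"
        assert by_pair[("e4", "e5")].direction == "exacerbation"
        assert by_pair[("e4", "e5")].extent == "small"

    def test_shared_population_matrix_scores_near_zero(self):
        from oxprofile.synthetic import GroupModel, StudyDesign, generate_endpoint_table

        p = 7
        r = np.eye(p)
        r[0, 1] = r[1, 0] = 0.3
        endpoints = tuple(f"e{i}" for i in range(p))
        design = StudyDesign(groups=("ref", "dis", "trt"), n_subjects=2000,
                             n_replicates=1, endpoints=endpoints, seed=7)
        models = {g: GroupModel((10.0,) * p, (1.0,) * p, r, 0.0)
                  for g in ("ref", "dis", "trt")}
        table = generate_endpoint_table(design, models)
        profs = {g: correlation_matrix(table, g) for g in ("ref", "dis", "trt")}
        rep = profile_report(profs["ref"], profs["dis"], profs["trt"])
        assert -1.0 <= rep.overall_score <= 1.0
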