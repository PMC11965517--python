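"""Correlations, group comparisons, three-level meta-analysis, BH correction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdelay.association import (
    AssociationResult,
    UndefinedCorrelationError,
    adjust_multiplicity,
    compare_groups,
    correlate_age,
    correlate_with_shifts,
    dl_pool,
    pool_domain,
    subgroup_labels,
)


def _res(outcome, cohort, r, n, kind="pearson"):
    z = float(np.arctanh(r))
    return AssociationResult(
        outcome=outcome, cohort=cohort, coefficient=r, coefficient_kind=kind,
        n=n, z=z, se_z=1 / np.sqrt(n - 3), p=0.5,
    )


class TestCorrelations:
    def test_perfect_linearity_gives_one(self):
        shifts = np.array([0.0, 1.0, 2.0, 3.0])
        res = correlate_with_shifts(2 * shifts + 1, shifts, "pearson")
        assert res.coefficient == pytest.approx(1.0)

    def test_point_biserial_equals_pearson_on_01(self):
        rng = np.random.default_rng(0)
        v = rng.integers(0, 2, 30).astype(float)
        d = rng.normal(size=30) + v
        pb = correlate_with_shifts(v, d, "point_biserial")
        pe = correlate_with_shifts(v, d, "pearson")
        assert pb.coefficient == pytest.approx(pe.coefficient, rel=1e-12)

    def test_tau_b_matches_pair_counting(self):
        # values (1,2,3,4) vs shifts (1,3,2,4): 5 concordant, 1 discordant
        res = correlate_with_shifts([1, 2, 3, 4], [1, 3, 2, 4], "kendall_tau_b")
        assert res.coefficient == pytest.approx(4 / 6)

    def test_probabilities_dichotomized_for_point_biserial(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=40)
        probs = 1 / (1 + np.exp(-d)) * 0.9 + 0.05
        res = correlate_with_shifts(probs, d, "point_biserial")
        expected = stats.pointbiserialr((probs >= 0.5).astype(float), d)
        assert res.coefficient == pytest.approx(expected.statistic)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_with_shifts([1.0, 1.0, 1.0], [0.0, 1.0, 2.0], "pearson")

    @pytest.mark.parametrize("kind", ["pearson", "kendall_tau_b"])
    def test_exhaustive_small_instances_match_brute_force(self, kind):
        """All 5-point integer vectors from a fixed grid vs scipy-free oracles."""
        grid = [(0, 1, 2, 3, 4), (1, 1, 2, 3, 5), (4, 2, 0, 3, 1), (0, 2, 2, 3, 3)]
        for v, d in itertools.product(grid, repeat=2):
            v = np.array(v, float)
            d = np.array(d, float)
            if np.ptp(v) == 0 or np.ptp(d) == 0:
                continue
            got = correlate_with_shifts(v, d, kind).coefficient
            if kind == "pearson":
                vc, dc = v - v.mean(), d - d.mean()
                expected = (vc @ dc) / np.sqrt((vc @ vc) * (dc @ dc))
            else:
                conc = disc = tx = ty = 0
                for i in range(5):
                    for j in range(i + 1, 5):
                        sv = np.sign(v[i] - v[j])
                        sd = np.sign(d[i] - d[j])
                        if sv == 0 and sd == 0:
                            continue
                        if sv == 0:
                            tx += 1
                        elif sd == 0:
                            ty += 1
                        elif sv == sd:
                            conc += 1
                        else:
                            disc += 1
                n0 = conc + disc + tx + ty
                expected = (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))
            assert got == pytest.approx(expected, rel=1e-12), (v, d, kind)


class TestAgeCorrelation:
    def test_null_generator_near_zero(self):
        rng = np.random.default_rng(2)
        n = 400
        age = rng.normal(63, 9, n)
        shifts = rng.normal(0, 1.5, n)
        res = correlate_age(shifts, age)
        assert abs(res.coefficient) < 2 / np.sqrt(n) + 0.15  # delta in both terms

    def test_age_dependent_shifts_detected(self):
        rng = np.random.default_rng(3)
        n = 300
        age = rng.normal(63, 9, n)
        shifts = 0.05 * (age - 63) + rng.normal(0, 1.0, n)
        res = correlate_age(shifts, age)
        assert res.coefficient > 0
        assert res.p < 0.05

    def test_constant_age_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_age(np.zeros(10), np.full(10, 60.0))

    def test_adjusted_fit_misuse_warns(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="covariate-adjusted"):
            correlate_age(
                rng.normal(size=50), rng.normal(60, 5, 50),
                from_covariate_adjusted_fit=True,
            )


class TestGroupComparisons:
    def test_identical_groups_null_result(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        d = np.concatenate([x, x])
        labels = ["a"] * 40 + ["b"] * 40
        res = compare_groups(d, labels)
        assert res.test_used == "t"
        assert res.cohens_d == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_cohens_d_definition(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(0.0, 1.0, 20000)
        g2 = rng.normal(0.22, 1.0, 20000)
        res = compare_groups(
            np.concatenate([g2, g1]), ["fast"] * 20000 + ["slow"] * 20000
        )
        assert res.cohens_d == pytest.approx(0.22, abs=0.03)

    def test_skewed_data_routes_to_mwu(self):
        rng = np.random.default_rng(7)
        g1 = rng.exponential(1.0, 80)
        g2 = rng.exponential(2.0, 80)
        res = compare_groups(np.concatenate([g1, g2]), ["a"] * 80 + ["b"] * 80)
        assert res.test_used == "mwu"

    def test_unequal_variances_route_to_welch(self):
        rng = np.random.default_rng(8)
        g1 = rng.normal(0, 1.0, 200)
        g2 = rng.normal(0.3, 3.0, 200)
        res = compare_groups(np.concatenate([g1, g2]), ["a"] * 200 + ["b"] * 200)
        assert res.test_used == "welch"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.arange(5.0), ["a"] * 5)


class TestMetaAnalysis:
    def test_single_study_passthrough(self):
        results = [_res("o1", "c1", 0.3, 100)]
        metas = pool_domain(results, {"o1": "dom"})
        m = metas[0]
        assert m.pooled_coefficient == pytest.approx(0.3, abs=1e-9)
        assert m.no_pooling
        z, se = np.arctanh(0.3), 1 / np.sqrt(97)
        assert m.ci_low == pytest.approx(np.tanh(z - 1.959964 * se), abs=1e-6)
        assert m.ci_high == pytest.approx(np.tanh(z + 1.959964 * se), abs=1e-6)

    def test_identical_effects_pool_to_same_with_narrower_ci(self):
        results = [_res("o1", "c1", 0.3, 100), _res("o1", "c2", 0.3, 100)]
        metas = pool_domain(results, {"o1": "dom"})
        m = metas[0]
        single = pool_domain([results[0]], {"o1": "dom"})[0]
        assert m.pooled_coefficient == pytest.approx(0.3, abs=1e-9)
        assert (m.ci_high - m.ci_low) < (single.ci_high - single.ci_low)

    def test_two_step_pooling_matches_hand_dl(self):
        """Three heterogeneous cohorts, two outcomes each, vs a hand-rolled
        two-stage DerSimonian-Laird computation."""
        rs = {
            "c1": [0.10, 0.30], "c2": [0.25, 0.45], "c3": [-0.05, 0.20],
        }
        ns = {"c1": [80, 120], "c2": [60, 200], "c3": [150, 90]}
        results = [
            _res(f"o{j}", c, rs[c][j], ns[c][j])
            for c in rs for j in range(2)
        ]
        metas = pool_domain(results, {"o0": "dom", "o1": "dom"})
        m = metas[0]

        def dl(y, v):
            y, v = np.asarray(y), np.asarray(v)
            w = 1 / v
            fe = np.sum(w * y) / np.sum(w)
            q = np.sum(w * (y - fe) ** 2)
            tau2 = max(0.0, (q - (len(y) - 1)) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
            ws = 1 / (v + tau2)
            return np.sum(ws * y) / np.sum(ws), 1 / np.sqrt(np.sum(ws))

        level2 = {}
        for c in rs:
            y = [np.arctanh(r) for r in rs[c]]
            v = [1 / (n - 3) for n in ns[c]]
            level2[c] = dl(y, v)
        pooled, se = dl([level2[c][0] for c in rs], [level2[c][1] ** 2 for c in rs])
        assert m.pooled_z == pytest.approx(pooled, rel=1e-10)
        assert m.pooled_se_z == pytest.approx(se, rel=1e-10)
        assert m.pooled_coefficient == pytest.approx(np.tanh(pooled), rel=1e-10)

    def test_dl_matches_statsmodels(self):
        """Independent oracle: statsmodels' DerSimonian-Laird pooling."""
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        rng = np.random.default_rng(9)
        y = rng.normal(0.2, 0.1, 6)
        v = rng.uniform(0.005, 0.02, 6)
        pooled, se, tau2 = dl_pool(y, v)
        res = sm_meta.combine_effects(y, v, method_re="dl")
        assert tau2 == pytest.approx(res.tau2, rel=1e-8)
        df = res.summary_frame()
        assert pooled == pytest.approx(df.loc["random effect", "eff"], rel=1e-8)

    def test_pooling_invariant_to_orderings(self):
        rng = np.random.default_rng(10)
        results = [
            _res(f"o{j}", c, rng.uniform(-0.3, 0.5), int(rng.integers(40, 200)))
            for c in ("c1", "c2", "c3") for j in range(3)
        ]
        dm = {f"o{j}": "dom" for j in range(3)}
        m1 = pool_domain(results, dm)[0]
        m2 = pool_domain(results[::-1], dm)[0]
        assert m1.pooled_coefficient == pytest.approx(m2.pooled_coefficient, rel=1e-12)
        assert m1.ci_low == pytest.approx(m2.ci_low, rel=1e-12)

    def test_unmapped_outcome_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            pool_domain([_res("o1", "c1", 0.3, 50)], {"other": "dom"})


class TestMultiplicity:
    @staticmethod
    def _metas(ps):
        metas = []
        for i, p in enumerate(ps):
            m = pool_domain([_res("o", "c", 0.2, 100)], {"o": f"d{i}"})[0]
            m.domain = f"d{i}"
            m.p = p
            metas.append(m)
        return metas

    def test_bh_arithmetic(self):
        out = adjust_multiplicity(self._metas([0.01, 0.02, 0.03]))
        assert [m.p_adjusted for m in out] == pytest.approx([0.03, 0.03, 0.03])

    def test_single_domain_unchanged(self):
        out = adjust_multiplicity(self._metas([0.04]))
        assert out[0].p_adjusted == pytest.approx(0.04)

    def test_monotonicity_enforcement(self):
        out = adjust_multiplicity(self._metas([0.005, 0.01]))
        assert [m.p_adjusted for m in out] == pytest.approx([0.01, 0.01])

    def test_matches_brute_force_step_up(self):
        """Hand-coded BH step-up on random p-vectors."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            ps = rng.uniform(0, 1, rng.integers(2, 12))
            out = adjust_multiplicity(self._metas(ps))
            m = len(ps)
            order = np.argsort(ps)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                idx = order[rank - 1]
                running = min(running, ps[idx] * m / rank)
                adj[idx] = running
            assert [x.p_adjusted for x in out] == pytest.approx(list(adj))
            # monotone and never below raw
            assert all(x.p_adjusted >= x.p - 1e-15 for x in out)

    def test_ci_level_tracks_attained_cutoff(self):
        out = adjust_multiplicity(self._metas([1e-6, 1e-5, 0.9]))
        # k* = 2 of m = 3 -> level = 1 - 0.05*2/3
        assert out[0].ci_level == pytest.approx(1 - 0.05 * 2 / 3)
        sig = [m for m in out if m.significant]
        assert len(sig) == 2


class TestSubgroups:
    @staticmethod
    def _individuals(ages):
        return pd.DataFrame(
            {"age_at_diagnosis": ages, "sex": ["male"] * len(ages)},
            index=pd.Index([f"p{i}" for i in range(len(ages))], name="individual_id"),
        )

    def test_median_split(self):
        lab = subgroup_labels(self._individuals([50.0, 60.0, 70.0, 80.0]), "median_age")
        assert list(lab) == ["younger", "younger", "older", "older"]

    @pytest.mark.parametrize(
        "age, expected", [(49.0, "eopd"), (55.0, None), (61.0, "lopd")]
    )
    def test_eopd_lopd_bounds(self, age, expected):
        lab = subgroup_labels(self._individuals([age]), "eopd_lopd")
        if expected is None:
            assert pd.isna(lab.iloc[0])
        else:
            assert lab.iloc[0] == expected

    def test_small_subgroup_skipped(self):
        from pdelay.association import subgroup_analysis

        rng = np.random.default_rng(12)
        n = 40
        ages = np.concatenate([rng.normal(45, 2, 10), rng.normal(70, 3, 30)])
        individuals = self._individuals(ages)
        mat = pd.DataFrame(
            {"y": rng.normal(size=n)}, index=individuals.index
        )
        shifts = pd.Series(rng.normal(size=n), index=individuals.index)
        out = subgroup_analysis(
            {"c1": {"manifestation": mat, "shifts": shifts,
                    "individuals": individuals}},
            split="eopd_lopd",
            domain_map={"y": "dom"},
            kinds={"y": "pearson"},
            min_n=30,
        )
        assert out["eopd"]["skipped_cohorts"] == ["c1"]
        assert out["eopd"]["meta"] == []
        assert len(out["lopd"]["associations"]) == 1
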