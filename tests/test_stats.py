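"""Matched-pair statistics: paired t, conditional logistic regression
(vs brute-force likelihood oracle), BMI categories, Kruskal-Wallis."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata

from vkrpipe import (
    PairedComparison,
    SeparationError,
    bmi_adjustment_covariates,
    bmi_category,
    build_table,
    clogit_1to1,
    kruskal_wallis,
    paired_t,
)


def brute_force_clogit_beta(d: np.ndarray) -> float:
    """Maximize the written 1:1 conditional likelihood directly."""

    def nll(beta):
        return float(np.sum(np.log1p(np.exp(-beta * d))))

    res = minimize_scalar(nll, bounds=(-30.0, 30.0), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)


class TestPairedT:
    def test_zero_mean_differences(self):
        t, p, df = paired_t([1, 0, 1, 0], [0, 1, 0, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        t, p, df = paired_t([1, 2, 3], [0, 0, 0])
        assert t == pytest.approx(2 / (1 / math.sqrt(3)), abs=1e-4)  # 3.4641
        assert df == 2

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1], [0])

    def test_constant_differences_rejected(self):
        with pytest.raises(ValueError):
            paired_t([2, 3, 4], [1, 2, 3])


class TestBmiAdjustment:
    @pytest.mark.parametrize(
        "bmi,cat", [(20.0, 0), (24.9, 0), (25.0, 1), (29.9, 1), (30.0, 2), (40.0, 2)]
    )
    def test_category_boundaries(self, bmi, cat):
        assert bmi_category(bmi) == cat

    def test_same_category_gives_zero_vector(self):
        assert np.array_equal(bmi_adjustment_covariates(24, 24), [0.0, 0.0])

    def test_obese_vs_overweight(self):
        assert np.array_equal(bmi_adjustment_covariates(31, 26), [-1.0, 1.0])


class TestClogit:
    def test_symmetric_differences_give_null_or(self):
        fit = clogit_1to1([1, -1, 1, -1], [0, 0, 0, 0], scale_sd=1.0)
        assert fit.beta_exposure == pytest.approx(0.0, abs=1e-9)
        assert fit.or_per_sd == pytest.approx(1.0, abs=1e-9)

    def test_monotone_likelihood_raises_separation(self):
        with pytest.raises(SeparationError):
            clogit_1to1([1, 1, 1], [0, 0, 0], scale_sd=1.0)

    def test_all_zero_differences_raise(self):
        with pytest.raises(SeparationError):
            clogit_1to1([1, 1], [1, 1], scale_sd=1.0)

    def test_small_instance_matches_brute_force(self):
        d = np.array([2.0, 2.0, -1.0])
        fit = clogit_1to1(d, np.zeros(3), scale_sd=1.0)
        assert fit.beta_exposure == pytest.approx(brute_force_clogit_beta(d), abs=1e-6)

    def test_random_small_instances_match_brute_force(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 60:
            n = int(rng.integers(2, 6))
            d = rng.integers(-3, 4, size=n).astype(float)
            if np.all(d >= 0) or np.all(d <= 0):
                continue
            fit = clogit_1to1(d, np.zeros(n), scale_sd=1.0)
            assert fit.beta_exposure == pytest.approx(
                brute_force_clogit_beta(d), abs=1e-6
            )
            checked += 1

    def test_or_invariant_to_common_scaling(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.3, 1.0, size=50)
        base = clogit_1to1(d, np.zeros(50), scale_sd=0.7)
        for c in (0.01, 3.0, 250.0):
            scaled = clogit_1to1(c * d, np.zeros(50), scale_sd=0.7 * c)
            assert scaled.beta_exposure == pytest.approx(
                base.beta_exposure, abs=1e-10
            )

    def test_invalid_scale_sd_rejected(self):
        with pytest.raises(ValueError):
            clogit_1to1([1, -1], [0, 0], scale_sd=0.0)

    def test_adjusted_model_recovers_exposure_with_balanced_covariate(self):
        rng = np.random.default_rng(5)
        n = 2000
        d = rng.normal(0.4, 1.0, size=n)
        cov = rng.choice([-1.0, 0.0, 1.0], size=(n, 1))
        fit = clogit_1to1(d, np.zeros(n), scale_sd=1.0, covariate_diffs=cov)
        assert fit.beta.shape == (2,)
        un = clogit_1to1(d, np.zeros(n), scale_sd=1.0)
        assert fit.beta_exposure == pytest.approx(un.beta_exposure, abs=0.1)

    def test_cluster_aggregation_changes_robust_variance_only(self):
        rng = np.random.default_rng(7)
        n = 200
        # Two pairs per participant with identical differences: strong
        # positive within-cluster correlation inflates the robust SE.
        d_half = rng.normal(0.3, 1.0, size=n // 2)
        d = np.repeat(d_half, 2)
        case_ids = [f"K{i}" for i in range(n)]
        ctrl_ids = [f"C{i}" for i in range(n)]
        clusters = {f"K{i}": f"P{i // 2}" for i in range(n)}
        clusters.update({f"C{i}": f"Q{i}" for i in range(n)})
        clustered = clogit_1to1(
            d, np.zeros(n), 1.0, case_ids=case_ids, control_ids=ctrl_ids,
            clusters=clusters,
        )
        independent = clogit_1to1(d, np.zeros(n), 1.0)
        assert clustered.beta_exposure == pytest.approx(independent.beta_exposure)
        assert np.allclose(clustered.cov_model, independent.cov_model)
        assert clustered.se(robust=True) > independent.se(robust=True)
        assert clustered.n_clusters == n // 2


class TestKruskalWallis:
    def test_exchangeable_groups(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic_separated_groups(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(12 / 42 * (3 * 2.25 + 3 * 2.25))  # 3.8571

    def test_all_identical_values_give_null_result(self):
        assert kruskal_wallis([5, 5, 5], [5, 5]) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([], [1, 2])

    def test_tied_data_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(21)
        a = rng.integers(0, 4, size=12).astype(float)
        b = rng.integers(1, 5, size=10).astype(float)
        h_obs, p_chi2 = kruskal_wallis(a, b)
        combined = np.concatenate([a, b])
        n_a = a.size

        def h_of(perm):
            ranks = rankdata(perm)
            n = perm.size
            r_a, r_b = ranks[:n_a], ranks[n_a:]
            h = 12 / (n * (n + 1)) * (
                r_a.size * (r_a.mean() - (n + 1) / 2) ** 2
                + r_b.size * (r_b.mean() - (n + 1) / 2) ** 2
            )
            _, counts = np.unique(perm, return_counts=True)
            tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
            return h / tie

        assert h_of(combined) == pytest.approx(h_obs, abs=1e-9)
        draws = np.array(
            [h_of(rng.permutation(combined)) for _ in range(10_000)]
        )
        p_perm = float(np.mean(draws >= h_obs - 1e-12))
        se = math.sqrt(p_perm * (1 - p_perm) / draws.size) + 1e-4
        # Chi-square approximation should sit near the permutation truth.
        assert abs(p_perm - p_chi2) < max(0.03, 4 * se)


class TestBuildTable:
    def test_empty_pairs_give_empty_table(self):
        assert build_table([], {}, ["cMFTC"], [(24, 48)]) == []

    def test_row_composes_individual_statistics(self, make_knee):
        from vkrpipe import MatchedPair, REGIONS, interval_change

        rng = np.random.default_rng(4)
        knees = {}
        pairs = []
        for i in range(12):
            case_id, ctrl_id = f"P0{i:02d}1-R", f"P9{i:02d}1-R"
            th_case = {
                24: 1500.0,
                48: 1500.0 + float(rng.normal(-80, 120)),
            }
            th_ctrl = {24: 1500.0, 48: 1500.0 + float(rng.normal(-10, 100))}
            knees[case_id] = make_knee(case_id, thickness=th_case)
            knees[ctrl_id] = make_knee(ctrl_id, thickness=th_ctrl)
            pairs.append(
                MatchedPair(case_id, ctrl_id, "F", 60, 60, "2", "medial", 0.0)
            )
        rows = build_table(pairs, knees, ["cMFTC"], [(24, 48)])
        assert len(rows) == 2  # unadjusted + adjusted
        row = rows[0]
        case_vals = [
            interval_change(knees[p.case_knee_id], REGIONS["cMFTC"], 24, 48).delta
            for p in pairs
        ]
        ctrl_vals = [
            interval_change(knees[p.control_knee_id], REGIONS["cMFTC"], 24, 48).delta
            for p in pairs
        ]
        t, p_t, _ = paired_t(case_vals, ctrl_vals)
        assert row.n_pairs == 12
        assert row.case_mean == pytest.approx(np.mean(case_vals))
        assert row.t_stat == pytest.approx(t)
        assert row.t_pvalue == pytest.approx(p_t)
        sd = float(np.std(ctrl_vals, ddof=1))
        fit = clogit_1to1(
            -np.asarray(case_vals), -np.asarray(ctrl_vals), sd
        )
        assert row.or_per_sd == pytest.approx(fit.or_per_sd)
        # Same-category BMIs everywhere: adjusted row equals unadjusted.
        assert rows[1].adjusted and rows[1].or_per_sd == pytest.approx(row.or_per_sd)

    def test_pairwise_complete_rows(self, make_knee):
        from vkrpipe import MatchedPair

        knees = {
            "P0001-R": make_knee("P0001-R", unreadable=(48,)),
            "P9001-R": make_knee("P9001-R"),
            "P0002-R": make_knee(
                "P0002-R", thickness={24: 1500.0, 48: 1400.0}
            ),
            "P9002-R": make_knee("P9002-R"),
            "P0003-R": make_knee(
                "P0003-R", thickness={24: 1500.0, 48: 1450.0}
            ),
            "P9003-R": make_knee(
                "P9003-R", thickness={24: 1500.0, 48: 1490.0}
            ),
        }
        pairs = [
            MatchedPair(f"P000{i}-R", f"P900{i}-R", "F", 60, 60, "2", "medial", 0.0)
            for i in (1, 2, 3)
        ]
        rows = build_table(pairs, knees, ["cMFTC"], [(24, 48)])
        assert rows and all(r.n_pairs == 2 for r in rows)


def test_paired_comparison_invariants():
    with pytest.raises(ValueError):
        PairedComparison(
            "cMFTC", 24, 48, 1, 0, 1, 0, 1, None, None, None, None, None, None
        )
    with pytest.raises(ValueError):
        PairedComparison(
            "cMFTC", 24, 48, 5, 0, 1, 0, 1, None, None, beta=0.5,
            or_per_sd=2.0, ci95_low=1.0, ci95_high=3.0,
        )
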