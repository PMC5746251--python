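"""Objective, AICc, optimizer plumbing, cross-validation and noise ceiling."""

import math

import numpy as np
import pandas as pd
import pytest

from vplsearch import (
    BehavioralDataset,
    GroupPhase,
    SimSettings,
    aicc,
    fit_variant,
    loo_cross_validate,
    model_dprime,
    noise_ceiling,
    objective_sse,
    predict_transfer,
)
from vplsearch.cohort import DEFAULT_TRUTH
from vplsearch.fitting import FrozenExperiments, session_labels
from vplsearch.learning import pack_params

FAST_SIM = SimSettings(n_trials=600)


class TestAicc:
    def test_hand_evaluated_value(self):
        expected = 14 * math.log(0.5 / 14) + 8 + 40 / 9
        assert aicc(0.5, 14, 4) == pytest.approx(expected, abs=1e-10)

    def test_penalty_difference_k3_vs_k6(self):
        # equal SSE at n=14: AICc difference is exactly 15.6 in favor of k=3
        assert aicc(1.0, 14, 6) - aicc(1.0, 14, 3) == pytest.approx(15.6, abs=1e-10)

    def test_scaling_sse_by_e_adds_n(self):
        assert aicc(2.0 * math.e, 14, 4) - aicc(2.0, 14, 4) == pytest.approx(14.0, abs=1e-10)

    def test_penalty_increases_with_k(self):
        values = [aicc(0.7, 14, k) for k in range(1, 7)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_undefined_correction_rejected(self):
        with pytest.raises(ValueError):
            aicc(1.0, 5, 4)

    def test_perfect_fit_is_minus_infinity(self):
        assert aicc(0.0, 14, 3) == float("-inf")


class TestModelDprime:
    def test_static_model_constant_across_sessions(self):
        from vplsearch.learning import VariantParams

        p = VariantParams("RL", 6.0, 7.5, rates={"tau_target": 0.0, "tau_distractor": 0.0})
        dps = [
            model_dprime(p, GroupPhase("oblique", "training", d), n_trials=20_000, rng=4)
            for d in (1, 3, 6)
        ]
        assert max(dps) - min(dps) < 0.1

    def test_baseline_asymmetry_favors_oblique_group(self):
        from vplsearch.learning import VariantParams

        p = VariantParams("R", 5.0, 10.0, rates={"tau": 0.5})
        nc = model_dprime(p, GroupPhase("near_cardinal", "training", 1), n_trials=20_000, rng=8)
        ob = model_dprime(p, GroupPhase("oblique", "training", 1), n_trials=20_000, rng=8)
        assert ob > nc + 0.3

    def test_monte_carlo_consistency(self):
        # repeated estimates at larger n scatter less
        gp = GroupPhase("oblique", "training", 2)
        small = [model_dprime(DEFAULT_TRUTH, gp, n_trials=500, rng=s) for s in range(12)]
        large = [model_dprime(DEFAULT_TRUTH, gp, n_trials=8000, rng=s) for s in range(12)]
        assert np.std(large) < np.std(small)


class TestObjective:
    def test_self_consistency_zero_sse(self):
        # targets taken from the same frozen evaluator at the same params
        labels = session_labels()
        frozen = FrozenExperiments(labels, FAST_SIM, base_seed=12)
        means = frozen.evaluate(DEFAULT_TRUTH)
        ds = BehavioralDataset.from_group_means(dict(means.items()))
        sse = objective_sse(pack_params(DEFAULT_TRUTH), "RL", ds, labels, frozen)
        assert sse == pytest.approx(0.0, abs=1e-20)

    def test_quadratic_in_observed_perturbation(self):
        labels = session_labels()
        frozen = FrozenExperiments(labels, FAST_SIM, base_seed=12)
        means = dict(frozen.evaluate(DEFAULT_TRUTH).items())
        delta = 0.37
        means[("oblique", "D3")] += delta
        ds = BehavioralDataset.from_group_means(means)
        sse = objective_sse(pack_params(DEFAULT_TRUTH), "RL", ds, labels, frozen)
        assert sse == pytest.approx(delta**2, abs=1e-12)

    def test_hand_summed_two_point_dataset(self):
        labels = ["D1"]
        frozen = FrozenExperiments(labels, FAST_SIM, base_seed=3)
        model = frozen.evaluate(DEFAULT_TRUTH)
        obs = {
            ("near_cardinal", "D1"): 1.0,
            ("oblique", "D1"): 2.0,
        }
        ds = BehavioralDataset.from_group_means(obs)
        expected = sum(
            (model[key] - obs[key]) ** 2 for key in obs
        )
        sse = objective_sse(pack_params(DEFAULT_TRUTH), "RL", ds, labels, frozen)
        assert sse == pytest.approx(expected, abs=1e-12)

    def test_missing_sessions_rejected(self):
        frozen = FrozenExperiments(["D1"], FAST_SIM, base_seed=3)
        ds = BehavioralDataset.from_group_means(
            {("near_cardinal", "D1"): 1.0, ("oblique", "D1"): 2.0}
        )
        with pytest.raises(ValueError):
            objective_sse(pack_params(DEFAULT_TRUTH), "RL", ds, ["D1", "D2"], frozen)


class TestFitVariant:
    def test_zero_iteration_budget_returns_start(self, small_cohort):
        start = np.array([6.0, 8.0, 0.3, 0.6])
        fit = fit_variant(
            "RL",
            small_cohort,
            n_starts=1,
            starts=[start],
            maxiter=0,
            rng=1,
            sim=FAST_SIM,
        )
        np.testing.assert_allclose(pack_params(fit.best_params), start)
        assert fit.sse == fit.starts[0]["sse"]

    def test_oversized_sigma_start_clipped_to_box(self, small_cohort):
        fit = fit_variant(
            "RL",
            small_cohort,
            n_starts=1,
            starts=[np.array([25.0, 30.0, 0.5, 0.5])],
            maxiter=0,
            rng=1,
            sim=FAST_SIM,
        )
        assert fit.starts[0]["start"][:2] == [20.0, 20.0]

    def test_deterministic_given_seed(self, small_cohort):
        kwargs = dict(
            sessions=["D1", "D2", "D3"], n_starts=2, sim=FAST_SIM, maxiter=30
        )
        a = fit_variant("R", small_cohort, rng=5, **kwargs)
        b = fit_variant("R", small_cohort, rng=5, **kwargs)
        assert a == b

    def test_best_start_attains_minimum_sse(self, small_cohort):
        fit = fit_variant(
            "R",
            small_cohort,
            sessions=["D1", "D2", "D3"],
            n_starts=3,
            rng=2,
            sim=FAST_SIM,
            maxiter=30,
        )
        assert fit.sse == min(r["sse"] for r in fit.starts)
        assert fit.aicc == aicc(fit.sse, fit.n_points, fit.k)

    def test_records_every_start(self, small_cohort):
        fit = fit_variant(
            "L",
            small_cohort,
            sessions=["D1", "D2", "D3"],
            n_starts=3,
            rng=2,
            sim=FAST_SIM,
            maxiter=20,
        )
        assert len(fit.starts) == 3


class TestNoiseCeiling:
    def test_identical_observers_hit_unity(self):
        rows = []
        traj = [0.5, 1.0, 1.5, 2.0]
        for group in ("near_cardinal", "oblique"):
            for obs in range(3):
                for i, d in enumerate(traj):
                    rows.append(
                        {
                            "observer_id": f"{group}_{obs}",
                            "group": group,
                            "session_label": f"D{i + 1}",
                            "dprime": d,
                        }
                    )
        ds = BehavioralDataset(pd.DataFrame(rows))
        lower, upper = noise_ceiling(ds)
        assert lower == pytest.approx(1.0, abs=1e-12)
        assert upper == pytest.approx(1.0, abs=1e-12)

    def test_hand_crafted_three_observer_bounds(self):
        # single-group, 3 observers, hand-checkable correlations
        trajs = {
            "a": [1.0, 2.0, 3.0],
            "b": [1.0, 2.5, 2.8],
            "c": [0.5, 1.8, 3.2],
        }
        rows = [
            {
                "observer_id": o,
                "group": "oblique",
                "session_label": f"D{i + 1}",
                "dprime": d,
            }
            for o, t in trajs.items()
            for i, d in enumerate(t)
        ]
        # mirror the group in the other arm so the dataset is well-formed
        rows += [
            dict(r, observer_id=r["observer_id"] + "_nc", group="near_cardinal")
            for r in rows
        ]
        ds = BehavioralDataset(pd.DataFrame(rows))

        def r2(x, y):
            return np.corrcoef(x, y)[0, 1] ** 2

        names = list(trajs)
        arr = {k: np.array(v) for k, v in trajs.items()}
        grand = np.mean(list(arr.values()), axis=0)
        expected_upper = np.mean([r2(arr[o], grand) for o in names])
        expected_lower = np.mean(
            [
                r2(arr[o], np.mean([arr[p] for p in names if p != o], axis=0))
                for o in names
            ]
        )
        lower, upper = noise_ceiling(ds)
        assert upper == pytest.approx(expected_upper, abs=1e-12)
        assert lower == pytest.approx(expected_lower, abs=1e-12)

    def test_requires_two_observers_per_group(self):
        rows = [
            {
                "observer_id": f"solo_{g}",
                "group": g,
                "session_label": f"D{i}",
                "dprime": float(i),
            }
            for g in ("near_cardinal", "oblique")
            for i in (1, 2)
        ]
        with pytest.raises(ValueError):
            noise_ceiling(BehavioralDataset(pd.DataFrame(rows)))


class TestLooCrossValidate:
    def test_refits_use_remaining_observers(self, small_cohort):
        # structure only: every refit sees one observer fewer
        n_total = len(small_cohort.observers)
        seen = []
        import vplsearch.fitting as fitting

        orig = fitting.fit_variant

        def spy(variant, dataset, **kwargs):
            seen.append(len(dataset.observers))
            return orig(variant, dataset, **kwargs)

        fitting.fit_variant, token = spy, None
        try:
            cv = fitting.loo_cross_validate(
                small_cohort, "R", sim=FAST_SIM, rng=3, n_starts=1, maxiter=10
            )
        finally:
            fitting.fit_variant = orig
        assert seen == [n_total - 1] * n_total
        assert set(cv.per_observer_r2) | set(cv.excluded) == set(small_cohort.observers)
        assert 0.0 <= cv.mean_r2 <= 1.0
        assert cv.ceiling_lower <= cv.ceiling_upper + 1e-12

    def test_perfect_prediction_for_identical_observers(self):
        # observers equal to a realisable model trajectory: r^2 -> 1 up to
        # the simulation noise of the refit evaluations
        labels = session_labels()
        sim = SimSettings(n_trials=2500)
        frozen = FrozenExperiments(labels, sim, base_seed=44)
        model = frozen.evaluate(DEFAULT_TRUTH)
        rows = []
        for group in ("near_cardinal", "oblique"):
            for obs in range(2):
                for label in labels:
                    rows.append(
                        {
                            "observer_id": f"{group}_{obs}",
                            "group": group,
                            "session_label": label,
                            "dprime": model[(group, label)],
                        }
                    )
        ds = BehavioralDataset(pd.DataFrame(rows))
        cv = loo_cross_validate(ds, "RL", sim=sim, rng=9, n_starts=2, maxiter=120)
        assert cv.mean_r2 > 0.95


class TestPredictTransfer:
    def test_rejects_fit_that_saw_test_session(self, small_cohort):
        fit = fit_variant(
            "R", small_cohort, n_starts=1, rng=1, sim=FAST_SIM, maxiter=0,
            starts=[np.array([6.0, 8.0, 0.5])],
        )
        assert "OrTest" in fit.sessions
        with pytest.raises(ValueError):
            predict_transfer(fit)

    def test_no_learning_swap_symmetry(self):
        # tau = 0: the test display equals the opposite group's day-1 display
        from vplsearch.learning import VariantParams

        p = VariantParams("RL", 6.0, 9.0, rates={"tau_target": 0.0, "tau_distractor": 0.0})
        test_nc = model_dprime(
            p, GroupPhase("near_cardinal", "orientation_test"), n_trials=40_000, rng=2
        )
        day1_ob = model_dprime(
            p, GroupPhase("oblique", "training", 1), n_trials=40_000, rng=3
        )
        assert test_nc == pytest.approx(day1_ob, abs=0.08)
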