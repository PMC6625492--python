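"""Pareto front, hypervolume, discrete suggestion, NSGA-II, mixture batches."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import solvoptim as sv
from solvoptim.errors import (
    ExhaustedLibraryError,
    InvalidArgumentError,
)
from solvoptim.optimizer import _hv_clipped


def brute_force_front(points):
    """O(n²) pairwise domination scan (maximisation)."""
    P = np.asarray(points, dtype=float)
    keep = []
    for i in range(len(P)):
        dominated = any(
            np.all(P[j] >= P[i]) and np.any(P[j] > P[i]) for j in range(len(P))
        )
        if not dominated:
            keep.append(tuple(P[i]))
    return sorted(set(keep), key=lambda t: (-t[0], -t[1]))


class TestParetoFront:
    def test_singleton(self):
        f = sv.pareto_front(np.array([[50.0, 10.0]]))
        assert len(f) == 1

    def test_hand_checkable(self):
        f = sv.pareto_front(np.array([[90, 50], [80, 70], [70, 60]]))
        assert f.points.tolist() == [[90, 50], [80, 70]]

    def test_matches_brute_force_on_random_points(self, rng):
        P = rng.uniform(0, 100, size=(50, 2))
        f = sv.pareto_front(P)
        assert [tuple(p) for p in f.points] == brute_force_front(P)

    def test_duplicates_collapsed_with_provenance(self):
        f = sv.pareto_front(np.array([[80, 70], [80, 70], [10, 10]]))
        assert len(f) == 1
        assert f.member_indices[0] == (0, 1)

    def test_no_member_weakly_dominates_another(self, rng):
        P = np.round(rng.uniform(0, 10, size=(60, 2)))  # many ties
        f = sv.pareto_front(P)
        for i in range(len(f)):
            for j in range(len(f)):
                if i != j:
                    assert not (
                        np.all(f.points[i] >= f.points[j])
                        and np.any(f.points[i] > f.points[j])
                    )

    @given(arrays(float, (12, 2), elements=st.floats(0, 100, width=16)))
    @settings(max_examples=30, deadline=None)
    def test_domination_partial_order(self, P):
        """Domination is irreflexive and transitive on random point sets."""
        from solvoptim.optimizer import _dominates

        for a in P:
            assert not _dominates(a, a)
        for a in P[:5]:
            for b in P[:5]:
                for c in P[:5]:
                    if _dominates(a, b) and _dominates(b, c):
                        assert _dominates(a, c)

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            sv.pareto_front(np.empty((0, 2)))


class TestHypervolume:
    def test_rectangle(self):
        hv = sv.hypervolume_2d(np.array([[90.0, 70.0]]), (0.0, -100.0))
        assert hv == 90 * 170

    def test_empty_front_zero(self):
        assert sv.hypervolume_2d(np.empty((0, 2)), (0, 0)) == 0.0

    def test_matches_monte_carlo_oracle(self, rng):
        P = rng.uniform(20, 100, size=(30, 2))
        front = sv.pareto_front(P)
        ref = np.array([0.0, 0.0])
        hv = sv.hypervolume_2d(front, ref)
        n_mc = 1_000_000
        pts = rng.uniform(ref, [100.0, 100.0], size=(n_mc, 2))
        inside = np.zeros(n_mc, dtype=bool)
        for p in front.points:
            inside |= np.all(pts <= p, axis=1)
        mc = inside.mean() * 100.0 * 100.0
        np.testing.assert_allclose(hv, mc, rtol=0.01)

    def test_reference_not_dominated_raises(self):
        with pytest.raises(InvalidArgumentError) as exc:
            sv.hypervolume_2d(np.array([[50.0, 60.0], [90.0, 10.0]]), (60.0, 0.0))
        assert "50.0" in str(exc.value)

    def test_monotone_under_insertion(self, rng):
        P = rng.uniform(10, 90, size=(15, 2))
        front = sv.pareto_front(P)
        ref = np.array([0.0, 0.0])
        hv = sv.hypervolume_2d(front, ref)
        # dominated insertion leaves the hypervolume unchanged
        inner = front.points[0] - 1.0
        f2 = sv.pareto_front(np.vstack([front.points, inner]))
        np.testing.assert_allclose(sv.hypervolume_2d(f2, ref), hv, atol=1e-10)
        # non-dominated insertion strictly increases it
        outer = np.array([95.0, 95.0])
        f3 = sv.pareto_front(np.vstack([front.points, outer]))
        assert sv.hypervolume_2d(f3, ref) > hv + 1e-10


class TestHypervolumeImprovement:
    def test_dominated_candidate_zero(self):
        front = np.array([[90.0, 50.0], [80.0, 70.0]])
        assert sv.hypervolume_improvement([70, 40], front, (0, 0)) == 0.0

    def test_dominating_candidate_subsumption(self):
        front = np.array([[50.0, 50.0]])
        ref = (0.0, 0.0)
        hvi = sv.hypervolume_improvement([60, 60], front, ref)
        np.testing.assert_allclose(hvi, 60 * 60 - 50 * 50)

    def test_matches_two_call_difference(self, rng):
        P = rng.uniform(10, 90, size=(12, 2))
        front = sv.pareto_front(P)
        ref = np.array([0.0, 0.0])
        cand = rng.uniform(10, 99, size=2)
        joint = sv.pareto_front(np.vstack([front.points, cand]))
        expected = sv.hypervolume_2d(joint, ref) - sv.hypervolume_2d(front, ref)
        np.testing.assert_allclose(
            sv.hypervolume_improvement(cand, front, ref), expected, atol=1e-10)


class TestSuggestDiscrete:
    def test_single_untested_gets_all_votes(self, campaign_setup):
        lib, oracle, state = campaign_setup
        # shrink to tested + one untested
        keep = state.tested_ids + [state.untested_ids[0]]
        sub = lib.subset(keep)
        state2 = sv.CampaignState(
            library=sub, conv_spec=state.conv_spec, de_spec=state.de_spec,
            experiments=state.experiments, gp_config=state.gp_config)
        state2.refit(seed=0)
        ranked = sv.suggest_discrete(state2, n_repeats=10, seed=0)
        assert len(ranked) == 1
        assert ranked["votes"].iloc[0] == 10

    def test_tested_solvents_never_returned(self, campaign_setup):
        lib, oracle, state = campaign_setup
        ranked = sv.suggest_discrete(state, n_repeats=20, seed=1)
        assert set(ranked["solvent_id"]) & set(state.tested_ids) == set()
        assert ranked["votes"].sum() == 20

    def test_exhausted_library(self, campaign_setup):
        lib, oracle, state = campaign_setup
        rows = [
            {"solvent_id": s, "conversion": 50.0, "de": 0.0}
            for s in lib.ids
        ]
        full = sv.CampaignState(
            library=lib, conv_spec=state.conv_spec, de_spec=state.de_spec,
            experiments=pd.DataFrame(rows), gp_config=state.gp_config)
        full.refit(seed=0)
        with pytest.raises(ExhaustedLibraryError):
            sv.suggest_discrete(full, n_repeats=5, seed=0)

    def test_vote_distribution_matches_replay_oracle(self, campaign_setup):
        """Replaying the recorded per-repeat rule on the same sample draws."""
        lib, oracle, state = campaign_setup
        n_repeats = 40
        ranked = sv.suggest_discrete(state, n_repeats=n_repeats, seed=7,
                                     n_spectral_features=128)
        # independent straight-line reimplementation
        untested = sorted(state.untested_ids)
        recs = [lib[i] for i in untested]
        Xc = sv.featurize(recs, state.conv_spec).to_numpy()
        Xd = sv.featurize(recs, state.de_spec).to_numpy()
        front = sv.pareto_front(state.observed_points())
        ref = state.reference
        base = _hv_clipped(front.points, ref)
        votes = {sid: 0 for sid in untested}
        ss = np.random.SeedSequence(7).spawn(n_repeats)
        for r in range(n_repeats):
            s_conv, s_de = ss[r].spawn(2)
            fc = sv.sample_posterior_function(state.gp_conv, 128, seed=s_conv)
            fd = sv.sample_posterior_function(state.gp_de, 128, seed=s_de)
            samp = np.column_stack([fc(Xc), fd(Xd)])
            best_i, best_h = 0, -np.inf
            for i in range(len(untested)):
                h = _hv_clipped(np.vstack([front.points, samp[i]]), ref) - base
                if h > best_h:
                    best_i, best_h = i, h
            votes[untested[best_i]] += 1
        expected = pd.Series(votes)
        got = ranked.set_index("solvent_id")["votes"]
        for sid in untested:
            assert got.get(sid, 0) == expected[sid]


class TestNsga2:
    def test_linear_tradeoff_spans_endpoints(self):
        X, F = sv.constrained_moo_solve(
            lambda X: np.column_stack([X[:, 0], 1 - X[:, 0]]),
            [(0.0, 1.0)], None, population=60, generations=50, seed=3)
        assert X[:, 0].min() <= 0.05 and X[:, 0].max() >= 0.95

    def test_active_simplex_constraint(self):
        # both objectives reward large Σx: optimum sits on the simplex face
        X, F = sv.constrained_moo_solve(
            lambda X: np.column_stack([-X.sum(axis=1), -(X**2).sum(axis=1)]),
            [(0.0, 1.0)] * 3,
            lambda X: X.sum(axis=1) - 1.0,
            population=60, generations=60, seed=4)
        assert np.all(X.sum(axis=1) <= 1.0 + 1e-9)
        assert np.all(X.sum(axis=1) >= 1.0 - 1e-6)

    def test_generational_distance_to_known_front(self):
        """ZDT1-style 2-var problem with closed-form Pareto front."""

        def objectives(X):
            f1 = X[:, 0]
            g = 1 + 9 * X[:, 1]
            f2 = g * (1 - np.sqrt(f1 / g))
            return np.column_stack([f1, f2])

        gds = []
        for seed in range(5):
            X, F = sv.constrained_moo_solve(
                objectives, [(0.0, 1.0)] * 2, None,
                population=60, generations=100, seed=seed)
            # true front: x2 = 0, f2 = 1 − √f1
            gd = np.mean(np.abs(F[:, 1] - (1 - np.sqrt(F[:, 0]))))
            gds.append(gd)
        assert np.median(gds) <= 0.02

    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            sv.constrained_moo_solve(lambda X: X, [(1.0, 0.0)], None)
        with pytest.raises(InvalidArgumentError):
            sv.constrained_moo_solve(lambda X: X, [(0.0, 1.0)], None,
                                     population=7)


@pytest.fixture(scope="module")
def mixture_state():
    rng = np.random.default_rng(21)
    X = rng.uniform(0, 0.5, size=(12, 3))
    T = rng.uniform(40, 100, size=12)
    conv = 100 / (1 + np.exp(-(X.sum(1) * 3 + (T - 70) / 20 - 1)))
    de = 60 * np.tanh(X[:, 0] * 2 - X[:, 1] + (70 - T) / 50)
    state = sv.MixtureCampaignState(
        experiments=pd.DataFrame(
            {"x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2],
             "temperature_C": T, "conversion": conv, "de": de}),
        gp_config=sv.GPConfig(n_restarts=3))
    state.refit(seed=22)
    return state


class TestMixtureBatch:
    def test_batch_contract(self, mixture_state):
        recipes = sv.suggest_mixture_batch(
            mixture_state, batch_size=5, seed=5,
            population=24, generations=15, n_spectral_features=128)
        assert len(recipes) == 5
        temps = [r.temperature_C for r in recipes]
        assert all(t == temps[0] for t in temps[1:])
        for r in recipes:
            assert r.x1 >= 0 and r.x2 >= 0 and r.x3 >= 0
            assert r.x1 + r.x2 + r.x3 <= 1.0 + 1e-9
            np.testing.assert_allclose(r.balance, 1 - (r.x1 + r.x2 + r.x3),
                                       atol=1e-9)
            assert 40.0 <= r.temperature_C <= 100.0

    def test_batch_size_one(self, mixture_state):
        recipes = sv.suggest_mixture_batch(
            mixture_state, batch_size=1, seed=6,
            population=24, generations=10, n_spectral_features=64)
        assert len(recipes) == 1

    def test_recipe_validation(self):
        with pytest.raises(InvalidArgumentError):
            sv.MixtureRecipe(0.5, 0.4, 0.3, 70.0)
        with pytest.raises(InvalidArgumentError):
            sv.MixtureRecipe(-0.1, 0.0, 0.0, 70.0)


class TestRunCampaign:
    def test_zero_iterations_no_change(self, campaign_setup):
        lib, oracle, state = campaign_setup
        n_before = len(state.experiments)
        sv.run_campaign(state, lambda s: oracle.query(s), iterations=0, seed=0)
        assert len(state.experiments) == n_before

    def test_bookkeeping_and_monotone_hypervolume(self, campaign_setup):
        import copy

        lib, oracle, state = campaign_setup
        st_ = copy.deepcopy(state)
        n0 = len(st_.experiments)
        sv.run_campaign(st_, lambda s: oracle.query(s), iterations=4,
                        per_iteration=1, n_repeats=8, seed=3,
                        n_spectral_features=64)
        assert len(st_.experiments) == n0 + 4
        hv = [e["hypervolume"] for e in st_.log]
        assert all(b >= a - 1e-10 for a, b in zip(hv, hv[1:]))

    def test_oracle_failure_checkpoints(self, campaign_setup):
        import copy

        lib, oracle, state = campaign_setup
        st_ = copy.deepcopy(state)
        calls = {"n": 0}

        def flaky(sid):
            calls["n"] += 1
            if calls["n"] > 2:
                raise RuntimeError("reactor offline")
            return oracle.query(sid)

        with pytest.raises(sv.OracleInterruption) as exc:
            sv.run_campaign(st_, flaky, iterations=5, per_iteration=1,
                            n_repeats=8, seed=4, n_spectral_features=64)
        # completed iterations were appended; state is re-entrant
        assert exc.value.state is st_
        sv.run_campaign(st_, lambda s: oracle.query(s), iterations=1,
                        per_iteration=1, n_repeats=8, seed=5,
                        n_spectral_features=64)
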