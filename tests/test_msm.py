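"""TICA, CNN clustering, counting, reversible estimation and validation."""

import numpy as np
import pytest

from depsikin import msm, synthetic
from depsikin.errors import DepsikinError, DimensionError


def partition_of(labels):
    """Canonical partition (frozenset of frozensets) ignoring label identity."""
    groups = {}
    for i, l in enumerate(labels):
        groups.setdefault(l, set()).add(i)
    noise = frozenset(groups.pop(msm.NOISE_LABEL, set()))
    return frozenset(frozenset(g) for g in groups.values()), noise


class TestEmbedding:
    def test_zero_angle_maps_to_sin0_cos1(self):
        ft = msm.embed_dihedrals(np.zeros((3, 2)), dt=1.0)
        np.testing.assert_allclose(ft.frames[:, 0::2], 0.0, atol=1e-15)
        np.testing.assert_allclose(ft.frames[:, 1::2], 1.0, atol=1e-15)

    def test_plus_180_equals_wrapped_minus_180(self):
        a = msm.embed_dihedrals(np.full((2, 1), 180.0), dt=1.0).frames
        np.testing.assert_allclose(a[:, 0], np.sin(np.deg2rad(-180.0)), atol=1e-12)
        np.testing.assert_allclose(a[:, 1], np.cos(np.deg2rad(-180.0)), atol=1e-12)

    def test_atan2_round_trip(self, rng):
        ang = rng.uniform(-179.999, 180.0, (50, 6))
        ft = msm.embed_dihedrals(ang, dt=0.1)
        rec = np.rad2deg(np.arctan2(ft.frames[:, 0::2], ft.frames[:, 1::2]))
        np.testing.assert_allclose(rec, ang, atol=1e-12)

    def test_out_of_range_angles_rejected(self):
        with pytest.raises(DimensionError):
            msm.embed_dihedrals(np.array([[190.0]]), dt=1.0)

    def test_lag_conversion_strict(self):
        assert msm.lag_ns_to_frames(10.0, 0.5) == 20
        with pytest.raises(DimensionError):
            msm.lag_ns_to_frames(10.0, 3.0)


class TestTica:
    def test_planted_slow_mode_dominates(self, rng):
        n = 40000
        # slow two-state telegraph signal in feature 1, fast noise in feature 2
        flips = rng.random(n) < 0.002
        slow = np.cumsum(flips) % 2 * 2.0 - 1.0
        X = np.column_stack([slow + 0.05 * rng.standard_normal(n), rng.standard_normal(n)])
        model = msm.tica([msm.FeatureTrajectory(X, dt=1.0)], lag=10)
        v = model.eigenvectors[:, 0]
        cosine = abs(v[0]) / np.linalg.norm(v)
        assert cosine > 0.99
        assert model.eigenvalues[0] > 0.9

    def test_white_noise_has_no_autocorrelation(self, rng):
        X = rng.standard_normal((20000, 3))
        model = msm.tica([msm.FeatureTrajectory(X, dt=1.0)], lag=5)
        assert np.all(np.abs(model.eigenvalues) < 0.05)

    def test_eigenvalues_invariant_under_feature_rotation(self, rng):
        n = 5000
        X = np.cumsum(rng.standard_normal((n, 4)), axis=0) * 0.01 + rng.standard_normal((n, 4))
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        m1 = msm.tica([msm.FeatureTrajectory(X, dt=1.0)], lag=3, n_components=4)
        m2 = msm.tica([msm.FeatureTrajectory(X @ q, dt=1.0)], lag=3, n_components=4)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)

    def test_trajectory_shorter_than_lag_rejected(self, rng):
        ft = msm.FeatureTrajectory(rng.standard_normal((10, 2)), dt=1.0)
        with pytest.raises(DimensionError):
            msm.tica([ft], lag=10)


class TestCnnCluster:
    def test_two_separated_blobs_fully_recovered(self, rng):
        n = 400
        a = rng.normal(0.0, 0.05, (n, 2))
        b = rng.normal(5.0, 0.05, (n, 2)) * [1, -1]
        pts = np.vstack([a, b])
        truth = np.array([0] * n + [1] * n)
        cm = msm.cnn_cluster(pts, cutoff=0.3, similarity=10, target_noise_fraction=0.2)
        assert cm.n_clusters == 2
        kept = cm.labels != msm.NOISE_LABEL
        # every retained point sits with its own blob, none are mixed
        for lab in (0, 1):
            blobs = truth[kept & (cm.labels == lab)]
            assert len(set(blobs)) == 1
        assert abs(cm.noise_fraction - 0.2) < 1e-9

    def test_identical_points_form_single_cluster(self):
        pts = np.zeros((30, 2))
        cm = msm.cnn_cluster(pts, cutoff=0.1, similarity=5, target_noise_fraction=0.0)
        assert cm.n_clusters == 1
        assert np.all(cm.labels == 0)

    def test_permutation_invariance(self, rng):
        pts = np.vstack(
            [rng.normal(0, 0.1, (100, 2)), rng.normal(3, 0.1, (100, 2)), rng.uniform(-1, 4, (40, 2))]
        )
        perm = rng.permutation(len(pts))
        cm1 = msm.cnn_cluster(pts, 0.3, 5, 0.15)
        cm2 = msm.cnn_cluster(pts[perm], 0.3, 5, 0.15)
        part1, noise1 = partition_of(cm1.labels)
        # map permuted result back to original indexing
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        part2, noise2 = partition_of(cm2.labels[inv])
        assert part1 == part2 and noise1 == noise2

    def test_invalid_arguments(self):
        with pytest.raises(DimensionError):
            msm.cnn_cluster(np.zeros((10, 2)), cutoff=-1.0, similarity=5)
        with pytest.raises(DimensionError):
            msm.cnn_cluster(np.zeros((10, 2)), cutoff=0.1, similarity=0)
        with pytest.raises(DimensionError):
            msm.cnn_cluster(np.zeros((3, 2)), cutoff=0.1, similarity=5)


class TestCounting:
    def test_constant_trajectory(self):
        C = msm.count_transitions(np.zeros(100, dtype=int), lag=7)
        assert C[0, 0] == 93

    def test_alternating_states(self):
        d = np.arange(101) % 2
        C = msm.count_transitions(d, lag=1)
        assert C[0, 1] == C[1, 0] == 50
        assert C[0, 0] == C[1, 1] == 0

    def test_brute_force_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            d = rng.integers(-1, 4, 200)  # includes noise labels
            lag = int(rng.integers(1, 6))
            C = msm.count_transitions(d, lag, n_states=4)
            # independent brute force
            B = np.zeros((4, 4), dtype=int)
            for t in range(len(d) - lag):
                i, j = d[t], d[t + lag]
                if i >= 0 and j >= 0:
                    B[i, j] += 1
            np.testing.assert_array_equal(C, B)

    def test_noise_breaks_the_chain(self):
        d = np.array([0, -1, 1, 1])
        C = msm.count_transitions(d, lag=1)
        assert C.sum() == 1 and C[1, 1] == 1


class TestConnectedSet:
    def test_block_diagonal_keeps_heavier_block(self):
        C = np.zeros((5, 5), int)
        C[0, 1] = C[1, 0] = 10
        C[2, 3] = C[3, 4] = C[4, 2] = 100
        active = msm.largest_connected_set(C)
        assert set(active.states) == {2, 3, 4}
        assert set(active.discarded) == {0, 1}

    def test_fully_connected_keeps_all(self):
        C = np.ones((4, 4), int)
        active = msm.largest_connected_set(C)
        assert active.states == (0, 1, 2, 3)

    def test_agrees_with_networkx_tarjan(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(20):
            C = (rng.random((8, 8)) < 0.15) * rng.integers(1, 50, (8, 8))
            np.fill_diagonal(C, rng.integers(0, 5, 8))
            g = nx.from_numpy_array(np.asarray(C > 0), create_using=nx.DiGraph)
            comps = list(nx.strongly_connected_components(g))
            weights = [C[np.ix_(list(c), list(c))].sum() for c in comps]
            active = msm.largest_connected_set(C)
            # the selected set is a true SCC carrying the maximal count weight
            assert set(active.states) in [set(c) for c in comps]
            sel = C[np.ix_(active.states, active.states)].sum()
            assert sel == max(weights)

    def test_single_simulation_provenance_reported(self):
        d1 = np.array([0, 1, 0, 1, 0])
        d2 = np.array([2, 2, 2, 2, 2])
        C = msm.count_transitions([d1, d2], lag=1)
        active = msm.largest_connected_set(C, dtraj_labels=[d1, d2], dtraj_ids=["run-a", "run-b"])
        assert set(active.states) == {0, 1}
        assert active.provenance[2] == ("run-b",)


class TestReversibleEstimation:
    def test_symmetric_counts_give_row_normalized_matrix(self):
        C = np.array([[50.0, 10.0, 5.0], [10.0, 80.0, 2.0], [5.0, 2.0, 30.0]])
        model = msm.estimate_reversible_msm(C)
        np.testing.assert_allclose(
            model.transition_matrix, C / C.sum(axis=1, keepdims=True), atol=1e-10
        )
        np.testing.assert_allclose(
            model.stationary_distribution, C.sum(axis=1) / C.sum(), atol=1e-10
        )

    def test_invariants_hold_on_random_counts(self, rng):
        for _ in range(20):
            C = rng.integers(1, 100, (4, 4))
            model = msm.estimate_reversible_msm(C)
            T, pi = model.transition_matrix, model.stationary_distribution
            np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(pi @ T, pi, atol=1e-10)
            np.testing.assert_allclose(pi[:, None] * T, (pi[:, None] * T).T, atol=1e-10)

    def test_planted_three_state_chain_recovery(self):
        T_true = np.array([[0.90, 0.08, 0.02], [0.16, 0.80, 0.04], [0.12, 0.12, 0.76]])
        # make it reversible with pi = (0.6, 0.3, 0.1): enforce detailed balance
        pi = np.array([0.6, 0.3, 0.1])
        flux = 0.5 * (pi[:, None] * T_true + (pi[:, None] * T_true).T)
        T_true = flux / flux.sum(axis=1, keepdims=True)
        pi = flux.sum(axis=1) / flux.sum()
        data = synthetic.gen_markov(
            synthetic.MarkovSpec(seed=5, transition_matrix=tuple(map(tuple, T_true)), n_frames=1_000_000)
        )
        C = msm.count_transitions(data.dtrajs, lag=1)
        model = msm.estimate_reversible_msm(C)
        # entry-wise agreement within 3 binomial standard errors
        rows = C.sum(axis=1)
        se = np.sqrt(T_true * (1 - T_true) / rows[:, None])
        assert np.all(np.abs(model.transition_matrix - T_true) < 3 * se + 1e-12)
        np.testing.assert_allclose(model.stationary_distribution, pi, atol=0.02)

    def test_disconnected_counts_rejected(self):
        C = np.array([[5, 0], [0, 5]])
        with pytest.raises(DepsikinError):
            msm.estimate_reversible_msm(C)


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        # exact flows of a reversible T with lambda_2 = 0.9
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        C = (np.diag([0.5, 0.5]) @ T * 1e6).astype(float)
        model = msm.estimate_reversible_msm(C, lag=1)
        assert model.timescales(1)[0] == pytest.approx(-1.0 / np.log(0.9), rel=1e-10)

    def test_markovian_data_flat_in_lag(self):
        data = synthetic.gen_markov(
            synthetic.MarkovSpec(
                seed=8,
                transition_matrix=((0.97, 0.03), (0.02, 0.98)),
                n_frames=40_000,
                n_trajs=8,
            )
        )
        its = msm.implied_timescales(data.dtrajs, [1, 2, 5, 10], 1, n_bootstrap=30, seed=0)
        # the point estimates at every lag stay inside every other lag's band
        assert its.lower is not None
        for a in range(4):
            for b in range(4):
                assert its.lower[b, 0] * 0.999 <= its.timescales[a, 0] <= its.upper[b, 0] * 1.001

    def test_too_many_timescales_rejected(self):
        d = np.array([0, 1, 0, 1, 1, 0])
        with pytest.raises(DimensionError):
            msm.implied_timescales([d], [1], n_timescales=5)


class TestCkTest:
    def test_first_step_is_exact(self):
        data = synthetic.gen_markov(
            synthetic.MarkovSpec(seed=3, transition_matrix=((0.9, 0.1), (0.2, 0.8)), n_frames=20_000)
        )
        C = msm.count_transitions(data.dtrajs, lag=2)
        model = msm.estimate_reversible_msm(C, lag=2)
        res = msm.ck_test(model, data.dtrajs, n_steps=3)
        np.testing.assert_allclose(res.predicted[0], res.estimated[0], atol=1e-10)

    def test_self_consistency_on_markovian_data(self):
        data = synthetic.gen_markov(
            synthetic.MarkovSpec(
                seed=9,
                transition_matrix=((0.95, 0.04, 0.01), (0.08, 0.90, 0.02), (0.02, 0.02, 0.96)),
                n_frames=20_000,
                n_trajs=10,
            )
        )
        C = msm.count_transitions(data.dtrajs, lag=1)
        model = msm.estimate_reversible_msm(C, lag=1)
        res = msm.ck_test(model, data.dtrajs, n_steps=5, n_bootstrap=30, seed=1)
        assert res.within_bands().all()

    def test_hidden_state_violation_detected(self):
        # observed state 0 lumps two hidden states with very different exit
        # rates -> strongly non-geometric dwell times -> CK failure for k >= 2
        T_hidden = np.array(
            [[0.98, 0.01, 0.01], [0.01, 0.5, 0.49], [0.02, 0.38, 0.60]]
        )
        data = synthetic.gen_markov(
            synthetic.MarkovSpec(seed=12, transition_matrix=tuple(map(tuple, T_hidden)), n_frames=100_000)
        )
        lumped = [np.where(d == 0, 0, 1) for d in data.dtrajs]
        C = msm.count_transitions(lumped, lag=1)
        model = msm.estimate_reversible_msm(C, lag=1)
        res = msm.ck_test(model, lumped, n_steps=5, n_bootstrap=30, seed=2)
        assert not res.within_bands().all()


class TestSymmetryDiagnostic:
    def test_exactly_symmetric_model_has_zero_discrepancy(self):
        C = np.array([[40.0, 10.0, 10.0], [10.0, 30.0, 5.0], [10.0, 5.0, 30.0]])
        model = msm.estimate_reversible_msm(C)
        (pair,) = msm.symmetry_diagnostic(model, [(1, 2)])
        assert pair.abs_difference < 1e-12
        assert pair.ratio == pytest.approx(1.0)

    def test_discrepancy_shrinks_with_sampling(self):
        T = ((0.96, 0.02, 0.02), (0.04, 0.92, 0.04), (0.04, 0.04, 0.92))
        diffs = []
        for n in (2_000, 200_000):
            data = synthetic.gen_markov(
                synthetic.MarkovSpec(seed=21, transition_matrix=T, n_frames=n)
            )
            C = msm.count_transitions(data.dtrajs, lag=1)
            model = msm.estimate_reversible_msm(C)
            (pair,) = msm.symmetry_diagnostic(model, [(1, 2)])
            diffs.append(pair.abs_difference)
        assert diffs[1] < diffs[0]

    def test_pair_outside_active_set_rejected(self):
        model = msm.estimate_reversible_msm(np.array([[5.0, 5.0], [5.0, 5.0]]))
        with pytest.raises(DimensionError):
            msm.symmetry_diagnostic(model, [(0, 7)])
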