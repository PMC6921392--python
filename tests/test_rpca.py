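"""Low-rank + sparse solvers: proximal steps, convex oracle, streaming."""

import numpy as np
import pytest
from scipy.optimize import minimize

import xravessel as xv
from xravessel.rpca import (
    BasisState,
    RpcaError,
    frame_objective,
    soft_threshold,
    solve_frame,
    surrogate_cost,
    update_basis,
)
from xravessel.sequence import ImageSequence


def convex_oracle(x, Lr, lam1, lam2):
    """Independent solver of the per-frame objective.

    The L1 term is split as E = P - N with P, N >= 0, giving a smooth
    bound-constrained problem handed to L-BFGS-B; this shares no code
    path with the alternating solver under test.
    """
    D, r = Lr.shape

    def fun(z):
        ce, p, n = z[:r], z[r : r + D], z[r + D :]
        e = p - n
        resid = x - Lr @ ce - e
        f = 0.5 * resid @ resid + 0.5 * lam1 * ce @ ce + lam2 * (p.sum() + n.sum())
        g_ce = -Lr.T @ resid + lam1 * ce
        g_e = -resid
        return f, np.concatenate([g_ce, g_e + lam2, -g_e + lam2])

    bounds = [(None, None)] * r + [(0, None)] * (2 * D)
    res = minimize(
        fun,
        np.zeros(r + 2 * D),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
    )
    return res.fun


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x, t, expected", [(0.0, 1.0, 0.0), (3.0, 1.0, 2.0), (-0.5, 1.0, 0.0)]
    )
    def test_closed_form(self, x, t, expected):
        assert soft_threshold(x, t) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(RpcaError):
            soft_threshold(1.0, -0.1)

    def test_is_prox_of_l1_by_grid_search(self, rng):
        # per coordinate, prox minimizes 0.5*(y-x)^2 + t*|y|
        x = rng.normal(size=8) * 2
        t = 0.7
        grid = np.linspace(-10, 10, 40001)
        for xi in x:
            best = grid[np.argmin(0.5 * (grid - xi) ** 2 + t * np.abs(grid))]
            assert abs(soft_threshold(xi, t) - best) < 1e-3


class TestSolveFrame:
    def test_zero_frame_gives_zero_solution(self, rng):
        Lr = rng.normal(size=(25, 3))
        Ce, E = solve_frame(np.zeros(25), Lr, 0.1, 0.1)
        assert not Ce.any() and not E.any()

    def test_zero_basis_decouples_to_soft_threshold(self, rng):
        x = rng.normal(size=30)
        Ce, E = solve_frame(x, np.zeros((30, 2)), 0.1, 0.2)
        assert not Ce.any()
        assert np.allclose(E, soft_threshold(x, 0.2))

    def test_objective_nonincreasing_in_iterations(self, rng):
        x = rng.normal(size=40)
        Lr = rng.normal(size=(40, 3))
        objs = []
        for iters in range(1, 12):
            Ce, E = solve_frame(x, Lr, 0.05, 0.05, max_inner_iters=iters, tol=0)
            objs.append(frame_objective(x, Lr, Ce, E, 0.05, 0.05))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_matches_convex_oracle_on_random_instances(self, rng):
        for _ in range(8):
            D = int(rng.integers(20, 101))
            r = int(rng.integers(1, 6))
            x = rng.normal(size=D)
            Lr = rng.normal(size=(D, r)) / np.sqrt(D)
            lam1, lam2 = 0.05, 2.1 / D
            Ce, E = solve_frame(x, Lr, lam1, lam2, max_inner_iters=500, tol=1e-10)
            ours = frame_objective(x, Lr, Ce, E, lam1, lam2)
            ref = convex_oracle(x, Lr, lam1, lam2)
            assert ours <= ref * (1 + 1e-4) + 1e-10

    def test_nan_input_rejected(self):
        with pytest.raises(RpcaError):
            solve_frame(np.array([np.nan, 0.0]), np.ones((2, 1)), 0.1, 0.1)


class TestUpdateBasis:
    def test_zero_coefficients_zero_stats_is_noop(self, rng):
        state = BasisState.initialize(20, 2, seed=0)
        new = update_basis(state, rng.normal(size=20), np.zeros(2), np.zeros(20), 0.1)
        assert np.array_equal(new.Lr, state.Lr)
        assert new.frames_seen == 1

    def test_rank1_closed_form_fixed_point(self, rng):
        # single frame, E = 0: minimizer is Lr = x*Ce / (Ce^2 + lam1)
        x = rng.normal(size=15)
        ce = np.array([0.8])
        lam1 = 0.3
        state = BasisState.initialize(15, 1, seed=1)
        for _ in range(50):
            stats = BasisState(
                Lr=state.Lr, stat_A=np.zeros((1, 1)), stat_B=np.zeros((15, 1))
            )
            state = update_basis(stats, x, ce, np.zeros(15), lam1)
        expected = x * ce[0] / (ce[0] ** 2 + lam1)
        assert np.allclose(state.Lr[:, 0], expected, atol=1e-10)

    def test_surrogate_cost_nonincreasing(self, rng):
        state = BasisState.initialize(30, 3, seed=2)
        lam1 = 0.1
        for _ in range(10):
            x = rng.normal(size=30)
            Ce, E = solve_frame(x, state.Lr, lam1, 0.05)
            before_state = update_basis(state, x, Ce, E, lam1)
            # cost of the *new* stats evaluated at old vs new basis
            old_at_new_stats = surrogate_cost(
                BasisState(state.Lr, before_state.stat_A, before_state.stat_B), lam1
            )
            new_cost = surrogate_cost(before_state, lam1)
            assert new_cost <= old_at_new_stats + 1e-10
            state = before_state

    def test_recovers_rank1_subspace_direction(self, rng):
        D = 60
        direction = rng.normal(size=D)
        direction /= np.linalg.norm(direction)
        state = BasisState.initialize(D, 1, seed=3)
        lam1 = 1e-3
        for _ in range(50):
            x = direction * rng.uniform(0.5, 1.5)
            Ce, E = solve_frame(x, state.Lr, lam1, 1e9)  # huge lam2: E stays 0
            assert not E.any()
            state = update_basis(state, x, Ce, E, lam1)
        b = state.Lr[:, 0] / np.linalg.norm(state.Lr[:, 0])
        angle = np.arccos(min(1.0, abs(b @ direction)))
        assert angle < 1e-3

    def test_shape_mismatch_rejected(self):
        state = BasisState.initialize(10, 2, seed=0)
        with pytest.raises(RpcaError):
            update_basis(state, np.zeros(11), np.zeros(2), np.zeros(11), 0.1)


class TestInterFrameRpca:
    def test_zero_sequence_gives_zero_components(self):
        seq = ImageSequence(np.zeros((5, 8, 8)))
        B, E, _ = xv.inter_frame_rpca(seq, xv.RpcaConfig(rank_r=2))
        assert not B.frames.any() and not E.frames.any()

    def test_streaming_equals_batched_processing(self):
        rng = np.random.default_rng(5)
        frames = rng.random((12, 12, 12))
        seq = ImageSequence(frames)
        cfg = xv.RpcaConfig(rank_r=3, seed=9)
        B_full, E_full, _ = xv.inter_frame_rpca(seq, cfg)
        # same frames in two chunks, carrying the state across
        B1, E1, state = xv.inter_frame_rpca(ImageSequence(frames[:5]), cfg)
        B2, E2, _ = xv.inter_frame_rpca(ImageSequence(frames[5:]), cfg, state=state)
        assert np.array_equal(B_full.frames, np.concatenate([B1.frames, B2.frames]))
        assert np.array_equal(E_full.frames, np.concatenate([E1.frames, E2.frames]))

    def test_fixed_seed_is_bit_deterministic(self):
        rng = np.random.default_rng(6)
        seq = ImageSequence(rng.random((6, 10, 10)))
        cfg = xv.RpcaConfig(seed=4)
        _, E1, _ = xv.inter_frame_rpca(seq, cfg)
        _, E2, _ = xv.inter_frame_rpca(seq, cfg)
        assert np.array_equal(E1.frames, E2.frames)

    def test_empty_sequence_rejected(self):
        with pytest.raises(Exception):
            xv.inter_frame_rpca(ImageSequence(np.zeros((0, 4, 4))), xv.RpcaConfig())


def planted_sequence(shape=(50, 64, 64), rank=3, sparse_frac=0.05, amp=0.5, seed=7):
    """Low-rank background + sparse spikes with known support."""
    n, h, w = shape
    rng = np.random.default_rng(seed)
    D = h * w
    U = rng.normal(size=(D, rank)) / np.sqrt(D)
    C = rng.normal(size=(n, rank))
    low = C @ U.T
    support = rng.random((n, D)) < sparse_frac
    spikes = support * amp * rng.choice([-1.0, 1.0], size=(n, D))
    frames = (low + spikes).reshape(n, h, w)
    return ImageSequence(frames), support.reshape(n, h, w)


class TestPlantedRecovery:
    def test_sparse_support_recovered_after_burn_in(self):
        seq, support = planted_sequence()
        _, E, _ = xv.inter_frame_rpca(seq, xv.RpcaConfig(rank_r=5, seed=0))
        est = np.abs(E.frames) > 1e-8
        tp = np.sum(est[10:] & support[10:])
        fp = np.sum(est[10:] & ~support[10:])
        fn = np.sum(~est[10:] & support[10:])
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.9

    def test_phantom_sparse_component_concentrates_on_vessels(self, fitted, default_phantom):
        _, gt = default_phantom
        E = np.abs(fitted.sparse.frames)
        inside = np.concatenate([E[i][gt.vessel_mask[i]] for i in range(10, 30)])
        outside = np.concatenate([E[i][~gt.vessel_mask[i]] for i in range(10, 30)])
        assert inside.mean() > outside.mean()


class TestIntraFrameRpca:
    def test_zero_frame_gives_zero(self):
        seq = ImageSequence(np.zeros((2, 8, 8)))
        V = xv.intra_frame_rpca(seq, xv.RpcaConfig())
        assert not V.frames.any()

    def test_constant_frame_absorbed_by_offset(self):
        c = 0.05
        seq = ImageSequence(np.full((1, 16, 16), c))
        cfg = xv.RpcaConfig(lambda2_prime=c)  # threshold >= residual level
        V = xv.intra_frame_rpca(seq, cfg)
        assert not V.frames.any()

    def test_single_spike_on_constant_background(self):
        frame = np.full((64, 64), 0.2)
        frame[30, 31] += 1.0
        V = xv.intra_frame_rpca(ImageSequence(frame[None]), xv.RpcaConfig())
        nz = np.argwhere(V.frames[0] != 0)
        assert len(nz) == 1 and tuple(nz[0]) == (30, 31)

    def test_matches_convex_oracle_with_ones_basis(self, rng):
        D, r = 49, 5
        ones = np.ones((D, r))
        lam = 2.1 / 49
        for _ in range(3):
            x = rng.random(D)
            Ce, E = solve_frame(x, ones, lam, lam, max_inner_iters=500, tol=1e-10)
            ours = frame_objective(x, ones, Ce, E, lam, lam)
            ref = convex_oracle(x, ones, lam, lam)
            assert ours <= ref * (1 + 1e-4) + 1e-10


class TestCheckpoint:
    def test_basis_state_roundtrip(self, tmp_path, rng):
        state = BasisState.initialize(30, 4, seed=11)
        state = update_basis(state, rng.normal(size=30), rng.normal(size=4), np.zeros(30), 0.1)
        state.save(tmp_path / "ck")
        loaded = BasisState.load(tmp_path / "ck")
        assert np.array_equal(loaded.Lr, state.Lr)
        assert np.array_equal(loaded.stat_A, state.stat_A)
        assert loaded.frames_seen == state.frames_seen
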