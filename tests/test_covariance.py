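"""Sliding-window scatter recursion and Miller rank-one inverse updates."""

import numpy as np
import numpy.linalg as la
import pytest

from alcmv.covariance import (
    CovarianceState,
    DegenerateUpdate,
    RankOneTerm,
    SingularCovariance,
    batch_covariance,
    init_state,
    load_state,
    miller_inverse_update,
    rank_one_decompose,
    recursive_inverse_update,
    save_state,
    window_update,
)


class TestBatchCovariance:
    def test_constant_channels_have_zero_covariance(self):
        block = np.array([[1.0, 1.0], [2.0, 2.0]])
        np.testing.assert_array_equal(batch_covariance(block, center=True), 0.0)

    def test_hand_evaluated_two_samples(self):
        block = np.array([[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(
            batch_covariance(block, center=True), [[2.0, -2.0], [-2.0, 2.0]]
        )

    def test_matches_numpy_cov_oracle(self, rng):
        block = rng.standard_normal((4, 50))
        np.testing.assert_allclose(
            batch_covariance(block, center=True), np.cov(block), atol=1e-12
        )

    def test_uncentered_is_scatter(self, rng):
        block = rng.standard_normal((3, 7))
        np.testing.assert_array_equal(
            batch_covariance(block, center=False), block @ block.T
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            batch_covariance(np.ones((2, 1)), center=True)


class TestInitState:
    def test_identity_block(self):
        state = init_state(np.eye(2), ns=2, cy=1)
        np.testing.assert_array_equal(state.C, np.eye(2))
        np.testing.assert_array_equal(state.Cinv, np.eye(2))
        assert (state.window_start, state.window_end) == (0, 2)

    def test_window_shorter_than_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="full rank"):
            init_state(rng.standard_normal((4, 3)), ns=3, cy=1)

    def test_stride_bound_enforced(self, rng):
        with pytest.raises(ValueError, match="floor"):
            init_state(rng.standard_normal((4, 8)), ns=8, cy=5)

    def test_dense_inverse(self, rng):
        block = rng.standard_normal((8, 16))
        state = init_state(block, ns=16, cy=2)
        np.testing.assert_allclose(state.C @ state.Cinv, np.eye(8), atol=1e-8)

    def test_rank_deficient_block_names_condition_number(self):
        block = np.ones((3, 6))
        with pytest.raises(SingularCovariance, match="condition number"):
            init_state(block, ns=6, cy=1)


class TestWindowUpdate:
    def test_identical_blocks_cancel(self, rng):
        y = rng.standard_normal((4, 8))
        state = init_state(y, ns=8, cy=2)
        D = rng.standard_normal((4, 2))
        out = window_update(state, D, D)
        np.testing.assert_allclose(out.C, state.C, atol=1e-12)
        assert (out.window_start, out.window_end) == (2, 10)
        assert not out.cinv_valid

    def test_scalar_stream(self):
        y = np.array([[1.0, 2.0, 3.0]])
        state = init_state(y[:, :2], ns=2, cy=1)
        out = window_update(state, y[:, :1], y[:, 2:3])
        assert out.C[0, 0] == pytest.approx(1 + 4 - 1 + 9)

    def test_wrong_block_width(self, rng):
        state = init_state(rng.standard_normal((3, 6)), ns=6, cy=2)
        with pytest.raises(ValueError, match="shape"):
            window_update(state, rng.standard_normal((3, 1)), rng.standard_normal((3, 1)))

    def test_slide_to_end_matches_batch_scatter(self, rng):
        k, ns, cy = 8, 8, 2
        y = rng.standard_normal((k, 64))
        state = init_state(y[:, :ns], ns=ns, cy=cy)
        while state.window_end + cy <= 64:
            D = y[:, state.window_start : state.window_start + cy]
            Dp = y[:, state.window_end : state.window_end + cy]
            state = window_update(state, D, Dp)
        expected = y[:, state.window_start : state.window_end]
        expected = expected @ expected.T
        np.testing.assert_allclose(state.C, expected, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(state.C, state.C.T, rtol=1e-10)


class TestRankOneDecompose:
    def test_hand_case(self):
        terms = rank_one_decompose(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_array_equal(terms[0].to_matrix(), [[1, 0], [3, 0]])
        np.testing.assert_array_equal(terms[1].to_matrix(), [[0, 2], [0, 4]])

    def test_zero_matrix(self):
        terms = rank_one_decompose(np.zeros((2, 2)))
        assert all(np.all(t.to_matrix() == 0) for t in terms)

    def test_conservation_and_rank(self, rng):
        H = rng.standard_normal((5, 5))
        terms = rank_one_decompose(H)
        assert len(terms) == 5
        total = sum(t.to_matrix() for t in terms)
        np.testing.assert_array_equal(total, H)  # bitwise
        for t in terms:
            assert np.sum(la.svd(t.to_matrix(), compute_uv=False) > 1e-12) <= 1

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError):
            rank_one_decompose(np.ones((2, 3)))


class TestMillerUpdate:
    def test_null_update_is_identity(self, rng):
        Cinv = la.inv(np.cov(rng.standard_normal((3, 30))))
        term = RankOneTerm(column=np.zeros(3), index=1)
        np.testing.assert_array_equal(miller_inverse_update(Cinv, term), Cinv)

    def test_scalar_sherman_morrison(self):
        out = miller_inverse_update(np.array([[0.5]]), np.array([[1.0]]))
        assert out[0, 0] == pytest.approx(1.0 / 3.0)

    def test_matches_dense_inverse(self, random_spd):
        rng = np.random.default_rng(5)
        for trial in range(20):
            C = random_spd(4, seed=trial)
            Cinv = la.inv(C)
            col = rng.standard_normal(4)
            idx = int(rng.integers(0, 4))
            t = float(Cinv[idx] @ col)
            if abs(1 + t) <= 0.1:
                continue
            term = RankOneTerm(column=col, index=idx)
            out = miller_inverse_update(Cinv, term)
            np.testing.assert_allclose(out, la.inv(C + term.to_matrix()), rtol=1e-8,
                                       atol=1e-10)

    def test_degenerate_denominator_raises(self):
        # C = I, E = -e1 e1^T makes 1 + tr(Cinv E) = 0 exactly
        term = RankOneTerm(column=np.array([-1.0, 0.0]), index=0)
        with pytest.raises(DegenerateUpdate):
            miller_inverse_update(np.eye(2), term)


class TestRecursiveInverseUpdate:
    def test_zero_H_preserves_state(self, rng):
        state = init_state(rng.standard_normal((4, 8)), ns=8, cy=1)
        out = recursive_inverse_update(state, np.zeros((4, 4)))
        np.testing.assert_array_equal(out.C, state.C)
        np.testing.assert_allclose(out.Cinv, state.Cinv, atol=1e-14)

    def test_single_slide_matches_dense_inverse(self, rng):
        k = 3
        y = rng.standard_normal((k, 10))
        state = init_state(y[:, :6], ns=6, cy=1)
        H = np.outer(y[:, 6], y[:, 6]) - np.outer(y[:, 0], y[:, 0])
        out = recursive_inverse_update(state, H)
        np.testing.assert_allclose(out.Cinv, la.inv(state.C + H), rtol=1e-8, atol=1e-10)

    def test_long_stream_inverse_residual(self, rng):
        k, ns, cy = 8, 16, 1
        N = ns + 200
        y = rng.standard_normal((k, N))
        state = init_state(y[:, :ns], ns=ns, cy=cy)
        worst = 0.0
        for pos in range(ns, N):
            D = y[:, state.window_start : state.window_start + 1]
            Dp = y[:, pos : pos + 1]
            state = recursive_inverse_update(state, Dp @ Dp.T - D @ D.T)
            worst = max(worst, np.abs(state.C @ state.Cinv - np.eye(k)).max())
        assert worst <= 1e-6
        assert state.update_count == 200
        # scatter stayed exactly in sync with the raw samples
        win = y[:, state.window_start : state.window_end]
        np.testing.assert_allclose(state.C, win @ win.T, rtol=1e-10, atol=1e-10)

    def test_degenerate_step_falls_back_and_logs(self):
        state = init_state(np.eye(2), ns=2, cy=1)
        # first column term gives 1 + tr(Cinv E1) = 1 + (-1) = 0, but C + H
        # overall is invertible, so the dense fallback must succeed
        H = np.array([[-1.0, 1.0], [1.0, 1.0]])
        out = recursive_inverse_update(state, H)
        assert len(out.fallback_log) == 1
        np.testing.assert_allclose(out.Cinv, la.inv(state.C + H))

    def test_stale_inverse_rejected(self, rng):
        y = rng.standard_normal((3, 8))
        state = init_state(y[:, :6], ns=6, cy=1)
        stale = window_update(state, y[:, :1], y[:, 6:7])
        with pytest.raises(ValueError, match="stale"):
            recursive_inverse_update(stale, np.zeros((3, 3)))


def test_checkpoint_roundtrip(tmp_path, rng):
    state = init_state(rng.standard_normal((4, 8)), ns=8, cy=2, check_every=3)
    state.fallback_log.append("synthetic event")
    path = tmp_path / "state.npz"
    save_state(path, state)
    back = load_state(path)
    np.testing.assert_array_equal(back.C, state.C)
    np.testing.assert_array_equal(back.Cinv, state.Cinv)
    assert back.ns == 8 and back.cy == 2 and back.check_every == 3
    assert back.fallback_log == ["synthetic event"]
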