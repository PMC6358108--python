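import numpy as np
import pytest

from gstreams.l1 import (
    AdaptationState,
    L1Config,
    RbmParams,
    adapt,
    apply_l1,
    cd_step,
    hidden_prob,
    load_rbm,
    rbm_energy,
    save_rbm,
    sparsity_penalty,
    train_l1,
    weights_to_filters,
)
from gstreams.peripheral import AuditorySpectrogram


def small_params(nv=6, nh=3, seed=0, scale=0.1):
    rng = np.random.default_rng(seed)
    return RbmParams(
        W=scale * rng.standard_normal((nv, nh)),
        A=rng.standard_normal(nv),
        B=rng.standard_normal(nh),
    )


class TestEnergy:
    def test_zero_at_visible_bias_with_hidden_off(self):
        p = small_params()
        assert rbm_energy(p.A, np.zeros(3), p) == pytest.approx(0.0)

    def test_single_unit_quadratic_term(self):
        p = RbmParams(W=np.ones((1, 1)), A=np.zeros(1), B=np.zeros(1))
        assert rbm_energy(np.ones(1), np.zeros(1), p) == pytest.approx(0.5)

    def test_energy_linear_in_each_hidden_unit(self):
        """Turning unit l on changes E by -B_l - sum_k x_k w_kl."""
        p = small_params(seed=2)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(6)
        for l in range(3):
            h0 = np.zeros(3)
            h1 = h0.copy()
            h1[l] = 1.0
            delta = rbm_energy(x, h1, p) - rbm_energy(x, h0, p)
            assert delta == pytest.approx(-p.B[l] - x @ p.W[:, l])

    def test_dimension_mismatch_raises(self):
        p = small_params()
        with pytest.raises(ValueError):
            rbm_energy(np.zeros(5), np.zeros(3), p)


class TestHiddenProb:
    def test_orthogonal_input_gives_half(self):
        p = small_params()
        p.B[:] = 0.0
        probs = hidden_prob(np.zeros(6), p)
        assert np.allclose(probs, 0.5)

    def test_closed_form_logistic_value(self):
        p = RbmParams(W=np.array([[np.log(3.0)]]), A=np.zeros(1), B=np.zeros(1))
        assert hidden_prob(np.ones(1), p)[0] == pytest.approx(0.75)

    def test_monotone_in_drive(self):
        p = small_params(seed=1)
        x = np.ones(6)
        lo = hidden_prob(x, p)
        hi = hidden_prob(2 * x, p)
        drive = x @ p.W + p.B
        up = drive + (x @ p.W) > drive  # sign of added drive
        assert np.all((hi > lo) == ((x @ p.W) > 0))


class TestSparsity:
    def test_symmetric_half(self):
        assert sparsity_penalty(0.5, 0.5) == pytest.approx(np.log(0.5))

    def test_maximized_at_target(self):
        p = 0.07
        qs = np.linspace(0.01, 0.99, 99)
        vals = sparsity_penalty(qs, p)
        assert qs[np.argmax(vals)] == pytest.approx(p, abs=0.01)

    def test_clamped_at_extremes(self):
        assert np.isfinite(sparsity_penalty(0.0, 0.3))
        assert np.isfinite(sparsity_penalty(1.0, 0.3))


def exact_gbrbm_gradient(X, params):
    """Exact max-likelihood weight gradient for a tiny Gaussian-Bernoulli
    RBM by enumerating all hidden states (visible integrated analytically:
    x | h ~ N(A + W h, I))."""
    nv, nh = params.W.shape
    states = np.array(
        [[(s >> l) & 1 for l in range(nh)] for s in range(2**nh)], dtype=float
    )
    # unnormalized log P(h): B.h + 0.5 ||A + W h||^2 - 0.5 ||A||^2
    mu = params.A[None, :] + states @ params.W.T
    logw = states @ params.B + 0.5 * (mu**2).sum(axis=1) - 0.5 * (params.A**2).sum()
    w = np.exp(logw - logw.max())
    w /= w.sum()
    model_xh = (w[:, None, None] * mu[:, :, None] * states[:, None, :]).sum(axis=0)
    ph = 1.0 / (1.0 + np.exp(-(X @ params.W + params.B)))
    data_xh = X.T @ ph / X.shape[0]
    return data_xh - model_xh


class TestCdStep:
    def test_zero_model_zero_batch_no_update(self, rng):
        p = RbmParams(W=np.zeros((4, 2)), A=np.zeros(4), B=np.zeros(2),
                      sparsity_cost=0.0, p=0.5)
        X = np.zeros((8, 4))
        new, err = cd_step(X, p, rng=rng)
        # positive and negative phase are statistically identical in
        # expectation; with zero weights the hidden samples do not couple
        assert np.allclose(new.A, 0.0)
        assert err == pytest.approx(0.0)

    def test_cd_matches_exact_gradient_direction(self):
        """CD-k with many chains approaches the enumerated ML gradient on a
        3-visible / 2-hidden model."""
        rng = np.random.default_rng(0)
        params = RbmParams(
            W=0.3 * rng.standard_normal((3, 2)),
            A=0.1 * rng.standard_normal(3),
            B=0.1 * rng.standard_normal(2),
            sparsity_cost=0.0,
        )
        X = rng.standard_normal((4000, 3)) @ np.diag([1.0, 0.5, 0.2])
        exact = exact_gbrbm_gradient(X, params)
        new, _ = cd_step(X, params, k_steps=25, lr=1.0, rng=rng)
        cd_dir = new.W - params.W
        cos = (cd_dir.ravel() @ exact.ravel()) / (
            np.linalg.norm(cd_dir) * np.linalg.norm(exact)
        )
        assert cos > 0.85

    def test_reconstruction_error_decreases_with_training(self):
        rng = np.random.default_rng(42)
        basis = rng.standard_normal((3, 12))
        X = rng.standard_normal((512, 3)) @ basis + 0.1 * rng.standard_normal((512, 12))
        X = (X - X.mean(0)) / X.std(0)
        log = []
        train_l1(X, L1Config(n_hidden=8, n_epochs=20, batch_size=64, seed=0), log=log)
        assert log[-1]["recon_error"] < log[0]["recon_error"]


class TestTrainL1:
    def test_default_hidden_units_is_400(self):
        assert L1Config().n_hidden == 400

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((256, 12))
        cfg = L1Config(n_hidden=6, n_epochs=2, batch_size=64, seed=3)
        a = train_l1(X, cfg)
        b = train_l1(X, cfg)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.B, b.B)

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            train_l1(np.empty((0, 12)), L1Config(n_hidden=4))


class TestFilters:
    def test_roundtrip_flatten(self):
        p = small_params(nv=384, nh=5, seed=0)
        fb = weights_to_filters(p)
        for k in range(5):
            assert np.array_equal(fb.filters[k].reshape(-1), p.W[:, k])

    def test_single_nonzero_coordinate_bookkeeping(self):
        W = np.zeros((384, 1))
        # frame 2 (last), channel 60 in the (3, 128) layout
        W[2 * 128 + 60, 0] = 1.0
        fb = weights_to_filters(RbmParams(W=W, A=np.zeros(384), B=np.zeros(1)))
        nz = np.argwhere(fb.filters[0] != 0)
        assert nz.tolist() == [[2, 60]]


def make_spec(values):
    return AuditorySpectrogram(values, 0.010, 180.0 * 2 ** (np.arange(values.shape[1]) / 24))


class TestApplyL1:
    def test_zero_spectrogram_zero_response(self):
        from gstreams.l1 import L1FilterBank

        fb = L1FilterBank(np.random.default_rng(0).standard_normal((4, 3, 128)))
        r = apply_l1(make_spec(np.zeros((20, 128))), fb)
        assert np.allclose(r, 0.0)

    def test_impulse_filter_sifts_input(self):
        from gstreams.l1 import L1FilterBank

        rng = np.random.default_rng(1)
        S = rng.standard_normal((30, 128))
        F = np.zeros((1, 3, 128))
        F[0, 2, 40] = 1.0  # current frame, channel 40
        r = apply_l1(make_spec(S), L1FilterBank(F))
        assert np.allclose(r[:, 0], S[:, 40])

    def test_linearity(self):
        from gstreams.l1 import L1FilterBank

        rng = np.random.default_rng(2)
        fb = L1FilterBank(rng.standard_normal((3, 3, 128)))
        S1, S2 = rng.standard_normal((2, 25, 128))
        lhs = apply_l1(make_spec(2.0 * S1 + 0.5 * S2), fb)
        rhs = 2.0 * apply_l1(make_spec(S1), fb) + 0.5 * apply_l1(make_spec(S2), fb)
        assert np.allclose(lhs, rhs)

    def test_matched_filter_peaks_at_alignment(self):
        from gstreams.l1 import L1FilterBank

        rng = np.random.default_rng(3)
        S = np.abs(rng.standard_normal((40, 128)))
        t0 = 20
        F = S[t0 - 2 : t0 + 1][None, :, :].copy()
        r = apply_l1(make_spec(S), L1FilterBank(F))
        assert int(np.argmax(r[:, 0])) == t0


class TestAdaptation:
    def test_zero_input_relaxes_to_one(self):
        state = AdaptationState(a=0.4 * np.ones(2))
        out = adapt(np.zeros((500, 2)), state)
        assert np.allclose(out.values, 0.0)
        assert np.allclose(state.a, 1.0, atol=1e-6)

    def test_steady_state_matches_closed_form(self):
        """a* = 1 / (1 + tau_a * alpha * c) for constant drive c."""
        c = 5e4
        state = AdaptationState(a=np.ones(1))
        out = adapt(np.full((4000, 1), c), state)
        a_star = 1.0 / (1.0 + state.tau_a * state.alpha * c)
        assert state.a[0] == pytest.approx(a_star, abs=1e-6)
        assert out.values[-1, 0] == pytest.approx(a_star * c, rel=1e-5)

    def test_steady_state_decreasing_in_drive(self):
        finals = []
        for c in (1e3, 1e4, 1e5):
            state = AdaptationState(a=np.ones(1))
            adapt(np.full((3000, 1), c), state)
            finals.append(state.a[0])
        assert finals[0] > finals[1] > finals[2]

    def test_never_amplifies(self, rng):
        raw = np.abs(rng.standard_normal((200, 4))) * 1e4
        out = adapt(raw, AdaptationState(a=np.ones(4)))
        assert np.all(out.values <= out.raw + 1e-12)


def test_rbm_hdf5_roundtrip(tmp_path):
    p = small_params(nv=8, nh=3, seed=4)
    save_rbm(tmp_path / "rbm.h5", p, L1Config(n_hidden=3))
    back = load_rbm(tmp_path / "rbm.h5")
    assert np.array_equal(back.W, p.W)
    assert back.p == p.p
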