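import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphema.ebm import (EBMConfig, EnergyNet, LogitSample, grid_inference,
                          grid_scores, logit, nce_loss, sample_targets,
                          sigmoid, sliding_sigma)
from graphema.nn import Tensor


class TestLogitSigmoid:
    def test_half_maps_to_zero(self):
        assert logit(0.5) == 0.0

    def test_inverse_pair(self):
        assert sigmoid(logit(0.3)) == pytest.approx(0.3, abs=1e-12)

    def test_clamped_extreme(self):
        assert logit(1.0, eps=1e-6) == pytest.approx(np.log((1 - 1e-6) / 1e-6),
                                                     abs=1e-6)
        assert logit(1.0, eps=1e-6) == pytest.approx(13.8155, abs=1e-3)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(deadline=None)
    def test_roundtrip_identity(self, p):
        assert abs(sigmoid(logit(p)) - p) < 1e-9


class TestSlidingSigma:
    def test_centered_value(self):
        # (logit(0.7) - logit(0.5)) / 0.675
        assert sliding_sigma(0.5, 0.2) == pytest.approx(
            np.log(0.7 / 0.3) / 0.675, abs=1e-12)

    def test_upper_branch_switch(self):
        got = sliding_sigma(0.9, 0.2)
        expected = (logit(0.9) - logit(0.7)) / 0.675
        assert got == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=0.99),
           st.floats(min_value=0.01, max_value=0.5))
    @settings(deadline=None)
    def test_strictly_positive(self, mu, gamma):
        assert sliding_sigma(mu, gamma) > 0.0

    def test_continuous_within_branch(self):
        mus = np.linspace(0.3, 0.6, 50)
        vals = [sliding_sigma(m, 0.1) for m in mus]
        assert np.all(np.abs(np.diff(vals)) < 0.05)


class TestSampling:
    def test_beta_to_zero_limit(self):
        cfg = EBMConfig(m_total=4, beta=1e-12, gamma=0.1)
        rng = np.random.default_rng(0)
        y0, _ = sample_targets(0.35, cfg, rng)
        assert y0.value == pytest.approx(logit(0.35), abs=1e-4)

    def test_adversarial_moments_match_proposal(self):
        cfg = EBMConfig(m_total=100_001, beta=0.05, gamma=0.15)
        rng = np.random.default_rng(1)
        _, adv = sample_targets(0.6, cfg, rng)
        vals = np.array([a.value for a in adv])
        sd = sliding_sigma(0.6, 0.15)
        se = sd / np.sqrt(len(vals))
        assert abs(vals.mean() - logit(0.6)) < 3 * se
        assert abs(vals.std() - sd) / sd < 0.02

    def test_samples_carry_proposal_log_density(self):
        cfg = EBMConfig(m_total=3, beta=0.05, gamma=0.1)
        rng = np.random.default_rng(2)
        y0, adv = sample_targets(0.4, cfg, rng)
        sd = sliding_sigma(0.4, 0.1)
        mu = logit(0.4)
        for s in [y0] + adv:
            expected = (-0.5 * ((s.value - mu) / sd) ** 2
                        - np.log(sd * np.sqrt(2 * np.pi)))
            assert s.log_density == pytest.approx(expected, abs=1e-12)


def naive_nce(f, logp):
    """Direct transcription of the contrastive loss, no log-sum-exp trick."""
    total = 0.0
    for i in range(f.shape[0]):
        num = np.exp(f[i, 0] - logp[i, 0])
        den = sum(np.exp(f[i, m] - logp[i, m]) for m in range(f.shape[1]))
        total += -np.log(num / den)
    return total / f.shape[0]


class TestNceLoss:
    def test_constant_arguments_give_log_m(self):
        f = Tensor(np.zeros((5, 8)))
        logp = np.zeros((5, 8))
        assert nce_loss(f, logp).item() == pytest.approx(np.log(8.0), abs=1e-12)

    def test_saturation_when_true_dominates(self):
        f = np.zeros((1, 8)); f[0, 0] = 200.0
        assert nce_loss(Tensor(f), np.zeros((1, 8))).item() < 1e-8

    def test_non_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = rng.standard_normal((4, 6)) * 5
            logp = rng.standard_normal((4, 6))
            assert nce_loss(Tensor(f), logp).item() >= 0.0

    def test_matches_naive_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            f = rng.standard_normal((3, 7)) * 3
            logp = rng.standard_normal((3, 7))
            got = nce_loss(Tensor(f), logp).item()
            assert got == pytest.approx(naive_nce(f, logp), abs=1e-6)

    def test_non_finite_energy_rejected(self):
        f = np.zeros((1, 4)); f[0, 1] = np.nan
        with pytest.raises(FloatingPointError):
            nce_loss(Tensor(f), np.zeros((1, 4)))


class TestEnergyNet:
    def test_eval_deterministic(self):
        cfg = EBMConfig(x_dim=8, hidden=(16, 16), dropout=0.4, seed=5)
        net = EnergyNet(cfg)
        net.eval()
        x = Tensor(np.ones((2, 8)))
        y = Tensor(np.array([[0.1], [0.2]]))
        assert np.array_equal(net(x, y).data, net(x, y).data)

    def test_finite_over_clamp_range(self):
        cfg = EBMConfig(x_dim=4, hidden=(8,), seed=6)
        net = EnergyNet(cfg)
        net.eval()
        ys = logit(grid_scores(50), cfg.eps_clamp)
        out = net(Tensor(np.zeros((50, 4))), Tensor(ys.reshape(-1, 1))).data
        assert np.all(np.isfinite(out))

    def test_skip_depth_changes_layer_widths(self):
        cfg = EBMConfig(x_dim=4, hidden=(8, 8, 8), skip_depth=2, seed=7)
        net = EnergyNet(cfg)
        assert net.layers[0].W.shape[0] == 5      # x + y
        assert net.layers[1].W.shape[0] == 9      # h + y re-appended
        assert net.layers[2].W.shape[0] == 9


class TestGridInference:
    def _quadratic_net(self, center):
        """Energy (y - logit(center))^2 realized as a closure-compatible net."""
        class Quad:
            cfg = EBMConfig(x_dim=1, grid_n=1000)

            def eval(self):
                pass

            def __call__(self, x, y):
                return Tensor((y.data - logit(center)) ** 2)
        return Quad()

    def test_quadratic_minimum_recovered(self):
        net = self._quadratic_net(0.3)
        got = grid_inference(net, np.zeros(1), grid_n=1000)
        assert abs(got - 0.3) <= 1.0 / 1000

    def test_monotone_energy_hits_boundary(self):
        class Mono:
            cfg = EBMConfig(x_dim=1, grid_n=200)

            def eval(self):
                pass

            def __call__(self, x, y):
                return Tensor(-y.data)
        got = grid_inference(Mono(), np.zeros(1), grid_n=200)
        assert got == grid_scores(200)[-1]

    def test_matches_exhaustive_argmin(self):
        cfg = EBMConfig(x_dim=4, hidden=(8, 8), seed=8, grid_n=250)
        net = EnergyNet(cfg)
        x = np.random.default_rng(9).standard_normal(4)
        got = grid_inference(net, x)
        scores = grid_scores(250)
        net.eval()
        energies = [net(Tensor(x.reshape(1, -1)),
                        Tensor([[logit(s, cfg.eps_clamp)]])).data[0, 0]
                    for s in scores]
        assert got == scores[int(np.argmin(energies))]
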