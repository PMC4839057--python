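"""Identification machinery: weighting, loss gradients, BIC, partitioning."""

import numpy as np
import pytest

from hybridferm.model import ANNParameters, pack_batches
from hybridferm.plant import BatchConditions, constant_kinetics, simulate_true_batch
from hybridferm.training import (
    TrainingConfig,
    bic,
    build_measurements,
    compute_sigma,
    input_scaling_from_batches,
    loss,
    output_scaling_from_batches,
    partition_study,
    partition_by_acetate,
    train,
)

from conftest import split_partitions


def _scaled_batch(scale=1.0, **kw):
    rec = simulate_true_batch(
        BatchConditions(X_ind=20.0, induction_duration=22.0),
        constant_kinetics(mu=0.05, v=0.01, a_base=1e-3),
        X0=18.0, **kw,
    )
    rec.offline.X_od = rec.offline.X_od * scale
    return rec


class TestSigma:
    def test_pooled_sample_variance(self):
        rec = _scaled_batch()
        rec.offline.t = np.array([0.0, 3.0, 25.0])
        rec.offline.X_od = np.array([10.0, 20.0, 30.0])
        sigma = compute_sigma([rec])
        assert sigma["X"] == pytest.approx(100.0)

    def test_variance_scales_quadratically(self):
        s1 = compute_sigma([_scaled_batch(1.0)])
        s2 = compute_sigma([_scaled_batch(2.0)])
        assert s2["X"] == pytest.approx(4.0 * s1["X"])

    def test_degenerate_variance_rejected(self):
        rec = _scaled_batch()
        rec.offline.X_od = np.full_like(rec.offline.X_od, 50.0)
        with pytest.raises(ValueError):
            compute_sigma([rec])


def test_loss_weighting_arithmetic(zero_feed_record, constant_mu_params):
    """A model reproducing the data exactly has zero loss and gradient; a
    single residual of 2 with sigma 4 contributes exactly 1."""
    rec = zero_feed_record
    packed = pack_batches([rec])
    meas = build_measurements([rec])
    theta = constant_mu_params.to_vector()
    sigma = {"X": 4.0, "PX": 1.0, "B": 1.0}

    # make the offline data equal the model's own predictions
    from hybridferm.model import euler_integrate, predict_offline
    traj = euler_integrate(constant_mu_params, rec)
    rec.offline.X_od = predict_offline(traj, rec.offline.t, "X")
    rec.offline.PX = predict_offline(traj, rec.offline.t, "PX")
    rec.online.u_Base = np.zeros_like(rec.online.u_Base)
    packed = pack_batches([rec])
    meas = build_measurements([rec])
    f0, g0 = loss(theta, constant_mu_params, packed, meas, sigma)
    assert f0 == pytest.approx(0.0, abs=1e-18)
    assert np.allclose(g0, 0.0, atol=1e-12)

    rec.offline.X_od = rec.offline.X_od + np.array([2.0] + [0.0] * (rec.offline.t.size - 1))
    meas = build_measurements([rec])
    f1, _ = loss(theta, constant_mu_params, packed, meas, sigma)
    assert f1 == pytest.approx(1.0)


def test_loss_gradient_matches_finite_differences(study_noiseless_doe):
    """Sensitivity-propagated gradients agree with central differences to
    1e-5 relative over all weights, for several random networks, on a
    two-batch toy study."""
    toy = study_noiseless_doe[:2]
    packed = pack_batches(toy)
    meas = build_measurements(toy)
    sigma = compute_sigma(toy)
    in_off, in_sc = input_scaling_from_batches(toy)
    out_off, out_sc = output_scaling_from_batches(toy)
    rng = np.random.default_rng(1234)
    for _ in range(5):
        p0 = ANNParameters.random(2, rng, in_off, in_sc, out_off, out_sc)
        theta = p0.to_vector()
        _, g = loss(theta, p0, packed, meas, sigma)
        g_fd = np.empty_like(g)
        for i in range(theta.size):
            e = np.zeros_like(theta); e[i] = 1e-6
            fp = loss(theta + e, p0, packed, meas, sigma, with_grad=False)[0]
            fm = loss(theta - e, p0, packed, meas, sigma, with_grad=False)[0]
            g_fd[i] = (fp - fm) / 2e-6
        rel = np.abs(g - g_fd) / np.maximum(np.maximum(np.abs(g), np.abs(g_fd)), 1e-8)
        assert rel.max() <= 1e-5


class TestBic:
    def test_direct_evaluation(self):
        assert bic(100.0, 100, 10) == pytest.approx(-10 * np.log(100.0), rel=1e-12)

    def test_parameter_penalty_monotone(self):
        assert bic(50.0, 200, 10) > bic(50.0, 200, 20)

    def test_halved_wsse_gains_n_log2(self):
        n = 150
        assert bic(50.0, n, 12) - bic(100.0, n, 12) == pytest.approx(n * np.log(2.0))

    def test_degenerate_wsse_warns(self):
        with pytest.warns(UserWarning):
            bic(0.0, 100, 5)


class TestPartitioning:
    def test_two_thirds_split_of_24(self, study_noiseless_doe):
        recs = [r for r in study_noiseless_doe]
        tags = partition_study(recs, (2 / 3, 1 / 3), seed=5)
        assert tags.count("train") == 16
        assert tags.count("validation") == 8
        assert partition_study(recs, (2 / 3, 1 / 3), seed=5) == tags  # deterministic
        assert all(t in ("train", "validation", "test") for t in tags)

    def test_every_batch_in_exactly_one_partition(self, study_noiseless_doe):
        tags = partition_study(list(study_noiseless_doe), (0.5, 0.25), seed=0)
        assert len(tags) == len(study_noiseless_doe)
        assert tags.count("train") + tags.count("validation") + tags.count("test") == len(tags)

    def test_acetate_partitioning(self, study_full_noisy):
        recs = [r for r in study_full_noisy]
        partition_by_acetate(recs, seed=17)
        with_ac = [r for r in recs if r.offline.acetate is not None]
        without = [r for r in recs if r.offline.acetate is None]
        assert all(r.partition == "test" for r in without)
        n_tr = sum(r.partition == "train" for r in with_ac)
        n_val = sum(r.partition == "validation" for r in with_ac)
        assert n_tr + n_val == len(with_ac)
        assert abs(n_tr - 2 * n_val) <= 2

    def test_bad_fractions_rejected(self, study_noiseless_doe):
        with pytest.raises(ValueError):
            partition_study(list(study_noiseless_doe), (0.7, 0.5), seed=0)


def test_restart_bookkeeping(study_noiseless_doe):
    """The restart log has one entry per restart; adding restarts never
    worsens the best validation loss (prefix-stable seeding)."""
    tr, val = split_partitions(study_noiseless_doe)
    cfg1 = TrainingConfig(n_restarts=1, max_iterations=40, patience=10, seed=2)
    cfg3 = TrainingConfig(n_restarts=3, max_iterations=40, patience=10, seed=2)
    fit1 = train(2, tr[:4], val[:2], cfg1)
    fit3 = train(2, tr[:4], val[:2], cfg3)
    assert len(fit1.restart_log) == 1
    assert len(fit3.restart_log) == 3
    assert fit3.restart_log[0]["val_wsse_best"] == pytest.approx(
        fit1.restart_log[0]["val_wsse_best"]
    )
    assert fit3.wsse["validation"] <= fit1.wsse["validation"] + 1e-12
    best_so_far = np.minimum.accumulate([r["val_wsse_best"] for r in fit3.restart_log])
    assert np.all(np.diff(best_so_far) <= 0)


def test_fit_result_json_roundtrip(fit_noiseless):
    from hybridferm.training import FitResult

    doc = fit_noiseless.to_json()
    back = FitResult.from_json(doc)
    assert back.hidden_size == fit_noiseless.hidden_size
    assert back.wsse == pytest.approx(fit_noiseless.wsse)
    assert np.array_equal(back.params.w1, fit_noiseless.params.w1)
    assert back.config.seed == fit_noiseless.config.seed


def test_empty_partition_rejected(study_noiseless_doe):
    tr, val = split_partitions(study_noiseless_doe)
    with pytest.raises(ValueError):
        train(2, [], val, TrainingConfig(n_restarts=1))
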