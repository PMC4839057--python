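"""Synthetic plant: physics, measurement model and study structure."""

import numpy as np
import pytest

from hybridferm.errors import SimulationError
from hybridferm.plant import (
    BatchConditions,
    apply_measurement_model,
    constant_kinetics,
    default_true_kinetics,
    example_ann_kinetics,
    generate_study,
    simulate_true_batch,
)


@pytest.fixture(scope="module")
def noiseless_batch(kinetics):
    return simulate_true_batch(
        BatchConditions(X_ind=58.0, induction_duration=24.0), kinetics, batch_id="demo"
    )


def test_default_kinetics_shape(kinetics):
    """Growth falls with biomass; productivity rate is product-inhibited
    (over a decade down between PX = 0.125 and PX = 1.0)."""
    hi, lo = 0.8, -0.8
    assert kinetics.mu_fn(50.0, 0.1, 0.0, 0.0, hi) > kinetics.mu_fn(100.0, 0.1, 0.0, 0.0, hi)
    assert kinetics.mu_fn(80.0, 0.1, 0.0, 0.0, hi) > kinetics.mu_fn(80.0, 0.1, 0.0, 0.0, lo)
    v_uninhibited = kinetics.v_fn(80.0, 0.0, 0.0, 0.0, 0.0)
    assert np.isclose(kinetics.v_fn(80.0, 0.0, 0.0, 0.0, 0.0), v_uninhibited, rtol=1e-6)
    assert kinetics.v_fn(80.0, 1.0, 0.0, 0.0, 0.0) < 0.05 * kinetics.v_fn(80.0, 0.125, 0.0, 0.0, 0.0)
    # mu non-negative across the scanned design region
    g = np.meshgrid(
        np.linspace(30, 130, 5), np.linspace(0, 1, 3),
        np.linspace(-1.5, 1, 4), np.linspace(-1, 1.3, 4), np.linspace(-1.3, 2.5, 5),
    )
    assert np.all(kinetics.mu_fn(*g) >= 0.0)
    assert np.all(kinetics.v_fn(*g) >= 0.0)


def test_base_addition_correlates_with_biomass(noiseless_batch, kinetics):
    """Cumulative base equals a_base * (X V - X0 V0) at every grid point, and
    the interval-averaged online base rates reconstruct it exactly."""
    tr = noiseless_batch.truth
    expected = kinetics.a_base_true * (tr.X * tr.V - tr.X.iloc[0] * tr.V.iloc[0])
    assert np.allclose(tr.B, expected, rtol=1e-8, atol=1e-14)
    b_online = np.cumsum(noiseless_batch.online.u_Base[:-1]) * 0.5
    b_truth = np.interp(noiseless_batch.online.t[1:], tr.t, tr.B)
    assert np.allclose(b_online, b_truth, rtol=1e-8, atol=1e-14)


def test_specific_product_flat_before_induction(noiseless_batch):
    tr = noiseless_batch.truth
    pre = tr.PX[tr.t < noiseless_batch.t_induction]
    assert np.all(pre.to_numpy() == pre.iloc[0])
    assert np.all(np.diff(tr.V) >= 0)  # volume non-decreasing
    assert np.allclose(tr.P, tr.PX * tr.X)  # volumetric product is algebraic


def test_zero_feed_constant_mu_is_exponential(zero_feed_record):
    """With no feeds and mu fixed at 0.1 1/h, X(10 h)/X(0) = e within 2 %."""
    tr = zero_feed_record.truth
    ratio = tr.X.iloc[-1] / tr.X.iloc[0]
    assert tr.t.iloc[-1] == pytest.approx(10.0)
    assert ratio == pytest.approx(np.e, rel=0.02)


def test_plant_euler_first_order_convergence(kinetics):
    """Global biomass error against a 0.01 h reference roughly doubles with
    the step (first-order convergence)."""
    cond = BatchConditions(X_ind=58.0, induction_duration=24.0)
    ref = simulate_true_batch(cond, kinetics, step=0.01, X0=52.0)
    probe = np.linspace(1.0, 26.0, 26)
    x_ref = np.interp(probe, ref.truth.t, ref.truth.X)
    err = {}
    for s in (0.05, 0.1, 0.2):
        r = simulate_true_batch(cond, kinetics, step=s, X0=52.0)
        err[s] = np.abs(np.interp(probe, r.truth.t, r.truth.X) - x_ref).max()
    assert err[0.05] < err[0.1] < err[0.2]
    assert err[0.1] / err[0.05] < 2.5
    assert err[0.2] / err[0.1] < 2.5


def test_nonphysical_state_raises():
    bad = constant_kinetics(mu=-5.0)  # forced decay crosses zero at Euler scale
    with pytest.raises(SimulationError):
        simulate_true_batch(
            BatchConditions(X_ind=10.0, induction_duration=22.0), bad, step=0.25, X0=1.0
        )


def test_measurement_model_determinism_and_cvs(noiseless_batch):
    """Same seed gives identical output; Monte-Carlo CV of replicated OD
    samples matches the configured 2.5 % within 5 % relative."""
    a = apply_measurement_model(noiseless_batch, seed=42)
    b = apply_measurement_model(noiseless_batch, seed=42)
    assert np.array_equal(a.offline.X_od, b.offline.X_od)
    assert np.array_equal(a.online.u_Base, b.online.u_Base)
    assert not np.array_equal(a.offline.X_od, apply_measurement_model(noiseless_batch, 43).offline.X_od)

    ratios = []
    for seed in range(3500):
        rec = apply_measurement_model(noiseless_batch, seed=seed, resample_schedule=False)
        with np.errstate(invalid="ignore"):
            r = rec.offline.X_od / noiseless_batch.offline.X_od
        ratios.extend(r[np.isfinite(r)])
    cv = np.std(ratios)
    assert cv == pytest.approx(0.025, rel=0.05)


def test_study_structure(study_full_noisy):
    """53 batches; 23-run Doehlert core; 2/3-1/3 train/validation split of the
    designed batches; >= 22 h of induction coverage; ~3.5 offline samples."""
    recs = study_full_noisy
    assert len(recs) == 53
    doe1 = [r for r in recs if r.scenario == "doe1"]
    assert len(doe1) == 23
    n_tr = sum(r.partition == "train" for r in doe1)
    n_val = sum(r.partition == "validation" for r in doe1)
    assert n_tr + n_val == 23
    assert abs(n_tr - 2 * n_val) <= 2  # 2:1 within one batch
    assert all(r.partition == "test" for r in recs if r.scenario in
               ("failed_feed", "variable_conditions", "doe2", "doe3"))
    assert all(r.t_end - r.t_induction >= 22.0 - 1e-9 for r in recs)
    assert all(22.0 <= r.conditions.induction_duration <= 30.0 for r in recs
               if r.scenario == "doe1")
    n_samples = [r.offline.t.size for r in recs]
    assert min(n_samples) >= 2 and max(n_samples) <= 6
    assert 3.0 <= np.mean(n_samples) <= 4.0
    # every batch carries a sample at induction and at induction + 22 h
    for r in recs:
        assert np.min(np.abs(r.offline.t - r.t_induction)) < 1e-6
        assert np.min(np.abs(r.offline.t - (r.t_induction + 22.0))) < 1e-6
    # online grid uniform at 0.5 h
    for r in recs:
        assert np.allclose(np.diff(r.online.t), 0.5)


def test_study_deterministic(kinetics, study_full_noisy):
    again = generate_study(kinetics, seed=3, noise=True)
    for a, b in zip(study_full_noisy, again):
        assert np.array_equal(a.offline.X_od, b.offline.X_od)
        assert np.array_equal(a.online.u_Base, b.online.u_Base)
        assert a.partition == b.partition


def test_ann_truth_kinetics_reproducible_and_plausible():
    params, kin = example_ann_kinetics()
    assert kin.mu_fn(70.0, 0.3, 0.0, 0.0, 0.0) > 0
    rec = simulate_true_batch(BatchConditions(X_ind=58.0, induction_duration=24.0), kin)
    assert rec.truth.X.iloc[-1] > rec.truth.X.iloc[0]
    assert np.all(rec.truth.PX.to_numpy() >= 0)
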