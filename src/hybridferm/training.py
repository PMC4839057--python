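"""Parameter identification and structure selection for the hybrid model.

Weights are identified by minimizing the variance-weighted sum of squared
residuals

    min_w  sum (c_exp - c(t, w))^2 / sigma_c

over the fitted variables: biomass X and specific productivity PX at offline
sample times, and cumulative base addition B at every online logging time
(base is logged at high frequency and correlates with biomass formation, so
it carries most of the growth dynamics).  ``sigma_c`` is the pooled sample
variance of each variable over the training measurements.

Gradients come from the forward sensitivity equations integrated along with
the states, so they are exact for the discrete Euler trajectory.  Minimization
is gradient-based (L-BFGS) from at least ten random weight initializations;
the validation partition is monitored every iteration and the weights are
snapshotted at the validation optimum (early stopping).  Network structures
(hidden-node counts) are compared by a Bayesian information criterion,
oriented so that larger is better, with the structure chosen as the greatest
validation BIC among candidates whose training performance stays consistent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import IntegrationError
from .model import (
    ANNParameters,
    PackedStudy,
    ann_eval,
    integrate_packed,
    pack_batches,
    EULER_STEP,
)
from .plant import BatchRecord, ONLINE_STEP

__all__ = [
    "TrainingConfig",
    "FitResult",
    "Measurements",
    "build_measurements",
    "compute_sigma",
    "loss",
    "train",
    "bic",
    "select_structure",
    "partition_study",
    "partition_by_acetate",
    "input_scaling_from_batches",
    "output_scaling_from_batches",
]

logger = logging.getLogger(__name__)

FITTED_VARIABLES = ("X", "PX", "B")


@dataclass
class TrainingConfig:
    """Knobs of the identification procedure."""

    n_restarts: int = 10
    max_iterations: int = 300
    patience: int = 25
    seed: int = 0
    euler_step: float = EULER_STEP
    hidden_sizes: tuple[int, ...] = (1, 2, 3, 5, 8)

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class Measurements:
    """Fitted-variable observations located on the Euler grid.

    For each variable: batch index, left grid node, interpolation fraction
    and the measured value.  X and PX live at offline sample times (linear
    interpolation between nodes); B lives at online logging times, which
    coincide with grid nodes, and is the running left-rectangle sum of the
    measured base addition rate.
    """

    batch_idx: dict[str, np.ndarray]
    node_idx: dict[str, np.ndarray]
    frac: dict[str, np.ndarray]
    value: dict[str, np.ndarray]

    def n_points(self, variables: Sequence[str] = FITTED_VARIABLES) -> int:
        return int(sum(self.value[v].size for v in variables))


def build_measurements(batches: Sequence[BatchRecord], step: float = EULER_STEP) -> Measurements:
    b_idx: dict[str, list] = {v: [] for v in FITTED_VARIABLES}
    n_idx: dict[str, list] = {v: [] for v in FITTED_VARIABLES}
    frac: dict[str, list] = {v: [] for v in FITTED_VARIABLES}
    val: dict[str, list] = {v: [] for v in FITTED_VARIABLES}

    for k, b in enumerate(batches):
        # offline X and PX
        rel = (b.offline.t - b.t0) / step
        i = np.floor(rel + 1e-9).astype(int)
        n_max = int(round((b.online.t[-1] - b.t0) / step))
        i = np.clip(i, 0, n_max - 1)
        f = rel - i
        for var, data in (("X", b.offline.X_od), ("PX", b.offline.PX)):
            b_idx[var] += [np.full(rel.size, k)]
            n_idx[var] += [i]
            frac[var] += [f]
            val[var] += [np.asarray(data, dtype=float)]
        # cumulative base at online times (skip t0 where B = 0 trivially)
        b_meas = np.cumsum(b.online.u_Base[:-1]) * ONLINE_STEP
        rel_b = (b.online.t[1:] - b.t0) / step
        ib = np.round(rel_b).astype(int)
        b_idx["B"] += [np.full(ib.size, k)]
        n_idx["B"] += [np.clip(ib, 0, n_max)]
        frac["B"] += [np.zeros(ib.size)]
        val["B"] += [b_meas]

    cat = lambda d: {v: np.concatenate(d[v]).astype(float) for v in FITTED_VARIABLES}
    icat = lambda d: {v: np.concatenate(d[v]).astype(int) for v in FITTED_VARIABLES}
    return Measurements(batch_idx=icat(b_idx), node_idx=icat(n_idx), frac=cat(frac), value=cat(val))


def compute_sigma(batches: Sequence[BatchRecord], step: float = EULER_STEP) -> dict[str, float]:
    """Pooled sample variance of each fitted variable over the given batches."""
    meas = build_measurements(batches, step=step)
    sigma = {}
    for v in FITTED_VARIABLES:
        vals = meas.value[v]
        if vals.size < 2:
            raise ValueError(f"need at least 2 measurements of {v} to estimate its variance")
        s = float(np.var(vals, ddof=1))
        if s <= 0.0:
            raise ValueError(f"degenerate (zero) variance for variable {v}")
        sigma[v] = s
    return sigma


def _predicted(states, sens, meas: Measurements, var: str):
    b = meas.batch_idx[var]; i = meas.node_idx[var]; f = meas.frac[var]
    S = states[var]
    pred = (1.0 - f) * S[b, i] + f * S[b, np.minimum(i + 1, S.shape[1] - 1)]
    if sens is None:
        return pred, None
    G = sens[var]
    dpred = (1.0 - f)[:, None] * G[b, i] + f[:, None] * G[b, np.minimum(i + 1, G.shape[1] - 1)]
    return pred, dpred


def loss(
    theta: np.ndarray,
    template: ANNParameters,
    packed: PackedStudy,
    meas: Measurements,
    sigma: dict[str, float],
    with_grad: bool = True,
):
    """Weighted SSE of the hybrid model and (optionally) its exact gradient.

    Returns ``(wsse, grad)`` with ``grad=None`` when ``with_grad`` is False.
    Integration failures yield an infinite loss with a diagnostic log entry.
    """
    params = template.with_vector(theta)
    try:
        states, _, sens = integrate_packed(params, packed, with_sensitivities=with_grad)
    except IntegrationError as err:
        logger.warning("integration failed during loss evaluation: %s", err)
        g = np.zeros(theta.size) if with_grad else None
        return np.inf, g
    wsse = 0.0
    grad = np.zeros(theta.size) if with_grad else None
    for var in FITTED_VARIABLES:
        pred, dpred = _predicted(states, sens, meas, var)
        r = meas.value[var] - pred
        wsse += float(np.dot(r, r)) / sigma[var]
        if with_grad:
            grad += (-2.0 / sigma[var]) * (r @ dpred)
    return wsse, grad


def input_scaling_from_batches(batches: Sequence[BatchRecord]):
    """z-score offsets/scales for [X, PX, T, pH, u_C] from the training data."""
    X = np.concatenate([b.offline.X_od for b in batches])
    PX = np.concatenate([b.offline.PX for b in batches])
    T = np.concatenate([b.online.T for b in batches])
    pH = np.concatenate([b.online.pH for b in batches])
    uC = np.concatenate([b.online.u_C for b in batches])
    offset = np.array([x.mean() for x in (X, PX, T, pH, uC)])
    scale = np.array([max(float(x.std()), 1e-8) for x in (X, PX, T, pH, uC)])
    scale[scale < 1e-6] = 1.0  # uninformative (constant) inputs
    return offset, scale


def output_scaling_from_batches(batches: Sequence[BatchRecord], step: float = EULER_STEP):
    """Affine output scaling placing random networks in a plausible regime.

    mu and v_px use fixed physical ranges; the a_base offset is estimated per
    batch as measured cumulative base over the measured increase of total
    biomass X*V between the first and last offline samples.
    """
    a0 = []
    for b in batches:
        packed = pack_batches([b], step=step)
        t_grid = b.t0 + step * np.arange(packed.n_steps[0] + 1)
        order = np.argsort(b.offline.t)
        t_first, t_last = b.offline.t[order[0]], b.offline.t[order[-1]]
        x_first, x_last = b.offline.X_od[order[0]], b.offline.X_od[order[-1]]
        v_first = np.interp(t_first, t_grid, packed.V[0])
        v_last = np.interp(t_last, t_grid, packed.V[0])
        b_cum = np.concatenate([[0.0], np.cumsum(b.online.u_Base[:-1]) * ONLINE_STEP])
        b_last = np.interp(t_last, b.online.t, b_cum)
        denom = x_last * v_last - x_first * v_first
        if denom > 0:
            a0.append(b_last / denom)
    a_mid = float(np.median(a0)) if a0 else 1e-3
    a_mid = max(a_mid, 1e-12)
    offset = np.array([0.275, 0.1, a_mid])
    scale = np.array([0.325, 0.2, 0.5 * a_mid])
    return offset, scale


@dataclass
class FitResult:
    """Outcome of training one network structure."""

    params: ANNParameters
    hidden_size: int
    wsse: dict[str, float]
    bic: dict[str, float]
    n_points: dict[str, int]
    sigma: dict[str, float]
    restart_log: list[dict]
    config: TrainingConfig

    def to_json(self) -> str:
        doc = {
            "hidden_size": self.hidden_size,
            "wsse": self.wsse,
            "bic": self.bic,
            "n_points": self.n_points,
            "sigma": self.sigma,
            "restart_log": self.restart_log,
            "config": {
                "n_restarts": self.config.n_restarts,
                "max_iterations": self.config.max_iterations,
                "patience": self.config.patience,
                "seed": self.config.seed,
                "euler_step": self.config.euler_step,
            },
            "params": json.loads(self.params.to_json()),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        doc = json.loads(text)
        return cls(
            params=ANNParameters.from_json(json.dumps(doc["params"])),
            hidden_size=doc["hidden_size"],
            wsse=doc["wsse"],
            bic=doc["bic"],
            n_points={k: int(v) for k, v in doc["n_points"].items()},
            sigma=doc["sigma"],
            restart_log=doc["restart_log"],
            config=TrainingConfig(**doc["config"]),
        )


def bic(weighted_sse: float, n_points: int, n_params: int) -> float:
    """Bayesian information criterion, oriented so larger is better:
    ``-n ln(WSSE/n) - p ln(n)`` (Gaussian-likelihood form)."""
    if n_points <= n_params:
        warnings.warn(
            f"BIC with n_points={n_points} <= n_params={n_params} is poorly determined",
            stacklevel=2,
        )
    if weighted_sse <= 0:
        warnings.warn("non-positive WSSE clipped to 1e-12 for BIC", stacklevel=2)
    w = max(float(weighted_sse), 1e-12)
    n = float(n_points)
    return -n * np.log(w / n) - n_params * np.log(n)


def train(
    hidden_size: int,
    train_batches: Sequence[BatchRecord],
    val_batches: Sequence[BatchRecord],
    config: TrainingConfig | None = None,
) -> FitResult:
    """Identify network weights on the training partition.

    Each restart draws random initial weights, minimizes the training loss
    with exact sensitivity gradients and records the weights at the best
    validation loss seen; the restart whose validation optimum is lowest wins.
    Fully reproducible given ``config.seed``.
    """
    if config is None:
        config = TrainingConfig()
    if not train_batches or not val_batches:
        raise ValueError("training and validation partitions must be non-empty")
    step = config.euler_step

    packed_tr = pack_batches(train_batches, step=step)
    packed_val = pack_batches(val_batches, step=step)
    meas_tr = build_measurements(train_batches, step=step)
    meas_val = build_measurements(val_batches, step=step)
    sigma = compute_sigma(train_batches, step=step)
    in_off, in_scale = input_scaling_from_batches(train_batches)
    out_off, out_scale = output_scaling_from_batches(train_batches, step=step)

    restart_log: list[dict] = []
    best_overall: tuple[float, np.ndarray] | None = None
    template: ANNParameters | None = None

    for r in range(config.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, hidden_size, r]))
        params0 = ANNParameters.random(
            hidden_size, rng,
            input_offset=in_off, input_scale=in_scale,
            output_offset=out_off, output_scale=out_scale,
        )
        template = params0
        theta0 = params0.to_vector()

        state = {"best_val": np.inf, "best_theta": theta0.copy(), "best_it": 0, "it": 0}

        def val_wsse(theta):
            return loss(theta, params0, packed_val, meas_val, sigma, with_grad=False)[0]

        def fun(theta):
            return loss(theta, params0, packed_tr, meas_tr, sigma, with_grad=True)

        def callback(xk):
            state["it"] += 1
            v = val_wsse(xk)
            if v < state["best_val"]:
                state["best_val"] = v
                state["best_theta"] = np.asarray(xk).copy()
                state["best_it"] = state["it"]
            elif state["it"] - state["best_it"] >= config.patience:
                raise StopIteration

        v0 = val_wsse(theta0)
        if np.isfinite(v0):
            state["best_val"] = v0
        try:
            res = minimize(
                fun, theta0, jac=True, method="L-BFGS-B",
                options={"maxiter": config.max_iterations},
                callback=callback,
            )
            final_train = float(res.fun)
        except StopIteration:
            final_train = fun(state["best_theta"])[0]

        restart_log.append(
            {
                "restart": r,
                "iterations": state["it"],
                "train_wsse_final": float(final_train),
                "val_wsse_best": float(state["best_val"]),
            }
        )
        logger.info(
            "h=%d restart %d: %d iters, train WSSE %.4g, best val WSSE %.4g",
            hidden_size, r, state["it"], final_train, state["best_val"],
        )
        if np.isfinite(state["best_val"]) and (
            best_overall is None or state["best_val"] < best_overall[0]
        ):
            best_overall = (state["best_val"], state["best_theta"])

    if best_overall is None:
        raise RuntimeError("all restarts failed to produce a finite validation loss")

    assert template is not None
    best_params = template.with_vector(best_overall[1])
    wsse_tr = loss(best_overall[1], template, packed_tr, meas_tr, sigma, with_grad=False)[0]
    wsse_val = loss(best_overall[1], template, packed_val, meas_val, sigma, with_grad=False)[0]
    n_tr, n_val = meas_tr.n_points(), meas_val.n_points()
    p = best_params.n_params
    return FitResult(
        params=best_params,
        hidden_size=hidden_size,
        wsse={"train": float(wsse_tr), "validation": float(wsse_val)},
        bic={"train": bic(wsse_tr, n_tr, p), "validation": bic(wsse_val, n_val, p)},
        n_points={"train": n_tr, "validation": n_val},
        sigma=sigma,
        restart_log=restart_log,
        config=config,
    )


def select_structure(
    candidates: Sequence[int],
    train_batches: Sequence[BatchRecord],
    val_batches: Sequence[BatchRecord],
    config: TrainingConfig | None = None,
) -> tuple[int, FitResult, dict[int, FitResult]]:
    """Train each candidate hidden size and select by validation BIC.

    The winner is the candidate with the greatest validation BIC among those
    with consistent training performance (training WSSE per point no worse
    than twice the best candidate's); ties break toward fewer nodes.
    """
    if config is None:
        config = TrainingConfig()
    fits: dict[int, FitResult] = {}
    for h in sorted(set(int(c) for c in candidates)):
        fits[h] = train(h, train_batches, val_batches, config)
    if len(fits) == 1:
        h = next(iter(fits))
        return h, fits[h], fits

    per_point = {h: f.wsse["train"] / f.n_points["train"] for h, f in fits.items()}
    floor = min(per_point.values())
    consistent = [h for h in sorted(fits) if per_point[h] <= 2.0 * floor]
    if not consistent:
        consistent = sorted(fits)
    best_h = consistent[0]
    for h in consistent[1:]:
        if fits[h].bic["validation"] > fits[best_h].bic["validation"]:
            best_h = h
    return best_h, fits[best_h], fits


def partition_by_acetate(batches: Sequence[BatchRecord], seed: int = 0) -> list[str]:
    """Partition a study the way the all-batches dataset is built: batches
    with acetate assays are split 2/3 train, 1/3 validation at random; the
    batches without acetate form the test partition."""
    with_ac = [b for b in batches if b.offline.acetate is not None]
    if not with_ac:
        raise ValueError("no acetate-bearing batches to partition")
    partition_study(with_ac, (2.0 / 3.0, 1.0 / 3.0), seed=seed)
    for b in batches:
        if b.offline.acetate is None:
            b.partition = "test"
    return [b.partition for b in batches]


def partition_study(
    batches: Sequence[BatchRecord],
    fractions: tuple[float, float] = (2.0 / 3.0, 1.0 / 3.0),
    seed: int = 0,
) -> list[str]:
    """Randomly assign whole batches to train/validation(/test) partitions.

    ``fractions`` are the train and validation shares (sum <= 1); any
    remainder goes to test.  Tags are written onto the records and returned.
    """
    f_tr, f_val = fractions
    if f_tr < 0 or f_val < 0 or f_tr + f_val > 1.0 + 1e-9:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    n = len(batches)
    n_tr = round(f_tr * n)
    n_val = min(round(f_val * n), n - n_tr)
    if n_tr == 0:
        raise ValueError("empty training partition")
    order = np.random.default_rng(seed).permutation(n)
    tags = np.empty(n, dtype=object)
    tags[order[:n_tr]] = "train"
    tags[order[n_tr : n_tr + n_val]] = "validation"
    tags[order[n_tr + n_val :]] = "test"
    for b, tag in zip(batches, tags):
        b.partition = str(tag)
    return [str(t) for t in tags]
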