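"""Post-fit process analysis.

Three views of a fitted hybrid model:

* rate surfaces — the learned specific growth and productivity rates over a
  (T, u_C) grid at several pH levels, with biomass and specific product held
  at a fixed process stage (early / mid / late induction);
* dynamic profile prediction — full trajectories plus rate time courses for a
  batch, including batches with stepwise time-varying conditions;
* regression reports — measured vs. predicted pairs with R^2, slope,
  intercept and RMSE per state variable and data partition.

Cells of a rate surface that fall outside the scaled-input support seen in
training (|z| > 3 on any input) are flagged as extrapolated rather than
refused: predictions there are the model's opinion, not evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ANNParameters, Trajectory, ann_eval, euler_integrate, predict_offline, EULER_STEP
from .plant import BatchRecord, ONLINE_STEP
from .training import FitResult

__all__ = [
    "rate_surface",
    "predict_profiles",
    "regression_report",
    "RegressionReport",
    "PROCESS_STAGES",
]

# (biomass OD, specific product OD^-1) at early, mid and late induction
PROCESS_STAGES = {
    "early": {"X": 50.0, "PX": 0.125},
    "mid": {"X": 80.0, "PX": 0.25},
    "late": {"X": 100.0, "PX": 0.5},
}


def rate_surface(
    params: ANNParameters,
    stage: Mapping[str, float],
    pH_levels: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0),
    T_grid: Sequence[float] | None = None,
    uC_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Evaluate the learned rates on a (pH, T, u_C) grid at a fixed stage.

    ``stage`` supplies the held-fixed biomass ``X`` and specific product
    ``PX``.  Returns a long-format table with columns pH, T, u_C, mu, v_px
    and an ``extrapolated`` flag.
    """
    if T_grid is None:
        T_grid = np.linspace(-1.0, 1.0, 21)
    if uC_grid is None:
        uC_grid = np.linspace(-1.0, 1.0, 21)
    ph, tt, uc = np.meshgrid(np.asarray(pH_levels, float), np.asarray(T_grid, float),
                             np.asarray(uC_grid, float), indexing="ij")
    x1 = np.stack(
        [np.full_like(ph, stage["X"]), np.full_like(ph, stage["PX"]), tt, ph, uc], axis=-1
    )
    y = ann_eval(params, x1)
    z = np.abs((x1 - params.input_offset) / params.input_scale)
    extrapolated = np.any(z > 3.0, axis=-1)
    return pd.DataFrame(
        {
            "pH": ph.ravel(), "T": tt.ravel(), "u_C": uc.ravel(),
            "mu": y[..., 0].ravel(), "v_px": y[..., 1].ravel(),
            "a_base": y[..., 2].ravel(),
            "extrapolated": extrapolated.ravel(),
        }
    )


def predict_profiles(
    params: ANNParameters, batch: BatchRecord, step: float = EULER_STEP
) -> Trajectory:
    """Full dynamic prediction of a batch (states plus rate time courses).

    Uses the same integration code path as training, so a training batch
    reproduces its training-time trajectory exactly.  Stepwise condition
    changes enter through the zero-order-hold input path.
    """
    return euler_integrate(params, batch, step=step)


@dataclass
class RegressionReport:
    """Measured-vs-predicted summary per (partition, variable)."""

    table: pd.DataFrame
    pairs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]


def _regression_metrics(meas: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    n = meas.size
    out = {"n": n, "r2": np.nan, "slope": np.nan, "intercept": np.nan, "rmse": np.nan}
    if n < 2:
        return out
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    ss_res = float(np.sum((meas - pred) ** 2))
    out["rmse"] = float(np.sqrt(ss_res / n))
    if ss_tot > 0:
        out["r2"] = 1.0 - ss_res / ss_tot
    var_p = float(np.var(pred))
    if var_p > 0:
        slope, intercept = np.polyfit(pred, meas, 1)
        out["slope"], out["intercept"] = float(slope), float(intercept)
    return out


def regression_report(
    fit: FitResult | ANNParameters,
    batches: Sequence[BatchRecord],
    step: float = EULER_STEP,
) -> RegressionReport:
    """Measured vs. predicted X, PX, P (offline) and cumulative base B
    (online) for every batch, grouped by partition."""
    params = fit.params if isinstance(fit, FitResult) else fit
    collected: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
    for b in batches:
        traj = euler_integrate(params, b, step=step)
        part = b.partition or "unassigned"
        for var, meas in (("X", b.offline.X_od), ("PX", b.offline.PX), ("P", b.offline.P)):
            pred = predict_offline(traj, b.offline.t, var=var)
            collected.setdefault((part, var), []).append((np.asarray(meas, float), pred))
        b_meas = np.cumsum(b.online.u_Base[:-1]) * ONLINE_STEP
        b_pred = predict_offline(traj, b.online.t[1:], var="B")
        collected.setdefault((part, "B"), []).append((b_meas, b_pred))

    pairs = {
        key: (np.concatenate([m for m, _ in lst]), np.concatenate([p for _, p in lst]))
        for key, lst in collected.items()
    }
    rows = []
    for (part, var), (meas, pred) in sorted(pairs.items()):
        rows.append({"partition": part, "variable": var, **_regression_metrics(meas, pred)})
    return RegressionReport(table=pd.DataFrame(rows), pairs=pairs)
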