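"""PLS analysis of product-concentration residuals.

After the hybrid model is fitted, the residual between measured and predicted
volumetric product is screened for remaining functional dependencies on
process variables that were deliberately left out of the rate network:
besides T, pH and u_C, also the base addition rate, the agitation rate and
the acetate concentration, plus the squares of all six.  A single-response
partial least squares model (PLS1, computed by NIPALS with deflation of both
blocks) regresses the residual on the standardized inputs; the number of
latent variables is chosen by repeating a random 2/3-1/3 split twenty times
and taking the mode of the per-split cross-validated optimum.

A small explained-variance fraction is the desired outcome: it means the
hybrid model already captures the dependence of product formation on the
tested variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ANNParameters, euler_integrate, predict_offline, EULER_STEP
from .plant import BatchRecord

__all__ = [
    "ResidualTable",
    "PLSModel",
    "build_residual_table",
    "pls_fit",
    "pls_predict",
    "select_latent",
    "report_coefficients",
]

RAW_INPUTS = ("T", "pH", "u_C", "u_Base", "agitation", "acetate")


@dataclass
class ResidualTable:
    """Standardized input matrix and centered product residuals.

    ``X`` holds the six process variables and their squares (12 columns),
    mean-centered and unit-variance scaled; ``y`` is the centered residual.
    Rows are restricted to offline product measurements of batches with
    acetate assays.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    col_mean: np.ndarray
    col_scale: np.ndarray
    y_mean: float
    batch_ids: list[str]


def build_residual_table(
    params: ANNParameters,
    batches: Sequence[BatchRecord],
    step: float = EULER_STEP,
) -> ResidualTable:
    """Residuals of volumetric product vs. process variables at sample times.

    Online variables are taken at the offline sample time by zero-order hold;
    acetate comes from the offline sample itself.  Squares are computed on the
    raw variables, then every column is standardized.
    """
    rows: list[list[float]] = []
    resid: list[float] = []
    ids: list[str] = []
    for b in batches:
        if b.offline.acetate is None:
            continue
        traj = euler_integrate(params, b, step=step)
        p_pred = predict_offline(traj, b.offline.t, var="P")
        zoh = np.clip(np.searchsorted(b.online.t, b.offline.t + 1e-9, side="right") - 1, 0, None)
        for j in range(b.offline.t.size):
            if not np.isfinite(b.offline.P[j]) or not np.isfinite(b.offline.acetate[j]):
                continue
            k = zoh[j]
            rows.append(
                [
                    b.online.T[k], b.online.pH[k], b.online.u_C[k],
                    b.online.u_Base[k], b.online.agitation[k], b.offline.acetate[j],
                ]
            )
            resid.append(float(b.offline.P[j] - p_pred[j]))
            ids.append(b.batch_id)
    if not rows:
        raise ValueError("no acetate-bearing batches: residual table would be empty")

    raw = np.asarray(rows, dtype=float)
    X = np.hstack([raw, raw**2])
    columns = list(RAW_INPUTS) + [f"{c}^2" for c in RAW_INPUTS]
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = (X - mean) / scale
    y = np.asarray(resid, dtype=float)
    y_mean = float(y.mean())
    return ResidualTable(
        X=Xs, y=y - y_mean, columns=columns,
        col_mean=mean, col_scale=scale, y_mean=y_mean, batch_ids=ids,
    )


@dataclass
class PLSModel:
    """PLS1 model on standardized inputs."""

    n_latent: int
    weights: np.ndarray    # (p, A) input weights w_a
    loadings: np.ndarray   # (p, A) input loadings p_a
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray     # (n, A)
    coef: np.ndarray       # (p,) regression coefficients on standardized inputs
    explained_variance: float


def pls_fit(table: ResidualTable, n_latent: int) -> PLSModel:
    """NIPALS PLS1 with deflation of both blocks.

    With as many components as (full-rank) inputs the coefficients coincide
    with the ordinary least-squares solution.  Rank deficiency truncates the
    component sequence with a warning.
    """
    X = table.X.copy()
    y = table.y.copy()
    n, p = X.shape
    if not 1 <= n_latent <= p:
        raise ValueError(f"n_latent must be in 1..{p}")

    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    q = np.zeros(n_latent)
    T = np.zeros((n, n_latent))
    a_used = 0
    for a in range(n_latent):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            warnings.warn(
                f"rank deficiency: stopping after {a_used} of {n_latent} components",
                stacklevel=2,
            )
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-24:
            warnings.warn(
                f"degenerate score vector: stopping after {a_used} of {n_latent} components",
                stacklevel=2,
            )
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X = X - np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        a_used += 1

    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    if a_used:
        coef = W @ np.linalg.solve(P.T @ W, q)
    else:
        coef = np.zeros(p)
    ss_tot = float(table.y @ table.y)
    ss_res = float(y @ y)
    explained = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PLSModel(
        n_latent=a_used, weights=W, loadings=P, y_loadings=q,
        scores=T, coef=coef, explained_variance=max(0.0, min(1.0, explained)),
    )


def pls_predict(model: PLSModel, X_std: np.ndarray) -> np.ndarray:
    """Predict centered residuals from standardized inputs."""
    return X_std @ model.coef


def select_latent(
    table: ResidualTable,
    max_latent: int,
    n_repeats: int = 20,
    seed: int = 0,
) -> tuple[int, list[int]]:
    """Choose the latent-variable count by repeated random-split validation.

    For each of ``n_repeats`` seeded 2/3-1/3 splits, the candidate count with
    the lowest held-out residual SSE wins the split; the overall choice is the
    most frequent winner, ties resolved toward fewer components.  Returns the
    chosen count and the per-split winners.
    """
    n = table.y.size
    if n < 6:
        raise ValueError("too few rows for 2/3-1/3 splits")
    rng = np.random.default_rng(seed)
    winners: list[int] = []
    for _ in range(n_repeats):
        order = rng.permutation(n)
        n_fit = round(2 * n / 3)
        fit_idx, hold_idx = order[:n_fit], order[n_fit:]
        sub = ResidualTable(
            X=table.X[fit_idx], y=table.y[fit_idx], columns=table.columns,
            col_mean=table.col_mean, col_scale=table.col_scale,
            y_mean=table.y_mean, batch_ids=[table.batch_ids[i] for i in fit_idx],
        )
        sse = []
        for a in range(1, max_latent + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = pls_fit(sub, a)
            r = table.y[hold_idx] - pls_predict(m, table.X[hold_idx])
            sse.append(float(r @ r))
        winners.append(1 + int(np.argmin(sse)))
    counts = np.bincount(winners, minlength=max_latent + 1)
    return int(np.argmax(counts)), winners


def report_coefficients(model: PLSModel, columns: Sequence[str]) -> pd.DataFrame:
    """Standardized regression coefficients ranked by magnitude."""
    df = pd.DataFrame({"variable": list(columns), "coefficient": model.coef})
    df["abs"] = df["coefficient"].abs()
    df = df.sort_values("abs", ascending=False).drop(columns="abs").reset_index(drop=True)
    return df
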