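"""Serial hybrid model: ANN rate functions inside bioreactor mass balances.

The parametric backbone is the fed-batch material balance system

    dX/dt    = mu * X - D * X,            D = (u_Feed + u_Base) / V
    dV/dt    = u_Feed + u_Base
    d(PX)/dt = v_px * I,                  I = 0 before induction, 1 after
    dB/dt    = a_base * mu * X * V

with biomass X (OD), culture volume V, specific productivity PX (OD^-1) and
cumulative base addition B.  Volumetric product is algebraic, P = PX * X, so
the volumetric product kinetic (growth and non-growth associated terms minus
dilution) holds identically.  The B state embeds the integral base/biomass
correlation: dB/dt is the time derivative of ``a_base * (X V - X0 V0)`` given
the X and V balances, which lets high-frequency base logging inform the
biomass fit.

The nonparametric part is a three-layer network with tanh hidden nodes and
linear input/output nodes,

    [mu, v_px, a_base] = w2 . tanh(w1 . x1 + b1) + b2,

on affinely scaled inputs x1 = [X, PX, T, pH, u_C] and affinely scaled
outputs.  Integration is forward Euler with a fixed 0.25 h step; online inputs
(logged every 30 min) are mapped to the Euler grid by zero-order hold.  When
requested, parameter sensitivities of the dynamic states are propagated by
exact forward-mode differentiation of the discrete Euler recursion, giving
machine-precision gradients of any loss built from the trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import IntegrationError
from .plant import BatchRecord

__all__ = [
    "ANNParameters",
    "Trajectory",
    "PackedStudy",
    "ann_eval",
    "rhs",
    "pack_batches",
    "integrate_packed",
    "euler_integrate",
    "predict_offline",
    "p_consistency_gap",
]

INPUT_NAMES = ("X", "PX", "T", "pH", "u_C")
OUTPUT_NAMES = ("mu", "v_px", "a_base")
EULER_STEP = 0.25  # h

# default affine output scaling: raw network outputs of order one map onto
# physically plausible rate ranges (mu in [-0.05, 0.6] 1/h, v_px in
# [-0.1, 0.3] OD^-1 h^-1); the a_base scaling is normally set from data
_DEFAULT_OUT_OFFSET = np.array([0.275, 0.1, 1.0e-3])
_DEFAULT_OUT_SCALE = np.array([0.325, 0.2, 5.0e-4])


@dataclass
class ANNParameters:
    """Weights, biases and input/output scalings of the rate network."""

    w1: np.ndarray  # (n_hidden, 5)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (3, n_hidden)
    b2: np.ndarray  # (3,)
    input_offset: np.ndarray  # (5,)
    input_scale: np.ndarray  # (5,)
    output_offset: np.ndarray  # (3,)
    output_scale: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        h = self.w1.shape[0]
        if self.w1.shape != (h, 5) or self.b1.shape != (h,):
            raise ValueError("w1 must be (n_hidden, 5) and b1 (n_hidden,)")
        if self.w2.shape != (3, h) or self.b2.shape != (3,):
            raise ValueError("w2 must be (3, n_hidden) and b2 (3,)")
        if np.any(self.input_scale <= 0) or np.any(self.output_scale == 0):
            raise ValueError("scales must be non-zero (input scales positive)")

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    @property
    def n_params(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    def with_vector(self, theta: np.ndarray) -> "ANNParameters":
        h = self.n_hidden
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.size}")
        i = 0
        w1 = theta[i : i + 5 * h].reshape(h, 5); i += 5 * h
        b1 = theta[i : i + h]; i += h
        w2 = theta[i : i + 3 * h].reshape(3, h); i += 3 * h
        b2 = theta[i : i + 3]
        return replace(self, w1=w1, b1=b1, w2=w2, b2=b2)

    @classmethod
    def random(
        cls,
        n_hidden: int,
        rng: np.random.Generator,
        input_offset: np.ndarray | None = None,
        input_scale: np.ndarray | None = None,
        output_offset: np.ndarray | None = None,
        output_scale: np.ndarray | None = None,
    ) -> "ANNParameters":
        """Random initialization, uniform in +/- 0.5/sqrt(fan-in) per layer."""
        lim1 = 0.5 / np.sqrt(5.0)
        lim2 = 0.5 / np.sqrt(n_hidden)
        return cls(
            w1=rng.uniform(-lim1, lim1, size=(n_hidden, 5)),
            b1=rng.uniform(-0.1, 0.1, size=n_hidden),
            w2=rng.uniform(-lim2, lim2, size=(3, n_hidden)),
            b2=rng.uniform(-0.1, 0.1, size=3),
            input_offset=np.zeros(5) if input_offset is None else np.asarray(input_offset, float),
            input_scale=np.ones(5) if input_scale is None else np.asarray(input_scale, float),
            output_offset=_DEFAULT_OUT_OFFSET.copy()
            if output_offset is None
            else np.asarray(output_offset, float),
            output_scale=_DEFAULT_OUT_SCALE.copy()
            if output_scale is None
            else np.asarray(output_scale, float),
        )

    def to_json(self) -> str:
        doc = {k: np.asarray(getattr(self, k)).tolist() for k in
               ("w1", "b1", "w2", "b2", "input_offset", "input_scale",
                "output_offset", "output_scale")}
        doc["n_hidden"] = self.n_hidden
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ANNParameters":
        doc = json.loads(text)
        return cls(**{k: np.asarray(doc[k], dtype=float) for k in
                      ("w1", "b1", "w2", "b2", "input_offset", "input_scale",
                       "output_offset", "output_scale")})


def ann_eval(params: ANNParameters, x1: np.ndarray) -> np.ndarray:
    """Evaluate the rate network on inputs ``x1`` of shape (..., 5) in the
    order [X, PX, T, pH, u_C]; returns (..., 3) = [mu, v_px, a_base]."""
    x1 = np.asarray(x1, dtype=float)
    if x1.shape[-1] != 5:
        raise ValueError("x1 must have 5 entries: [X, PX, T, pH, u_C]")
    z = (x1 - params.input_offset) / params.input_scale
    h = np.tanh(z @ params.w1.T + params.b1)
    raw = h @ params.w2.T + params.b2
    return params.output_offset + params.output_scale * raw


def _ann_eval_grads(params: ANNParameters, x1: np.ndarray):
    """Batched network evaluation with gradients.

    ``x1``: (nb, 5).  Returns ``y`` (nb, 3), ``dy_dtheta`` (nb, 3, n_params)
    and ``dy_dx`` (nb, 3, 5) where derivatives are with respect to the raw
    (unscaled) inputs.
    """
    nh = params.n_hidden
    os_, oo = params.output_scale, params.output_offset
    z = (x1 - params.input_offset) / params.input_scale
    h = np.tanh(z @ params.w1.T + params.b1)
    d = 1.0 - h * h
    y = oo + os_ * (h @ params.w2.T + params.b2)

    nb = x1.shape[0]
    ntheta = params.n_params
    # dy[o]/dx[i] = os[o] * sum_j w2[o,j] d[j] w1[j,i] / in_scale[i]
    dy_dx = (os_[:, None] * np.einsum("bj,oj,ji->boi", d, params.w2, params.w1)) \
        / params.input_scale[None, None, :]

    G = np.zeros((nb, 3, ntheta))
    A = os_[None, :, None] * params.w2[None, :, :] * d[:, None, :]  # (nb, 3, nh)
    G[:, :, : 5 * nh] = (A[:, :, :, None] * z[:, None, None, :]).reshape(nb, 3, 5 * nh)
    G[:, :, 5 * nh : 6 * nh] = A
    for o in range(3):
        G[:, o, 6 * nh + o * nh : 6 * nh + (o + 1) * nh] = os_[o] * h
        G[:, o, 9 * nh + o] = os_[o]
    return y, G, dy_dx


def rhs(
    X: float, V: float, PX: float,
    mu: float, v_px: float, a_base: float,
    u_Feed: float, u_Base: float, I: int,
) -> tuple[float, float, float, float]:
    """Right-hand side of the balance system; returns (dX, dV, dPX, dB)/dt."""
    if V <= 0:
        raise ValueError("volume must be positive")
    D = (u_Feed + u_Base) / V
    return (mu * X - D * X, u_Feed + u_Base, v_px * I, a_base * mu * X * V)


@dataclass
class Trajectory:
    """Hybrid-model trajectory on the Euler grid, with rates and optional
    parameter sensitivities of X, PX and B (each (n_grid, n_params))."""

    t: np.ndarray
    X: np.ndarray
    V: np.ndarray
    PX: np.ndarray
    B: np.ndarray
    mu: np.ndarray
    v_px: np.ndarray
    a_base: np.ndarray
    D: np.ndarray
    I: np.ndarray
    sens: dict[str, np.ndarray] | None = None

    @property
    def P(self) -> np.ndarray:
        return self.PX * self.X


@dataclass
class PackedStudy:
    """Several batches padded onto a common Euler grid for vectorized
    integration.  Per-node input arrays are zero-order holds of the online
    logs; V and D are exogenous (they depend only on the measured feeds)."""

    t0: np.ndarray          # (nb,)
    step: float
    n_steps: np.ndarray     # (nb,) active steps per batch
    uF: np.ndarray          # (nb, m+1)
    uB: np.ndarray
    T: np.ndarray
    pH: np.ndarray
    uC: np.ndarray
    V: np.ndarray
    D: np.ndarray
    I: np.ndarray           # (nb, m+1) induction indicator per node
    X0: np.ndarray          # (nb,)
    PX0: np.ndarray
    batch_ids: list[str]

    @property
    def n_batches(self) -> int:
        return self.t0.size

    @property
    def max_steps(self) -> int:
        return self.uF.shape[1] - 1


def pack_batches(batches: Sequence[BatchRecord], step: float = EULER_STEP) -> PackedStudy:
    """Prepare batch records for integration on the fixed Euler grid.

    The grid runs from t0 to the last online time of each batch.  Initial X
    and PX come from the earliest offline sample; V starts at the known
    initial volume and is integrated from the measured feed and base rates.
    """
    nb = len(batches)
    n_steps = np.empty(nb, dtype=int)
    grids = []
    for b in batches:
        span = b.online.t[-1] - b.t0
        n = int(round(span / step))
        if abs(n * step - span) > 1e-6:
            raise ValueError(f"batch {b.batch_id}: online span is not a multiple of {step} h")
        grids.append(n)
    n_steps[:] = grids
    m = int(n_steps.max())

    shape = (nb, m + 1)
    uF = np.zeros(shape); uB = np.zeros(shape)
    T = np.zeros(shape); pH = np.zeros(shape); uC = np.zeros(shape)
    I = np.zeros(shape)
    X0 = np.empty(nb); PX0 = np.empty(nb)
    t0 = np.empty(nb)
    for k, b in enumerate(batches):
        t_grid = b.t0 + step * np.arange(n_steps[k] + 1)
        zoh = np.clip(np.searchsorted(b.online.t, t_grid + 1e-9, side="right") - 1, 0, None)
        for src, dst in ((b.online.u_Feed, uF), (b.online.u_Base, uB),
                         (b.online.T, T), (b.online.pH, pH), (b.online.u_C, uC)):
            dst[k, : n_steps[k] + 1] = src[zoh]
            dst[k, n_steps[k] + 1 :] = src[zoh][-1]
        I[k] = (b.t0 + step * np.arange(m + 1)) >= b.t_induction - 1e-9
        j0 = int(np.argmin(b.offline.t))
        X0[k] = b.offline.X_od[j0]
        PX0[k] = b.offline.PX[j0]
        t0[k] = b.t0

    V = np.empty(shape)
    V[:, 0] = [b.v0 for b in batches]
    for n in range(m):
        V[:, n + 1] = V[:, n] + step * (uF[:, n] + uB[:, n])
    D = (uF + uB) / V

    return PackedStudy(
        t0=t0, step=step, n_steps=n_steps, uF=uF, uB=uB, T=T, pH=pH, uC=uC,
        V=V, D=D, I=I, X0=X0, PX0=PX0, batch_ids=[b.batch_id for b in batches],
    )


def integrate_packed(params: ANNParameters, packed: PackedStudy, with_sensitivities: bool = False):
    """Forward-Euler integration of all packed batches simultaneously.

    Returns ``(states, rates, sens)`` where ``states`` maps 'X', 'PX', 'B' to
    (nb, m+1) arrays (plus 'V'), ``rates`` maps 'mu', 'v_px', 'a_base', and
    ``sens`` maps 'X', 'PX', 'B' to (nb, m+1, n_params) sensitivity arrays
    (``None`` unless requested).  States are frozen past each batch's own end
    so padding never feeds back into results.
    """
    nb, m = packed.n_batches, packed.max_steps
    dt = packed.step
    ntheta = params.n_params

    X = np.empty((nb, m + 1)); PX = np.empty((nb, m + 1)); B = np.empty((nb, m + 1))
    MU = np.empty((nb, m + 1)); VP = np.empty((nb, m + 1)); AB = np.empty((nb, m + 1))
    X[:, 0], PX[:, 0], B[:, 0] = packed.X0, packed.PX0, 0.0

    if with_sensitivities:
        SX = np.zeros((nb, m + 1, ntheta))
        SPX = np.zeros((nb, m + 1, ntheta))
        SB = np.zeros((nb, m + 1, ntheta))
        sx = np.zeros((nb, ntheta)); spx = np.zeros((nb, ntheta)); sb = np.zeros((nb, ntheta))

    V = packed.V
    for n in range(m + 1):
        x1 = np.stack([X[:, n], PX[:, n], packed.T[:, n], packed.pH[:, n], packed.uC[:, n]], axis=1)
        if with_sensitivities:
            y, G, dy_dx = _ann_eval_grads(params, x1)
        else:
            y = ann_eval(params, x1)
        mu, v, a = y[:, 0], y[:, 1], y[:, 2]
        MU[:, n], VP[:, n], AB[:, n] = mu, v, a
        if n == m:
            break
        active = n < packed.n_steps
        Ind = packed.I[:, n]
        Xn, PXn, Vn, Dn = X[:, n], PX[:, n], V[:, n], packed.D[:, n]

        Xnew = Xn + dt * (mu - Dn) * Xn
        PXnew = PXn + dt * v * Ind
        Bnew = B[:, n] + dt * a * mu * Xn * Vn
        X[:, n + 1] = np.where(active, Xnew, Xn)
        PX[:, n + 1] = np.where(active, PXnew, PXn)
        B[:, n + 1] = np.where(active, Bnew, B[:, n])
        if not np.all(np.isfinite(X[:, n + 1]) & np.isfinite(PX[:, n + 1]) & np.isfinite(B[:, n + 1])):
            bad = ~(np.isfinite(X[:, n + 1]) & np.isfinite(PX[:, n + 1]) & np.isfinite(B[:, n + 1]))
            k = int(np.argmax(bad))
            raise IntegrationError(
                f"non-finite state in batch {packed.batch_ids[k]} at "
                f"t={packed.t0[k] + (n + 1) * dt:.2f} h",
                time=float(packed.t0[k] + (n + 1) * dt),
                weight_norm=float(np.linalg.norm(params.to_vector())),
            )

        if with_sensitivities:
            dmu_dX, dmu_dPX = dy_dx[:, 0, 0], dy_dx[:, 0, 1]
            dv_dX, dv_dPX = dy_dx[:, 1, 0], dy_dx[:, 1, 1]
            da_dX, da_dPX = dy_dx[:, 2, 0], dy_dx[:, 2, 1]
            Gmu, Gv, Ga = G[:, 0], G[:, 1], G[:, 2]

            fX_X = mu + Xn * dmu_dX - Dn
            fX_PX = Xn * dmu_dPX
            fPX_X = Ind * dv_dX
            fPX_PX = Ind * dv_dPX
            fB_X = Vn * (a * mu + Xn * (da_dX * mu + a * dmu_dX))
            fB_PX = Vn * Xn * (da_dPX * mu + a * dmu_dPX)

            sx_new = sx + dt * (fX_X[:, None] * sx + fX_PX[:, None] * spx + Xn[:, None] * Gmu)
            spx_new = spx + dt * (fPX_X[:, None] * sx + fPX_PX[:, None] * spx + Ind[:, None] * Gv)
            sb_new = sb + dt * (
                fB_X[:, None] * sx
                + fB_PX[:, None] * spx
                + (Vn * Xn)[:, None] * (mu[:, None] * Ga + a[:, None] * Gmu)
            )
            act = active[:, None]
            sx = np.where(act, sx_new, sx)
            spx = np.where(act, spx_new, spx)
            sb = np.where(act, sb_new, sb)
            SX[:, n + 1] = sx; SPX[:, n + 1] = spx; SB[:, n + 1] = sb

    states = {"X": X, "PX": PX, "B": B, "V": V}
    rates = {"mu": MU, "v_px": VP, "a_base": AB}
    sens = {"X": SX, "PX": SPX, "B": SB} if with_sensitivities else None
    return states, rates, sens


def euler_integrate(
    params: ANNParameters,
    batch: BatchRecord,
    with_sensitivities: bool = False,
    step: float = EULER_STEP,
) -> Trajectory:
    """Integrate one batch record; see :func:`integrate_packed` for the scheme."""
    packed = pack_batches([batch], step=step)
    states, rates, sens = integrate_packed(params, packed, with_sensitivities)
    n = int(packed.n_steps[0])
    sl = slice(0, n + 1)
    t = batch.t0 + step * np.arange(n + 1)
    return Trajectory(
        t=t,
        X=states["X"][0, sl], V=states["V"][0, sl],
        PX=states["PX"][0, sl], B=states["B"][0, sl],
        mu=rates["mu"][0, sl], v_px=rates["v_px"][0, sl], a_base=rates["a_base"][0, sl],
        D=packed.D[0, sl], I=packed.I[0, sl],
        sens=None if sens is None else {k: v[0, sl] for k, v in sens.items()},
    )


def predict_offline(traj: Trajectory, sample_times: np.ndarray, var: str = "X") -> np.ndarray:
    """Linear interpolation of a trajectory state to offline sample times."""
    st = np.asarray(sample_times, dtype=float)
    if np.any(st < traj.t[0] - 1e-9) or np.any(st > traj.t[-1] + 1e-9):
        raise ValueError("sample times outside the integration span")
    values = {"X": traj.X, "PX": traj.PX, "B": traj.B, "P": traj.P, "V": traj.V}[var]
    return np.interp(st, traj.t, values)


def p_consistency_gap(params: ANNParameters, batch: BatchRecord, step: float = EULER_STEP) -> float:
    """End-of-batch gap between direct Euler integration of the volumetric
    product kinetic, dP/dt = (v_px I + PX mu) X - D P, and the algebraic
    product P = PX * X.  The gap is O(step); halving the step should shrink it
    by roughly two, which quantifies the consistency of the two formulations.
    """
    traj = euler_integrate(params, batch, step=step)
    P_direct = traj.PX[0] * traj.X[0]
    for n in range(traj.t.size - 1):
        dP = (traj.v_px[n] * traj.I[n] + traj.PX[n] * traj.mu[n]) * traj.X[n] - traj.D[n] * P_direct
        P_direct = P_direct + step * dP
    return float(abs(P_direct - traj.P[-1]))
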