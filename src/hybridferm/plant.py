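"""Ground-truth fed-batch fermentation plant and measurement model.

This module emulates an industrial *E. coli* high-cell-density process
development study: fed-batch fermentations induced at a target biomass, with
induction temperature, pH and carbon feed rate varied according to an
experimental design.  It provides

* smooth "true" kinetics (specific growth rate, specific productivity rate and
  a base-to-biomass correlation coefficient) with the qualitative structure of
  such processes: substrate-limited growth that increases with feed rate and
  decreases with biomass, and product-inhibition of the specific productivity
  rate above ~0.5 OD^-1 of specific product;
* a forward-Euler integrator of the reactor mass balances that produces
  noiseless batch records (30-min online logging, sparse offline samples);
* a measurement model with analytical error levels typical of OD (CV 2.5 %),
  RP-HPLC product quantification (CV 7.5 %) and acetate assays (CV 15 %);
* a study generator producing a 53-batch campaign (23-run four-factor Doehlert
  design plus failed, investigative, secondary-design and reproducibility
  batches) with train/validation/test partitions.

All product quantities are in arbitrary scaled units; biomass is in OD650.
Base addition is generated mechanistically as ``a_base * mu * X * V`` — the
time derivative of the integral base/biomass correlation — so that cumulative
base equals ``a_base * (X V - X0 V0)`` identically in the noiseless plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .doehlert import FactorRange, assign_factors, generate_doehlert, scale_to_process
from .errors import SimulationError

__all__ = [
    "TrueKinetics",
    "BatchConditions",
    "OnlineSeries",
    "OfflineSamples",
    "BatchRecord",
    "default_true_kinetics",
    "constant_kinetics",
    "ann_true_kinetics",
    "example_ann_kinetics",
    "simulate_true_batch",
    "apply_measurement_model",
    "generate_study",
    "DOE1_RANGES",
]

ONLINE_STEP = 0.5  # h, 30-min online logging grid
_FEED_BASE = 0.010  # gravimetric feed rate at center feed setting (scaled L/h)
_FEED_GAIN = 0.3  # relative feed change per coded u_C unit


@dataclass(frozen=True)
class TrueKinetics:
    """Ground-truth rate functions of the plant.

    ``mu_fn`` and ``v_fn`` map ``(X, P/X, T, pH, u_C)`` (OD, OD^-1, coded,
    coded, coded) to the specific growth rate (1/h) and the specific
    productivity rate (OD^-1 h^-1).  ``a_base_true`` is the constant
    base-to-biomass correlation coefficient (base mass per OD*L).
    """

    mu_fn: Callable[..., np.ndarray]
    v_fn: Callable[..., np.ndarray]
    a_base_true: float


def default_true_kinetics() -> TrueKinetics:
    """Smooth default kinetics spanning the studied design region.

    * mu rises with feed rate (saturating), falls with biomass (substrate
      limitation at constant feed) and depends weakly on temperature.
    * v_px rises with temperature and feed, falls with pH, and is shut down by
      a sigmoidal product-inhibition term centered at P/X = 0.5 OD^-1.
    """

    def mu(X, PX, T, pH, u_C):
        feed = 0.5 * (1.0 + np.tanh(0.55 * (u_C + 0.6)))
        return 0.25 * feed * (20.0 / (20.0 + X)) * (1.0 + 0.03 * T)

    def v(X, PX, T, pH, u_C):
        drive = 1.0 + 0.25 * T - 0.2 * pH + 0.25 * np.tanh(u_C)
        inhibition = 1.0 / (1.0 + np.exp((PX - 0.5) / 0.06))
        return 0.1 * np.maximum(drive, 0.0) * inhibition

    return TrueKinetics(mu_fn=mu, v_fn=v, a_base_true=1.0e-3)


def constant_kinetics(mu: float = 0.1, v: float = 0.0, a_base: float = 0.0) -> TrueKinetics:
    """Kinetics with constant rates; useful for closed-form checks."""
    return TrueKinetics(
        mu_fn=lambda X, PX, T, pH, u_C: np.full_like(np.asarray(X, float), mu),
        v_fn=lambda X, PX, T, pH, u_C: np.full_like(np.asarray(X, float), v),
        a_base_true=a_base,
    )


def ann_true_kinetics(params, a_base: float = 1.0e-3) -> TrueKinetics:
    """Wrap an ANN rate model (:class:`~hybridferm.model.ANNParameters`) as
    plant truth, with a constant base correlation coefficient."""
    from .model import ann_eval

    def mu(X, PX, T, pH, u_C):
        x = np.stack(np.broadcast_arrays(X, PX, T, pH, u_C), axis=-1)
        return ann_eval(params, x)[..., 0]

    def v(X, PX, T, pH, u_C):
        x = np.stack(np.broadcast_arrays(X, PX, T, pH, u_C), axis=-1)
        return ann_eval(params, x)[..., 1]

    return TrueKinetics(mu_fn=mu, v_fn=v, a_base_true=a_base)


def example_ann_kinetics(a_base: float = 1.0e-3):
    """A fixed two-hidden-node ANN ground truth.

    Node 1 drives growth (decreasing in biomass, increasing in feed), node 2
    drives productivity (product-inhibited, temperature/pH/feed modulated).
    Returns ``(ANNParameters, TrueKinetics)``.
    """
    from .model import ANNParameters

    w1 = np.array(
        [
            [-1.2, 0.0, 0.1, 0.0, 0.4],
            [0.0, -1.5, 0.3, -0.25, 0.3],
        ]
    )
    b1 = np.array([0.3, 1.2])
    w2 = np.array(
        [
            [0.8, 0.0],
            [0.0, 0.9],
            [0.0, 0.0],
        ]
    )
    b2 = np.array([0.0, 0.0, 0.0])
    params = ANNParameters(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        input_offset=np.array([70.0, 0.3, 0.0, 0.0, 0.0]),
        input_scale=np.array([25.0, 0.2, 0.7, 0.7, 0.8]),
        output_offset=np.array([0.08, 0.07, a_base]),
        output_scale=np.array([0.06, 0.05, 1.0]),
    )
    return params, ann_true_kinetics(params, a_base=a_base)


@dataclass(frozen=True)
class BatchConditions:
    """Induction-phase settings of one fermentation.

    ``T``, ``pH`` and ``u_C`` are coded (scaled, dimensionless) settings that
    apply after induction; before induction every batch runs at the common
    center conditions (0, 0, 0).  ``profiles`` optionally overrides a setting
    with a piecewise-constant time course, given as ``(hours after induction,
    value)`` breakpoints (used for failed-feed and variable-condition batches).
    """

    X_ind: float
    T: float = 0.0
    pH: float = 0.0
    u_C: float = 0.0
    induction_duration: float = 24.0
    profiles: dict[str, tuple[tuple[float, float], ...]] | None = None


@dataclass
class OnlineSeries:
    """Online signals on the uniform 30-min grid (hours from t0)."""

    t: np.ndarray
    u_Feed: np.ndarray
    u_Base: np.ndarray
    T: np.ndarray
    pH: np.ndarray
    agitation: np.ndarray
    u_C: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "u_Feed": self.u_Feed,
                "u_Base": self.u_Base,
                "T": self.T,
                "pH": self.pH,
                "agitation": self.agitation,
                "u_C": self.u_C,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OnlineSeries":
        return cls(**{c: df[c].to_numpy(dtype=float) for c in
                      ["t", "u_Feed", "u_Base", "T", "pH", "agitation", "u_C"]})


@dataclass
class OfflineSamples:
    """Sparse offline samples: biomass (OD650), specific and volumetric
    product, optional acetate (``None`` when not assayed for the batch)."""

    t: np.ndarray
    X_od: np.ndarray
    PX: np.ndarray
    P: np.ndarray
    acetate: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.t, "X_od": self.X_od, "PX": self.PX, "P": self.P}
        if self.acetate is not None:
            d["acetate"] = self.acetate
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OfflineSamples":
        ac = df["acetate"].to_numpy(dtype=float) if "acetate" in df.columns else None
        return cls(
            t=df["t"].to_numpy(dtype=float),
            X_od=df["X_od"].to_numpy(dtype=float),
            PX=df["PX"].to_numpy(dtype=float),
            P=df["P"].to_numpy(dtype=float),
            acetate=ac,
        )


@dataclass
class BatchRecord:
    """One fermentation record starting at t0 (first fed-batch sample)."""

    batch_id: str
    conditions: BatchConditions
    online: OnlineSeries
    offline: OfflineSamples
    t_induction: float
    t0: float = 0.0
    v0: float = 1.0
    partition: str = ""
    scenario: str = ""
    truth: pd.DataFrame | None = None

    @property
    def t_end(self) -> float:
        return float(self.online.t[-1])


def _piecewise(breakpoints: Sequence[tuple[float, float]], tau: np.ndarray) -> np.ndarray:
    """Zero-order-hold evaluation of (time, value) breakpoints at times tau."""
    bp = sorted(breakpoints)
    times = np.array([b[0] for b in bp])
    vals = np.array([b[1] for b in bp])
    idx = np.clip(np.searchsorted(times, tau, side="right") - 1, 0, len(bp) - 1)
    return vals[idx]


def _condition_signal(cond: BatchConditions, name: str, t: np.ndarray, t_ind: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    post = np.full_like(t, float(getattr(cond, name)))
    if cond.profiles and name in cond.profiles:
        post = _piecewise(cond.profiles[name], t - t_ind)
    return np.where(t < t_ind, 0.0, post)


def simulate_true_batch(
    conditions: BatchConditions,
    kinetics: TrueKinetics | None = None,
    step: float = 0.05,
    pre_induction: float = 3.0,
    v0: float = 1.0,
    X0: float | None = None,
    feed_base: float = _FEED_BASE,
    batch_id: str = "batch",
    sample_times: Sequence[float] | None = None,
    include_acetate: bool = True,
) -> BatchRecord:
    """Integrate the true plant forward and return a noiseless batch record.

    The record starts at t0 = 0 in fed-batch mode at common (center) settings;
    induction occurs at ``pre_induction`` hours, when the batch switches to its
    design conditions.  Unless ``X0`` is given, the initial biomass is chosen
    by shooting so that biomass at induction equals ``conditions.X_ind``.
    The full fine-grid state trajectory is attached as ``record.truth``.
    """
    if kinetics is None:
        kinetics = default_true_kinetics()
    if step > 0.25:
        raise ValueError("plant integration step must be <= 0.25 h")

    t_ind = float(pre_induction)
    t_end = t_ind + float(conditions.induction_duration)
    if abs(round(t_end / ONLINE_STEP) * ONLINE_STEP - t_end) > 1e-9:
        raise ValueError("batch span must be a multiple of the 0.5 h online grid")
    n = int(round(t_end / step))
    if abs(n * step - t_end) > 1e-9 or abs(round(t_ind / step) * step - t_ind) > 1e-9:
        raise ValueError("step must divide both the induction time and the batch span")
    t = np.arange(n + 1) * step

    T_arr = _condition_signal(conditions, "T", t, t_ind)
    pH_arr = _condition_signal(conditions, "pH", t, t_ind)
    uC_arr = _condition_signal(conditions, "u_C", t, t_ind)
    uF_arr = np.maximum(feed_base * (1.0 + _FEED_GAIN * uC_arr), 0.0)
    induced = t >= t_ind - 1e-12

    a = kinetics.a_base_true

    def integrate(x_init: float, n_stop: int):
        X = np.empty(n_stop + 1)
        V = np.empty(n_stop + 1)
        PX = np.empty(n_stop + 1)
        mu_s = np.empty(n_stop + 1)
        v_s = np.empty(n_stop + 1)
        uB_s = np.empty(n_stop + 1)
        X[0], V[0], PX[0] = x_init, v0, 0.0
        for i in range(n_stop + 1):
            mu_i = float(kinetics.mu_fn(X[i], PX[i], T_arr[i], pH_arr[i], uC_arr[i]))
            v_i = float(kinetics.v_fn(X[i], PX[i], T_arr[i], pH_arr[i], uC_arr[i]))
            uB_i = a * mu_i * X[i] * V[i]
            mu_s[i], v_s[i], uB_s[i] = mu_i, v_i, uB_i
            if i == n_stop:
                break
            D = (uF_arr[i] + uB_i) / V[i]
            X[i + 1] = X[i] + step * (mu_i - D) * X[i]
            V[i + 1] = V[i] + step * (uF_arr[i] + uB_i)
            PX[i + 1] = PX[i] + step * (v_i if induced[i] else 0.0)
            if not (np.isfinite(X[i + 1]) and X[i + 1] > 0 and V[i + 1] > 0 and np.isfinite(PX[i + 1])):
                raise SimulationError(
                    f"non-physical state at t={t[i + 1]:.2f} h (X={X[i + 1]}, V={V[i + 1]})"
                )
        return X, V, PX, mu_s, v_s, uB_s

    n_pre = int(round(t_ind / step))
    if X0 is None:
        x_init = 0.88 * conditions.X_ind
        for _ in range(4):  # shooting on the pre-induction phase
            X_pre, *_ = integrate(x_init, n_pre)
            x_init *= conditions.X_ind / X_pre[-1]
    else:
        x_init = float(X0)

    X, V, PX, mu_s, v_s, uB_s = integrate(x_init, n)
    B = a * (X * V - X[0] * V[0])
    P = PX * X
    acetate = 0.25 + 0.35 * np.maximum(uC_arr + 1.0, 0.0) * (t / 30.0)
    agitation = 1000.0 - 150.0 / (1.0 + np.exp(-(t - (t_ind + 8.0)) / 2.0))

    truth = pd.DataFrame(
        {
            "t": t, "X": X, "V": V, "PX": PX, "P": P, "B": B,
            "mu": mu_s, "v_px": v_s, "u_Feed": uF_arr, "u_Base": uB_s,
            "T": T_arr, "pH": pH_arr, "u_C": uC_arr,
            "agitation": agitation, "acetate": acetate,
        }
    )

    # online series on the 30-min grid; rate signals are interval averages
    # (matching the averaging of high-frequency plant logs), so that the
    # left-rectangle sum of u_Base exactly reconstructs cumulative base
    stride = int(round(ONLINE_STEP / step))
    idx = np.arange(0, n + 1, stride)
    uB_online = np.empty(idx.size)
    uB_online[:-1] = np.diff(B[idx]) / ONLINE_STEP
    uB_online[-1] = uB_s[idx[-1]]
    online = OnlineSeries(
        t=t[idx],
        u_Feed=uF_arr[idx],
        u_Base=uB_online,
        T=T_arr[idx],
        pH=pH_arr[idx],
        agitation=agitation[idx],
        u_C=uC_arr[idx],
    )

    if sample_times is None:
        sample_times = [0.0, t_ind, min(t_ind + 22.0, t_end)]
    st = np.asarray(sorted(sample_times), dtype=float)
    offline = OfflineSamples(
        t=st,
        X_od=np.interp(st, t, X),
        PX=np.interp(st, t, PX),
        P=np.interp(st, t, P),
        acetate=np.interp(st, t, acetate) if include_acetate else None,
    )

    return BatchRecord(
        batch_id=batch_id,
        conditions=conditions,
        online=online,
        offline=offline,
        t_induction=t_ind,
        v0=v0,
        truth=truth,
    )


def apply_measurement_model(
    record: BatchRecord,
    seed: int,
    od_cv: float = 0.025,
    product_cv: float = 0.075,
    acetate_cv: float = 0.15,
    resample_schedule: bool = True,
) -> BatchRecord:
    """Corrupt a noiseless record with the study's measurement model.

    Offline values get multiplicative Gaussian noise (CV 2.5 % on OD, 7.5 % on
    both product quantities, 15 % on acetate); online signals get small
    perturbations.  When ``resample_schedule`` is set, the offline sampling
    schedule is redrawn: samples at t0, induction and induction + 22 h always,
    plus 0-3 extra samples (2-6 per batch, averaging ~3.5).  Deterministic
    given ``seed``.
    """
    if record.truth is None:
        raise ValueError("measurement model requires the plant truth trajectory")
    rng = np.random.default_rng(seed)
    truth = record.truth
    t_fine = truth["t"].to_numpy()
    t_ind, t_end = record.t_induction, record.t_end

    if resample_schedule:
        required = np.array([0.0, t_ind, min(t_ind + 22.0, t_end)])
        n_extra = rng.choice([0, 1, 2, 3], p=[0.55, 0.35, 0.05, 0.05])
        extras = rng.uniform(1.0, t_ind + 21.0, size=int(n_extra))
        extras = np.array([e for e in extras if np.min(np.abs(required - e)) > 0.5])
        st = np.sort(np.concatenate([required, extras]))[:6]
    else:
        st = record.offline.t

    def tr(col):
        return np.interp(st, t_fine, truth[col].to_numpy())

    has_acetate = record.offline.acetate is not None
    offline = OfflineSamples(
        t=st,
        X_od=tr("X") * (1.0 + od_cv * rng.standard_normal(st.size)),
        PX=tr("PX") * (1.0 + product_cv * rng.standard_normal(st.size)),
        P=tr("P") * (1.0 + product_cv * rng.standard_normal(st.size)),
        acetate=tr("acetate") * (1.0 + acetate_cv * rng.standard_normal(st.size))
        if has_acetate
        else None,
    )

    o = record.online
    m = o.t.size
    online = OnlineSeries(
        t=o.t.copy(),
        u_Feed=o.u_Feed * (1.0 + 0.005 * rng.standard_normal(m)),
        u_Base=o.u_Base * (1.0 + 0.01 * rng.standard_normal(m)),
        T=o.T + 0.01 * rng.standard_normal(m),
        pH=o.pH + 0.01 * rng.standard_normal(m),
        agitation=o.agitation + 5.0 * rng.standard_normal(m),
        u_C=o.u_C + 0.005 * rng.standard_normal(m),
    )
    return replace(record, online=online, offline=offline)


DOE1_RANGES = (
    FactorRange("X_ind", 58.0, 20.0),
    FactorRange("T", 0.0, 0.9),
    FactorRange("pH", 0.0, 0.9),
    FactorRange("u_C", 0.0, 0.8),
)


def doe1_conditions(durations: np.ndarray | None = None) -> list[BatchConditions]:
    """Induction conditions of the 23-run four-factor Doehlert campaign.

    Biomass at induction and temperature occupy the seven-level columns, pH
    the five-level column and feed rate the three-level column.
    """
    design = generate_doehlert(4, center_replicates=3)
    design = assign_factors(design, {"pH": 0, "X_ind": 1, "T": 2, "u_C": 3})
    scaled = scale_to_process(design, DOE1_RANGES)
    if durations is None:
        durations = np.full(len(scaled), 24.0)
    return [
        BatchConditions(
            X_ind=float(row["X_ind"]), T=float(row["T"]), pH=float(row["pH"]),
            u_C=float(row["u_C"]), induction_duration=float(d),
        )
        for (_, row), d in zip(scaled.iterrows(), durations)
    ]


def _two_factor_conditions(
    names: tuple[str, str],
    ranges: tuple[FactorRange, FactorRange],
    fixed: dict[str, float],
    x_ind: np.ndarray,
    durations: np.ndarray,
) -> list[BatchConditions]:
    design = generate_doehlert(2, center_replicates=2)
    design = assign_factors(design, {names[0]: 0, names[1]: 1})
    scaled = scale_to_process(design, ranges)
    out = []
    for i, (_, row) in enumerate(scaled.iterrows()):
        kw = dict(fixed)
        kw.update({names[0]: float(row[names[0]]), names[1]: float(row[names[1]])})
        out.append(
            BatchConditions(X_ind=float(x_ind[i]), induction_duration=float(durations[i]), **kw)
        )
    return out


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x) * 2.0) / 2.0


def generate_study(
    kinetics: TrueKinetics | None = None,
    seed: int = 0,
    noise: bool = True,
    doe_only: bool = False,
    step: float = 0.05,
) -> list[BatchRecord]:
    """Generate the full synthetic study of batch records.

    The default (``doe_only=False``) emulates the structure of a 53-batch
    campaign: 23 Doehlert runs, four failed batches with fluctuating feed
    during induction, one investigative batch at presumed-optimal conditions,
    one batch with stepwise time-varying conditions, two secondary two-factor
    designs of eight runs each, four investigative batches near those designs
    and four reproducibility replicates.  ``doe_only=True`` keeps only the 23
    Doehlert runs plus the investigative batch (24 batches).

    Doehlert batches are split 2/3 train, 1/3 validation at random; the
    investigative batch joins the training partition; all other batches go to
    test.  Acetate assays are available for training/validation batches only.
    Induction lasts 22-30 h.  Deterministic given ``seed``.
    """
    if kinetics is None:
        kinetics = default_true_kinetics()
    rng = np.random.default_rng(seed)

    entries: list[tuple[str, BatchConditions, str]] = []  # (scenario, conditions, partition)

    doe1 = doe1_conditions(durations=_round_half(rng.uniform(22.0, 30.0, size=23)))
    order = rng.permutation(23)
    n_train = round(23 * 2 / 3)
    part = np.empty(23, dtype=object)
    part[order[:n_train]] = "train"
    part[order[n_train:]] = "validation"
    for cond, p in zip(doe1, part):
        entries.append(("doe1", cond, p))

    entries.append(
        (
            "investigative_optimal",
            BatchConditions(X_ind=43.0, T=-0.8, pH=0.0, u_C=0.5, induction_duration=24.0),
            "train",
        )
    )

    if not doe_only:
        for _ in range(4):  # feed-control failures: u_C fluctuates during induction
            bp = tuple(
                (float(tau), float(rng.uniform(-1.0, 2.5))) for tau in np.arange(0.0, 22.0, 2.0)
            )
            entries.append(
                (
                    "failed_feed",
                    BatchConditions(
                        X_ind=float(rng.uniform(58.0, 70.0)),
                        T=0.0,
                        pH=float(rng.uniform(-0.1, 0.5)),
                        u_C=0.3,
                        induction_duration=float(_round_half(rng.uniform(22.0, 26.0))),
                        profiles={"u_C": bp},
                    ),
                    "test",
                )
            )
        entries.append(
            (
                "variable_conditions",
                BatchConditions(
                    X_ind=55.0,
                    induction_duration=24.0,
                    profiles={
                        "T": ((0.0, -1.0), (8.0, 0.5), (16.0, 1.0)),
                        "pH": ((0.0, 1.0), (10.0, -1.0)),
                        "u_C": ((0.0, 0.0), (6.0, 1.0), (12.0, -1.0), (18.0, 0.5)),
                    },
                ),
                "test",
            )
        )
        doe2 = _two_factor_conditions(
            ("T", "u_C"),
            (FactorRange("T", -0.5, 1.0), FactorRange("u_C", 1.05, 0.85)),
            {"pH": 1.0},
            x_ind=rng.uniform(35.0, 40.0, size=8),
            durations=_round_half(rng.uniform(22.0, 26.0, size=8)),
        )
        entries += [("doe2", c, "test") for c in doe2]
        doe3 = _two_factor_conditions(
            ("u_C", "pH"),
            (FactorRange("u_C", 1.0, 1.5), FactorRange("pH", 0.7, 0.3)),
            {"T": -1.0},
            x_ind=rng.uniform(40.0, 44.0, size=8),
            durations=_round_half(rng.uniform(22.0, 26.0, size=8)),
        )
        entries += [("doe3", c, "test") for c in doe3]
        for _ in range(4):
            entries.append(
                (
                    "investigative",
                    BatchConditions(
                        X_ind=float(rng.uniform(40.0, 44.0)),
                        T=-1.0,
                        pH=float(rng.uniform(1.0, 1.3)),
                        u_C=float(rng.uniform(1.0, 3.0)),
                        induction_duration=float(_round_half(rng.uniform(22.0, 26.0))),
                    ),
                    "test",
                )
            )
        for _ in range(4):
            entries.append(
                (
                    "reproducibility",
                    BatchConditions(X_ind=39.5, T=-1.0, pH=1.0, u_C=2.0, induction_duration=24.0),
                    "test",
                )
            )

    # acetate assays cover the designed and reproducibility batches; the
    # anomalous and investigative batches went without them
    no_acetate = {"failed_feed", "variable_conditions", "investigative", "investigative_optimal"}
    records = []
    for i, (scenario, cond, partition) in enumerate(entries):
        rec = simulate_true_batch(
            cond,
            kinetics,
            step=step,
            batch_id=f"B{i + 1:03d}",
            include_acetate=scenario not in no_acetate,
        )
        rec.partition = partition
        rec.scenario = scenario
        if noise:
            rec = apply_measurement_model(rec, seed=int(rng.integers(2**31)))
        records.append(rec)
    return records
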