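# Methods

## Scope and model structure

`hybridferm` models fed-batch *E. coli* high-cell-density fermentations from
the first fed-batch sample (t0) to end of batch.  The parametric backbone is
the ideally-mixed-reactor material balance system for biomass `X` (OD650),
volume `V`, specific productivity `PX = P/X` (OD⁻¹, scaled product units) and
cumulative base `B`:

    dX/dt  = μ·X − D·X,      D = (u_Feed + u_Base)/V
    dV/dt  = u_Feed + u_Base
    dPX/dt = v_px·I,         I = 0 before induction, 1 after
    dB/dt  = a_base·μ·X·V

Volumetric product is derived algebraically, `P = PX·X`.  Integrating `P` as
a separate state would duplicate the `PX` dynamics and drift apart from
`PX·X` under Euler discretization; the tests quantify that the two
formulations converge at first order as the step shrinks.

The base state deserves comment.  Base is added for pH control in proportion
to acid-producing growth, so cumulative base correlates with total biomass:
`B(t) = a_base·(X(t)V(t) − X₀V₀)`.  Differentiating with the `X` and `V`
balances gives `dB/dt = a_base·μ·X·V`.  Embedding this as a state lets the
30-minute base log — tens of points per batch — constrain the growth rate
even though each batch has only ~3–4 offline biomass samples.  The measured
`u_Base` still drives `D` and `dV/dt`; only the *prediction* of cumulative
base flows through the model, so there is no circular self-feedback.

The three rate quantities `[μ, v_px, a_base]` are one three-layer network
with tanh hidden nodes and linear input/output layers on the inputs
`x₁ = [X, PX, T, pH, u_C]` (the last three are scaled, dimensionless process
settings; `u_C` is the carbon feed rate, proportional to the gravimetric
feed rate).  Nuisance measurements (base rate, agitation, acetate) are
deliberately *not* network inputs: they cannot be set independently in a
control space and belong to the residual analysis instead.

## Integration and sensitivities

Forward Euler with a fixed 0.25 h step; online inputs logged every 0.5 h are
mapped to the grid by zero-order hold (gravimetric set-points are piecewise
constant, so interpolation would invent information).  The induction
indicator switches at the first grid point at or after the recorded
induction time, avoiding sub-step event handling.  `V` depends only on the
measured feeds and is integrated once per batch as an exogenous trajectory.

Initial `X` and `PX` come from the earliest offline sample; `B` starts at
zero and `V` at the known initial volume.  Parameter sensitivities
`∂(X,PX,B)/∂w` are propagated by differentiating the discrete Euler
recursion exactly (forward mode), including the state-dependence of the
network inputs.  Gradients of the training loss are therefore exact for the
discretized trajectory; the suite verifies agreement with central finite
differences to better than 1e-5 relative over all weights.

## Training

The loss is the variance-weighted squared residual summed over: `X` and `PX`
at offline sample times (linear interpolation between grid nodes) and
cumulative base at every online time (left-rectangle sum of the logged
rate).  `PX` rather than `P` enters the loss because the productivity
balance is formulated in `PX`; `P` is reported in the regression analysis.
Weights `σ_c` are pooled sample variances of each variable over the training
measurements — a zero variance is a configuration error, not a silent
division.

Minimization uses L-BFGS with the exact gradients, from `n_restarts ≥ 10`
random initializations (uniform ±0.5/√fan-in, seeded per restart so restart
sequences are prefix-stable).  The validation loss is evaluated every
iteration; weights are snapshotted at the validation minimum and training
stops after `patience = 25` iterations without improvement (the stopping
*point* is validation-determined; the exact patience is a pragmatic default).
The best restart is the one with the lowest validation loss.

Input scaling is a z-score computed from the training partition and frozen
into the model (tanh saturation control).  Output scaling is affine:
μ ∈ [−0.05, 0.6] h⁻¹ and v_px ∈ [−0.1, 0.3] OD⁻¹h⁻¹ map raw outputs of order
one onto plausible rate ranges, and the a_base offset/scale is estimated per
study as the median ratio of measured cumulative base to measured total
biomass increase — an initialization from data, not a fitted quantity.

### Structure selection

Hidden-node candidates are compared by a Bayesian information criterion in
the larger-is-better orientation, `BIC = −n·ln(WSSE/n) − p·ln(n)`, computed
per partition (the standard Gaussian-likelihood form; the criterion is used
only for ranking).  The selected structure maximizes validation BIC among
candidates whose training WSSE per point is within a factor two of the best
candidate — a concrete operationalization of "consistent training
performance" — with ties broken toward fewer nodes.

## Synthetic plant

Because the motivating industrial data are confidential and scaled, the
package ships a ground-truth plant whose statistical structure mirrors such
a campaign; every downstream stage is tested against it.

* **Kinetics** (`default_true_kinetics`): μ rises with feed (saturating
  tanh), falls with biomass as `X_half/(X_half+X)` (substrate limitation at
  fixed feed), weak temperature dependence; v_px rises with temperature and
  feed, falls with pH, and is multiplied by a sigmoidal product-inhibition
  term centered at `PX = 0.5 OD⁻¹` (width 0.06 OD⁻¹), dropping the rate by
  more than a decade by `PX = 1`; `a_base` is constant at 1e-3 base units
  per OD·L.  Magnitudes were chosen once to give realistic trajectories:
  induction at OD 38–78, end-of-batch OD ≈ 70–120, v_px plateau ≈ 0.1
  OD⁻¹h⁻¹, volume growth ≈ 30 %.
* **Batch timeline**: records start at t0 in fed-batch mode at common
  center settings; induction occurs 3 h later, when design conditions are
  applied.  The initial biomass is found by shooting so biomass at induction
  hits the design target.  Induction lasts 22–30 h; every batch carries
  offline samples at t0, induction and induction + 22 h, plus 0–3 random
  extras (2–6 per batch, averaging ≈ 3.5).
* **Base generation**: the truth `B` is defined algebraically as
  `a_base·(XV − X₀V₀)` and the online `u_Base` is the interval-averaged rate,
  so the left-rectangle sum reconstructs `B` exactly — the correlation the
  hybrid model assumes holds by construction, and mirrors how high-frequency
  logs are averaged before analysis.
* **Study generator** (`generate_study`): 53 batches — the 23-run four-factor
  Doehlert campaign (X_ind and T at seven levels, pH five, u_C three; ranges
  X_ind 38–78 OD, T and pH ±0.9, u_C ±0.8 coded), four feed-failure batches
  with u_C fluctuating every 2 h, one investigative batch, one batch with
  stepwise T/pH/u_C profiles, two secondary two-factor designs of eight runs,
  four investigative and four reproducibility batches.  Doehlert batches are
  split 2/3 train / 1/3 validation at random; anomalous and secondary
  batches go to test.  `partition_by_acetate` provides the alternative
  all-regions partitioning in which acetate-bearing batches (the designed
  and reproducibility scenarios) are split 2/3–1/3 and the rest form the
  test set.
* **Measurement model**: multiplicative Gaussian noise with CV 2.5 % on OD,
  7.5 % on both product quantities, 15 % on acetate (typical analytical
  errors of OD, RP-HPLC and enzymatic acetate assays); small perturbations
  on online signals.  Deterministic given a seed.

What the plant does **not** emulate: dissolved-oxygen/kLa dynamics, pH-control
transients, mechanistic acetate overflow metabolism, sample-volume removal
and evaporation, or the batch phase before t0.  Acetate and agitation are
generated as condition-correlated nuisance series solely to exercise the
residual analysis; they do not feed back on the kinetics.  Passing tests
therefore demonstrate correctness of the estimation machinery under the
stated noise structure, not robustness to un-modeled physiology.

## Residual PLS

Product residuals (measured − predicted `P`) of acetate-bearing batches are
regressed on T, pH, u_C, u_Base, agitation and acetate plus the squares of
all six (squares computed on raw values, then every column standardized, so
each column's scaling stays interpretable).  The PLS1 model is computed by
NIPALS with deflation of both blocks; with as many components as full-rank
inputs it reproduces the OLS solution, which the tests check against a
normal-equations oracle and against scikit-learn.  The latent count is the
mode over 20 seeded 2/3–1/3 splits of the per-split cross-validated optimum
(held-out residual SSE), ties toward fewer components.  All product samples
with acetate available enter the table; a small explained-variance fraction
is the desired outcome, indicating the hybrid model already captures the
tested dependencies.  Note that in-sample explained variance of several
supervised components has a chance-level floor of roughly p/n even for pure
noise, so the diagnostic is only meaningful with well over a hundred rows —
one reason the analysis pools all acetate-bearing batches.

## Numerical choices and degenerate inputs

* Level counting in designs uses a 1e-9 tolerance (coordinates like √3/2 are
  irrational).
* Constant (zero-variance) network inputs get unit scale rather than a
  division by zero; they are simply uninformative.
* Non-finite states during integration raise an error carrying the time and
  weight norm; during training such restarts score an infinite loss and are
  discarded rather than crashing the scan.
* WSSE ≤ 0 in a BIC evaluation is clipped to 1e-12 with a warning.
* Rate-surface cells more than three z-score units outside the training
  input support are flagged `extrapolated`, not refused: extrapolated
  predictions are the model's opinion, and the study design history shows
  such opinions must be confirmed by experiments.
* CSV round trips write floats with 17 significant digits and read them with
  round-trip float parsing, so study directories are lossless.

## Problem sizes in the test suite

The recovery experiments train a five-hidden-node network (48 weights) on
the 24-batch synthetic campaign (16 train / 8 validation, ~1 550 fitted
points) with 10 restarts and up to 300 L-BFGS iterations; the structure scan
trains candidates {1, 2, 4, 8} with 5 restarts on data generated by a known
two-node network; the full-campaign fit uses the 43 acetate-bearing batches
of the 53-batch study.  These sizes make the whole suite run in a few
minutes on one CPU while leaving the conclusions (gradient exactness,
recovery, selection, residual behaviour) unchanged at larger sizes.

## Known limitations

* Forward Euler at 0.25 h is part of the method definition; the fitted rates
  absorb an O(Δt) discretization bias (≈ 1 % on μ here).  The tests measure
  this rather than hide it; an adaptive integrator would change the method.
* The network is a global smooth approximator: abrupt physiological shifts
  (e.g. overflow metabolism onset) appear only as smooth trends.
* `a_base` is modeled as a network output and may drift where data are
  sparse; the recovery test checks its design-space mean, not every corner.
* The plant's induction-time shooting assumes pre-induction growth at center
  conditions; campaigns that vary pre-induction feeding are out of scope.
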