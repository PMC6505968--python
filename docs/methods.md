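# Methods

`brainabc` implements a likelihood-free Bayesian workflow for systems-level
models of brain haemodynamics and metabolism driven by systemic signals
(arterial blood pressure ABP, arterial oxygen saturation SaO2, partial
pressure of CO2 PaCO2) and observed through NIRS: tissue oxygenation index
TOI (%), concentration changes ΔHbO2, ΔHHb, ΔHbT, ΔHbD and ΔCCO (μM), and
cerebral blood flow CBF. The pipeline is: sensitivity screening to pick the
parameters worth fitting, rejection-ABC to obtain a posterior sample, and
posterior predictive checks to judge the fit.

## Model simulation core

Models are expressed as differential-algebraic systems M·dy/dt = f(y, θ, t)
with a diagonal 0/1 mass matrix: a zero row marks an algebraic state, whose
component of f is a residual solved by nested root finds inside the
right-hand side (warm-started from the previous time step). At the problem
sizes here this is numerically equivalent to a mass-matrix integrator and
considerably simpler. The default integrator is scipy's implicit Radau
method at rtol 1e-6 / atol 1e-9 (both configurable); the stiff-capable
implicit scheme was chosen after observing that non-stiff and
Adams/BDF-switching methods can step over the piecewise-smooth kinks
introduced by the saturating activation and clipping terms below.

Every simulation starts from the steady state implied by the t = 0 inputs,
so constant inputs give constant outputs and Δ-channels (reported as changes
from the record start, as NIRS measures them) begin at exactly zero. Inputs
between samples are interpolated linearly — the data are 1 Hz and
physiologically smooth.

For the large simulation counts needed by ABC, models may provide a
vectorised right-hand side over parameter batches; a fixed-step classical
Runge-Kutta integrator then advances the whole batch on the 1 Hz input grid
with 2 substeps per sample. The fixed step is well inside the stability
region for the bundled models (fastest eigenvalue ≈ 3 s⁻¹) and the test
suite verifies the batch path against the adaptive integrator to better
than 1% of each output's range.

## The surrogate brain model (`minibrain`)

The full brain-circulation models in this literature have hundreds of
parameters; `minibrain` is a compact surrogate with four states — vessel
radius r, filtered CO2 tension v_c, tissue O2 concentration c, and oxidised
CCO fraction a_ox — built to house the standard parameter set with its usual
meanings and to reproduce the characteristic autoregulation behaviours.

Mechanics. The radius relaxes toward a Laplace tension balance,
dr/dt = k_r·[(P_d − σ_coll)·r − (T_e(r) + μ_act·T_m(r))], with distending
pressure P_d = (ABP + P_v)/2, collapse pressure σ_coll, exponential elastic
tension T_e(r) = h_fac·σ_e0·(exp(K_σ·(r/r0 − 1)) − 1) and the bell-shaped
active tension T_m(r) = T_max·exp(−|(r − r_m)/(r_t − r_m)|^{n_m}). T_m peaks
at the optimal radius r_m; shrinking r_t widens the bell so the wall carries
more active tension at any radius below r_m — the model's representation of
vessel stiffening, and the single parameter changed (r_t: 0.018 → 0.013 cm)
to define the impaired state.

Activation. Muscle activation is a squashed stimulus,
μ_act = mu_max·clip(1/2 + k_stim·k_aut·η, mu_floor, 1), with
η = R_auto·(SvO2/SvO2_n − 1) + R_autc·(1 − v_c/v_cn) + k_myo·(P_d/P_dn − 1):
raised venous oxygenation, lowered CO2 or raised pressure constrict; their
opposites dilate; k_aut = 0 freezes the stimulus at its midpoint,
disconnecting the reactivities entirely. Three design choices here were
forced by the target behaviours and are worth recording:

* a clipped-linear squash instead of a logistic — a logistic's gain collapses
  at the strongly negative stimulus of the impaired operating point, and
  with it the overcompensating constriction that makes dCBF/dABP turn
  negative for stiffened vessels at high pressure;
* a basal tone floor (mu_floor = 0.3·mu_max) — if activation can fall to
  zero, both healthy and impaired vessels reach identical fully-dilated
  mechanics during deep hypoxia and the CBF(r_t = 0.013) < CBF(r_t = 0.018)
  ordering collapses; real vascular smooth muscle retains basal tone.
  The floor also pins the impaired state near its dilation limit, which is
  why its responses to further desaturation are small — the literature-reported
  "impaired responds less" behaviour;
* a myogenic pressure term (gain k_myo) — without a direct pressure
  stimulus the only ABP pathway is distension, which always raises flow;
  the myogenic response converts a pressure rise into constriction whose
  strength scales with T_m(r), i.e. with stiffening, producing the sign flip
  at low r_t while leaving the normal vessel's response positive.

Transport and metabolism. Flow is Poiseuille, q = G·r⁴·(ABP − P_v), with G
fixed so q = 1 (i.e. CBF_n = 40 ml·100g⁻¹·min⁻¹) at defaults. Venous
saturation comes from an instantaneous O2 mass balance
q·Xtot·(SaO2 − SvO2) = CMRO2 (clipped to [0, 1]), with CMRO2 fixed by the
baseline SvO2_n = 0.65. The Hill curve with exponent n_h and half-saturation
phi maps mean capillary saturation to the dissolved O2 feeding the tissue
store, dc/dt = k_d·(c_cap − c) − cmro_max·c/(c + c50) (Michaelis–Menten
consumption so c cannot be driven negative during deep hypoxia). The CCO
redox state follows da_ox/dt = (k2_n/k2_scale)·c·(1 − a_ox) −
k_dem·(demand/p_tot)·a_ox and is observed as ΔCCO = cco_tot·Δa_ox.

Measurement. Arterial volume scales as r² (fraction f_a = 0.25 of baseline
blood volume), venous volume is constant. Haemoglobin observables use the
tissue blood-volume fraction v_frac = 0.04 and Xtot/4 (Xtot counts O2
binding sites, four per haemoglobin): ΔHbT follows total volume, ΔHbO2 the
saturated fraction, ΔHHb = ΔHbT − ΔHbO2, ΔHbD = ΔHbO2 − ΔHHb, and
TOI = 100 × volume-weighted mean saturation (≈ 73% at baseline, ≈ 55% in the
impaired state).

Parameters vs constants. The seventeen parameters exposed to screening and
fitting (σ_coll 62.79 mmHg, R_auto 1.5, R_autc 2.2, n_h 2.5, r_t 0.018 cm,
mu_max 1, n_m 1.83, r_m 0.027 cm, P_v 4 mmHg, phi 0.036 mM, Xtot 9.1 mM,
K_σ 10, p_tot 20, k_aut 1, v_cn 40 mmHg, σ_e0 0.1425 mmHg, k2_n 3915.68 s⁻¹)
carry their standard defaults and physiological meanings. Everything else
(`minibrain.CAL`: r_b, T_max, h_fac, k_stim, k_myo, mu_floor, rate and
volume constants) is a named surrogate calibration constant, fixed once so
that (i) baseline CBF normalises to 1 and baseline TOI sits in the
low 70s, (ii) dCBF/dABP at ABP = 130 mmHg is ≥ 0 at r_t = 0.018 and ≤ 0 at
r_t = 0.013, (iii) steady CBF at r_t = 0.013 is below the r_t = 0.018 value
across SaO2 ∈ {70, 80, 90, 97}%, and (iv) every Δ-output responds less in
the impaired state. These constants are excluded from priors by default and
the surrogate makes no claim of quantitative equivalence to the full
models — parameter *rankings* and posterior *geometry* transfer only
qualitatively. An additional `dummy` parameter with no pathway to any output
is included deliberately as a negative control for the screening and
information-gain machinery.

The steady state is found by a bracketed scan-plus-bisection on the radius
imbalance (other states then follow in closed form). Where the tension
balance admits several equilibria (possible in the stiffened regime, where
the clipped activation makes the balance piecewise), the root closest to the
default baseline radius is chosen — a deterministic tie-break towards the
physiological branch.

## Summary statistic and distances

The scaled baseline-to-peak statistic of a series y with reference range R
is SBTP(y) = max(|max y − y(0)|, |min y − y(0)|)/R, with R = max − min of
the default/reference signal. It condenses "how far did the signal excurse
from baseline" into one number per channel while making channels of very
different magnitudes (TOI in tens of %, ΔCCO under 1 μM) comparable. The
distance between two series' summaries is the absolute difference of their
SBTP values. The baseline is the literal first sample, not a fitted
pre-event mean.

Pointwise distances: Euclidean, RMSE, and NRMSE = RMSE/(max x₁ − min x₁)
where x₁ is the observed (reference) series — argument order matters and is
fixed throughout. Multi-channel fitting sums per-channel NRMSE with equal
weights by default (equalising scales is precisely what the normalisation is
for); custom weights are accepted.

## Morris screening

Sensitivity uses Morris elementary effects with one-at-a-time random
trajectories: each of r trajectories (default 50) visits k+1 points,
perturbing every parameter exactly once by Δ = p/(2(p−1)) on a p-level grid
(default p = 4) in unit-scaled parameter space. Ranges default to the
parameter default ±50%. Effects are computed in unit space so μ* (mean
|effect|, the ranking statistic) is comparable across differently-scaled
parameters; σ (their SD) is reported as a non-linearity indicator but never
drives selection. The response is the SBTP value per output against the
default run's range, and a joint response sums SBTP across outputs.
Trajectory count, level count and seed are free choices (they are not fixed
by any reference), so absolute μ* magnitudes are design-dependent; only
ranking and order-of-magnitude structure should be interpreted. Model
failures inside a trajectory drop that whole trajectory to keep effect
pairing valid; the count is reported.

## Rejection ABC

Fitting draws θ* from independent uniform priors, simulates, and measures
the summed NRMSE over the fitted channels. Two acceptance rules:

* tolerance — keep draws with d ≤ ε (the textbook rule);
* fixed rate — keep the fraction q of draws with the smallest distances.
  The accepted count is q·N rounded half away from zero, so 0.01% of
  30 million is exactly 3000. The rate rule is preferred in practice because
  workable ε values differ wildly between datasets.

Failed simulations count toward N (they were sampled) but carry infinite
distance and can never be accepted; more than 50% failures aborts the run.
Acceptance across batches uses a streaming top-k selector with memory
bounded by k plus one batch; ties at the cutoff keep the first-seen draw, so
the result is deterministic and identical to a stable full sort (verified in
the tests). One master seed spawns an independent RNG stream per batch.

Default problem sizes in the tests and examples are scaled to a desktop:
10⁵ draws at a 0.1% rate recovers r_t on the synthetic protocols with
central 50% intervals of the healthy and impaired marginals clearly
disjoint. Larger N at smaller rates sharpens but does not change the
geometry.

## Posterior checks

The posterior predictive band resamples the posterior 25 times with
replacement, simulates each draw, and takes pointwise medians and central
95% percentile intervals (2.5/97.5; pointwise, not simultaneous). Checks per
channel: normalised autocorrelation of observed vs predicted-median series;
residuals (observed − predicted, in that sign convention) with mean, SD,
histogram and Q-Q points against standard-normal quantiles. Information gain
per parameter is KL(posterior ‖ prior) in nats estimated from shared-bin
histograms over the prior support (50 bins by default) — simple, bounded,
and adequate at posterior sizes of order 10³; a KDE-based estimator would
smooth more but adds bandwidth choices. With uniform priors the posterior
cannot occupy a zero-prior bin; the estimator guards against it anyway.

## Synthetic protocols

The generators are pure functions of their spec and seed.

* Hypoxia challenge (healthy/impaired): ABP and PaCO2 constant at 100 and
  40 mmHg; SaO2 falls 97 → 65% and recovers along a smoothed trapezoid
  (300 s fall, 300 s hold, 300 s recovery inside a 1080 s record, 90 s
  lead-in/tail). Corner smoothing uses repeated boxcar convolution so the
  programmed trough is attained exactly. Outputs are the surrogate
  simulation at defaults (healthy) or with r_t = 0.013 cm — the only change
  — for the impaired state; observation noise defaults to zero because the
  reference datasets these emulate are themselves model-generated.
* Experiment-like record: three desaturation episodes to 80%, ABP = 100 mmHg
  plus band-limited noise (smoothed white noise, SD ≈ 3 mmHg), PaCO2
  near-constant and quantised to integer mmHg (emulating coarse end-tidal
  readings), and Gaussian observation noise on each output (default 2% of
  the channel range). This generator emulates the *described features* of a
  measured adult hypoxia challenge — episode count, depth, noise character —
  not any particular recording; fits to it exercise the machinery, not
  clinical conclusions.

Preprocessing utilities match the standard recipe for such data: 5th-order
Butterworth low-pass at 0.05 Hz (zero-phase by default, forward-backward,
with a single-pass option) and mean-bin resampling to 1 Hz.

## What the synthetic data do and do not show

Passing the recovery tests shows the estimator is consistent in the
well-specified case: data generated by the same model, same noise model,
known truth. Real recordings add model misspecification (the surrogate is
not the brain), non-Gaussian and autocorrelated noise, drifting baselines
and coupled systemic inputs; none of these are represented, so test results
bound optimism, not realism. The experiment-like generator narrows the gap
only in signal character, not in physiology.

## Numerical conventions

Time is in seconds, first sample t = 0, uniform 1 Hz grid after
preprocessing. Δ-channels are normalised by subtracting the first sample.
Steady-state residual tolerance 1e-8; integration rtol 1e-6 / atol 1e-9;
bisection for the steady radius to machine precision. Ranking ties break by
parameter declaration order. CSV I/O writes 17 significant digits and reads
with exact round-tripping.
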