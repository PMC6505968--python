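"""Compact surrogate model of brain haemodynamics, O2 transport and metabolism.

``minibrain`` is a deliberately small closed system (4 differential states)
that reproduces the qualitative behaviour of the large brain-circulation
models it stands in for: pressure/metabolic autoregulation through vessel
radius dynamics, oxygen delivery and consumption, and a cytochrome-c-oxidase
redox state, mapped to NIRS observables (TOI, ΔHbO2, ΔHHb, ΔHbT, ΔHbD, ΔCCO)
and cerebral blood flow (CBF).

Mechanism
---------
* Vessel radius r relaxes towards a tension balance (Laplace form):
  dr/dt = k_r·[ (P_d − σ_coll)·r − (T_e(r) + μ_act·T_m(r)) ],
  with distending pressure P_d = (ABP + P_v)/2, exponential elastic tension
  T_e(r) = h_fac·σ_e0·(exp(K_σ·(r/r0 − 1)) − 1) and bell-shaped active
  muscular tension T_m(r) = T_max·exp(−|(r − r_m)/(r_t − r_m)|^{n_m}).
  Reducing r_t widens the bell, i.e. stiffens the vessel.
* Muscle activation μ_act = mu_max·s(k_stim·k_aut·η) with s the logistic
  function and stimulus η = R_auto·(SvO2/SvO2_n − 1) + R_autc·(1 − v_c/v_cn):
  raised venous oxygenation or lowered CO2 constrict; hypoxia and
  hypercapnia dilate. k_aut = 0 removes the autoregulatory stimulus
  (μ_act pinned at its midpoint).
* Flow is Poiseuille, q = G·r⁴·(ABP − P_v), with conductance G calibrated so
  q equals the normal CBF at default parameters and baseline inputs.
* Venous saturation from steady O2 mass balance q·Xtot·(SaO2 − SvO2) = CMRO2
  (treated as instantaneous), clipped to [0, 1]; the Hill curve with
  exponent n_h and half-saturation phi maps saturation to dissolved O2.
* Tissue O2: dc/dt = k_d·(c_cap − c) − J(c) with c_cap the inverse-Hill of
  the mean capillary saturation and Michaelis-Menten consumption
  J(c) = cmro_max·c/(c + c50).
* CCO redox: da_ox/dt = (k2_n/k2_scale)·c·(1 − a_ox) −
  k_dem·(demand/p_tot)·a_ox; ΔCCO = cco_tot·(a_ox − a_ox(0)).
* Measurement: arterial compartment volume ∝ r² (fraction f_a at baseline),
  venous volume constant; haemoglobin observables scale with Xtot/4 and the
  tissue blood-volume fraction; TOI is the volume-weighted mean saturation
  in percent.

Parameters exposed for sensitivity analysis and fitting carry their standard
defaults (σ_coll = 62.79 mmHg, R_auto = 1.5, R_autc = 2.2, n_h = 2.5,
r_t = 0.018 cm, mu_max = 1, n_m = 1.83, r_m = 0.027 cm, P_v = 4 mmHg,
phi = 0.036 mM, Xtot = 9.1 mM, K_σ = 10, p_tot = 20, k_aut = 1,
v_cn = 40 mmHg, σ_e0 = 0.1425 mmHg, k2_n = 3915.68 1/s). The remaining
constants (module-level ``CAL``) are surrogate-only calibration choices, are
documented in docs/methods.md, and are excluded from priors by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelDefinition, ParameterSpec

__all__ = ["VesselWallParams", "muscular_tension", "minibrain_model", "steady_cbf", "CAL", "FITTABLE"]


@dataclass(frozen=True)
class VesselWallParams:
    """Parameters of the vessel-wall tension relationships."""

    T_max: float
    r_m: float
    r_t: float
    n_m: float
    sigma_e0: float = 0.1425
    K_sigma: float = 10.0
    sigma_coll: float = 62.79

    def __post_init__(self) -> None:
        if self.r_t == self.r_m:
            raise ValueError("r_t must differ from r_m (bell width undefined)")
        if self.n_m <= 0:
            raise ValueError("n_m must be > 0")
        if self.T_max < 0:
            raise ValueError("T_max must be >= 0")


def muscular_tension(r, w: VesselWallParams):
    """Bell-shaped active wall tension T_max·exp(−|(r−r_m)/(r_t−r_m)|^n_m).

    Maximal (= T_max) at r = r_m, symmetric about r_m, decreasing in
    |r − r_m|; r_t sets the width of the bell. Accepts scalar or array r.
    """
    r = np.asarray(r, dtype=float)
    z = np.abs((r - w.r_m) / (w.r_t - w.r_m))
    out = w.T_max * np.exp(-(z**w.n_m))
    return float(out) if out.ndim == 0 else out


# --- surrogate calibration constants (not model parameters; see methods note) ---

_SAO2_N = 97.0      # % baseline arterial saturation
_SVO2_N = 0.65      # baseline venous saturation (fraction)
_ABP_N = 100.0      # mmHg baseline arterial pressure
_PV_DEF = 4.0       # mmHg default venous pressure (for flow normalisation)

CAL = {
    "CBF_n": 40.0,     # ml 100g^-1 min^-1, normal CBF (flow normalisation)
    "r_b": 0.010,      # cm, baseline vessel radius at defaults
    "T_max": 4.0,      # mmHg·cm, peak active tension
    "h_fac": 3.0,      # wall-thickness factor scaling sigma_e0 into tension units
    "k_stim": 0.38,    # gain of the clipped-linear muscle-activation squash
    "k_myo": 6.0,      # myogenic (distending-pressure) reactivity of the stimulus
    "mu_floor": 0.3,   # basal muscle tone as a fraction of mu_max
    "P_d_n": 52.0,     # mmHg, baseline distending pressure (ABP_n + P_v)/2
    "k_r": 0.01,       # (mmHg·cm)^-1 s^-1, radius relaxation rate
    "tau_c": 5.0,      # s, time constant of the PaCO2 input filter
    "k_d": 0.2,        # s^-1, capillary->tissue O2 transfer rate
    "c50": 0.01,       # mM, half-saturation of tissue O2 consumption
    "cmro_frac": 0.55, # baseline consumption as a fraction of cmro_max
    "k2_scale": 2350.0,# scales k2_n into the surrogate CCO forward rate
    "k_dem": 0.0214,   # s^-1, CCO demand-side rate scale
    "demand": 20.0,    # relative demand (pairs with p_tot)
    "cco_tot": 5.0,    # uM, total CCO pool scaling DeltaCCO
    "f_a": 0.25,       # arterial fraction of baseline blood volume
    "v_frac": 0.04,    # tissue blood-volume fraction (for Hb in uM)
    "SvO2_n": _SVO2_N,
    "SaO2_n": _SAO2_N,
}

#: parameters offered to the sensitivity/fitting machinery
FITTABLE = [
    "sigma_coll", "R_auto", "R_autc", "n_h", "r_t", "mu_max", "n_m", "r_m",
    "P_v", "phi", "Xtot", "K_sigma", "p_tot", "k_aut", "v_cn", "sigma_e0",
    "k2_n",
]

# O2 mass-balance constant: q~ * Xtot * (SaO2 - SvO2) at defaults (q~ = 1)
_CMRO2_C = 1.0 * 9.1 * (_SAO2_N / 100.0 - _SVO2_N)


def _r0_for_baseline() -> float:
    """Rest radius r0 of the elastic tension law, set so the default steady
    state sits exactly at r_b with the default parameter values."""
    p = {s.name: s.default for s in _parameter_specs()}
    P_d = 0.5 * (_ABP_N + p["P_v"])
    w = VesselWallParams(CAL["T_max"], p["r_m"], p["r_t"], p["n_m"])
    tm = muscular_tension(CAL["r_b"], w)
    # eta = 0 at defaults -> mu_act = mu_max/2
    te = (P_d - p["sigma_coll"]) * CAL["r_b"] - 0.5 * p["mu_max"] * tm
    arg = te / (CAL["h_fac"] * p["sigma_e0"]) + 1.0
    if arg <= 0:
        raise ValueError("calibration infeasible: elastic tension out of range")
    return CAL["r_b"] / (1.0 + np.log(arg) / p["K_sigma"])


def _parameter_specs() -> list[ParameterSpec]:
    return [
        ParameterSpec("sigma_coll", 62.79, "mmHg", "pressure at which blood vessels collapse"),
        ParameterSpec("R_auto", 1.5, "", "autoregulatory reactivity to oxygen"),
        ParameterSpec("R_autc", 2.2, "", "autoregulatory reactivity to carbon dioxide"),
        ParameterSpec("n_h", 2.5, "", "Hill coefficient for O2 dissociation from haemoglobin"),
        ParameterSpec("r_t", 0.018, "cm", "radius in the muscular tension relationship"),
        ParameterSpec("mu_max", 1.0, "", "upper bound for the transformed stimulus"),
        ParameterSpec("n_m", 1.83, "", "exponent in the muscular tension relationship"),
        ParameterSpec("r_m", 0.027, "cm", "vessel radius at which muscular tension is maximal"),
        ParameterSpec("P_v", 4.0, "mmHg", "venous blood pressure"),
        ParameterSpec("phi", 0.036, "mM", "O2 concentration at half-maximal saturation"),
        ParameterSpec("Xtot", 9.1, "mM", "total haemoglobin O2 binding sites in blood"),
        ParameterSpec("K_sigma", 10.0, "", "sensitivity of elastic tension to vessel radius"),
        ParameterSpec("p_tot", 20.0, "", "protons pumped per modelled electron-transport turnover"),
        ParameterSpec("k_aut", 1.0, "", "overall autoregulation functioning (1 = intact)"),
        ParameterSpec("v_cn", 40.0, "mmHg", "normal filtered PaCO2"),
        ParameterSpec("sigma_e0", 0.1425, "mmHg", "scale of the elastic tension relationship"),
        ParameterSpec("k2_n", 3915.68, "1/s", "normal forward rate of cytochrome a3 reduction"),
        ParameterSpec("dummy", 1.0, "", "inert control parameter with no pathway to any output"),
    ]


def _hill(sat, phi, n_h):
    """Inverse Hill curve: saturation -> dissolved O2 concentration (mM)."""
    sat = np.clip(sat, 1e-6, 1.0 - 1e-6)
    return phi * (sat / (1.0 - sat)) ** (1.0 / n_h)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _tensions(r, th):
    """Elastic and (unit-amplitude-scaled) muscular tension, vectorised."""
    r0 = _R0
    te = CAL["h_fac"] * th["sigma_e0"] * (np.exp(th["K_sigma"] * (r / r0 - 1.0)) - 1.0)
    z = np.abs((r - th["r_m"]) / (th["r_t"] - th["r_m"]))
    tm = CAL["T_max"] * np.exp(-(z ** th["n_m"]))
    return te, tm


def _flow_and_svo2(r, abp, sao2, th):
    q = _G * r**4 * np.maximum(abp - th["P_v"], 1e-6)
    svo2 = np.clip(sao2 / 100.0 - _CMRO2_C / (q * th["Xtot"]), 1e-3, 1.0)
    return q, svo2


def _mu_act(svo2, v_c, p_d, th):
    """Muscle activation in [0, mu_max]: clipped-linear squash of the stimulus.

    The stimulus combines venous-oxygenation, CO2 and myogenic (distending
    pressure) reactivities; raised oxygenation, lowered CO2 or raised
    pressure all constrict. A clipped-linear squash (rather than a logistic)
    keeps the feedback gain constant over the physiological operating range
    and saturates hard at the bounds.
    """
    eta = (
        th["R_auto"] * (svo2 / CAL["SvO2_n"] - 1.0)
        + th["R_autc"] * (1.0 - v_c / th["v_cn"])
        + CAL["k_myo"] * (p_d / CAL["P_d_n"] - 1.0)
    )
    return th["mu_max"] * np.clip(0.5 + CAL["k_stim"] * th["k_aut"] * eta, CAL["mu_floor"], 1.0)


def _radius_imbalance(r, v_c, abp, sao2, th):
    """Tension imbalance driving dr/dt (zero at mechanical equilibrium)."""
    P_d = 0.5 * (abp + th["P_v"])
    te, tm = _tensions(r, th)
    q, svo2 = _flow_and_svo2(r, abp, sao2, th)
    mu = _mu_act(svo2, v_c, P_d, th)
    return (P_d - th["sigma_coll"]) * r - (te + mu * tm)


def _o2_rates(th):
    """Baseline-consistent tissue O2 constants (cmro_max from cmro_frac)."""
    c_cap_n = _hill((_SAO2_N / 100.0 + _SVO2_N) / 2.0, 0.036, 2.5)
    # At defaults: k_d*(c_cap_n - c_b) = cmro_max * c_b/(c_b + c50), with
    # c_b/(c_b + c50) = cmro_frac  =>  c_b = c50*f/(1-f)
    f = CAL["cmro_frac"]
    c_b = CAL["c50"] * f / (1.0 - f)
    cmro_max = CAL["k_d"] * (c_cap_n - c_b) / f
    return cmro_max


_CMRO_MAX = None  # set after module constants resolve
_R0 = None


def _rhs_batch(t, Y, th, u):
    """Vectorised right-hand side: Y is (4, B) = [r, v_c, c, a_ox]."""
    abp, sao2, paco2 = u[0], u[1], u[2]
    r, v_c, c, a_ox = Y
    dr = CAL["k_r"] * _radius_imbalance(r, v_c, abp, sao2, th)
    dv = (paco2 - v_c) / CAL["tau_c"]
    _q, svo2 = _flow_and_svo2(r, abp, sao2, th)
    s_cap = (sao2 / 100.0 + svo2) / 2.0
    c_cap = _hill(s_cap, th["phi"], th["n_h"])
    cpos = np.maximum(c, 0.0)
    dc = CAL["k_d"] * (c_cap - c) - _CMRO_MAX * cpos / (cpos + CAL["c50"])
    k_f = th["k2_n"] / CAL["k2_scale"]
    k_b = CAL["k_dem"] * (CAL["demand"] / th["p_tot"])
    da = k_f * cpos * (1.0 - a_ox) - k_b * a_ox
    return np.stack([dr, dv, dc, da])


def _steady_radius_batch(th, abp, sao2, paco2):
    """Vectorised steady radius: grid scan for a bracket, then bisection.

    Among possibly several mechanical equilibria the root closest to the
    default baseline radius is selected (deterministic tie-break towards the
    physiological branch).
    """
    B = np.asarray(next(iter(th.values()))).size
    grid = np.linspace(0.2 * CAL["r_b"], 3.0 * CAL["r_b"], 241)
    F = np.empty((grid.size, B))
    for i, rg in enumerate(grid):
        F[i] = _radius_imbalance(np.full(B, rg), np.asarray(paco2), abp, sao2, th)
    sign = np.signbit(F)
    flips = sign[:-1] != sign[1:]  # (n-1, B)
    # choose the sign change whose left edge is closest to r_b
    dist = np.abs(grid[:-1, None] - CAL["r_b"]) + np.where(flips, 0.0, 1e9)
    pick = np.argmin(dist, axis=0)
    ok = flips[pick, np.arange(B)]
    lo = grid[pick].astype(float)
    hi = grid[pick + 1].astype(float)
    lo = np.where(ok, lo, CAL["r_b"])
    hi = np.where(ok, hi, CAL["r_b"])
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        Fm = _radius_imbalance(mid, np.asarray(paco2), abp, sao2, th)
        Flo = _radius_imbalance(lo, np.asarray(paco2), abp, sao2, th)
        same = np.signbit(Fm) == np.signbit(Flo)
        lo = np.where(same, mid, lo)
        hi = np.where(same, hi, mid)
    return 0.5 * (lo + hi)


def _steady_state_batch(th, u0):
    abp, sao2, paco2 = float(u0[0]), float(u0[1]), float(u0[2])
    B = np.asarray(next(iter(th.values()))).size
    abp_v = np.full(B, abp)
    sao2_v = np.full(B, sao2)
    r = _steady_radius_batch(th, abp_v, sao2_v, paco2)
    v_c = np.full(B, paco2)
    _q, svo2 = _flow_and_svo2(r, abp_v, sao2_v, th)
    s_cap = (sao2 / 100.0 + svo2) / 2.0
    c_cap = _hill(s_cap, th["phi"], th["n_h"])
    # steady c: k_d*(c_cap - c) = cmro_max*c/(c + c50)  (positive quadratic root)
    kd, c50, vm = CAL["k_d"], CAL["c50"], _CMRO_MAX
    b = c50 + vm / kd - c_cap
    c = 0.5 * (-b + np.sqrt(b**2 + 4.0 * c_cap * c50))
    k_f = th["k2_n"] / CAL["k2_scale"]
    k_b = CAL["k_dem"] * (CAL["demand"] / th["p_tot"])
    a_ox = k_f * c / (k_f * c + k_b)
    return np.stack([r, v_c, c, a_ox])


def _outputs_batch(t, traj, th, U):
    """Map state trajectories (4, B, n_t) + inputs (3, n_t) to observables (B, n_t)."""
    r = traj[0]
    a_ox = traj[3]
    v_c = traj[1]
    abp, sao2 = U[0][None, :], U[1][None, :]
    th_c = {k: (np.asarray(v)[:, None] if np.ndim(v) else v) for k, v in th.items()}
    q, svo2 = _flow_and_svo2(r, abp, sao2, th_c)
    sa = sao2 / 100.0
    V_a = CAL["f_a"] * (r / CAL["r_b"]) ** 2
    V_v = 1.0 - CAL["f_a"]
    V_tot = V_a + V_v
    s_mean = (V_a * sa + V_v * svo2) / V_tot
    hb_scale = CAL["v_frac"] * (th_c["Xtot"] / 4.0) * 1000.0  # uM at unit relative volume
    hbt = hb_scale * V_tot
    hbo2 = hb_scale * V_tot * s_mean
    hhb = hbt - hbo2
    cco = CAL["cco_tot"] * a_ox
    return {
        "TOI": 100.0 * s_mean,
        "DHbO2": hbo2,
        "DHHb": hhb,
        "DHbT": hbt,
        "DHbD": hbo2 - hhb,
        "DCCO": cco,
        "CBF": CAL["CBF_n"] * q,
    }


def _rhs_scalar(t, y, theta, u):
    th = {k: np.asarray([v], dtype=float) for k, v in theta.items()}
    return _rhs_batch(t, np.asarray(y, dtype=float)[:, None], th, np.asarray(u, dtype=float))[:, 0]


def _outputs_scalar(t, Y, theta, U):
    th = {k: np.asarray([v], dtype=float) for k, v in theta.items()}
    out = _outputs_batch(t, Y[:, None, :], th, U)
    return {k: v[0] for k, v in out.items()}


def _steady_scalar(theta, u0):
    th = {k: np.asarray([v], dtype=float) for k, v in theta.items()}
    return _steady_state_batch(th, u0)[:, 0]


def steady_cbf(model: ModelDefinition, theta: dict | None, const_inputs: dict[str, float]) -> float:
    """Steady cerebral blood flow for constant inputs, as a fraction of
    normal CBF (1.0 = 40 ml 100g⁻¹ min⁻¹ at defaults)."""
    from .core import steady_state

    ss = steady_state(model, theta, const_inputs)
    full = model.complete_theta(theta)
    th = {k: np.array([v]) for k, v in full.items()}
    q, _ = _flow_and_svo2(
        np.array([ss[0]]),
        np.array([const_inputs["ABP"]]),
        np.array([const_inputs["SaO2"]]),
        th,
    )
    return float(q[0])


def minibrain_model() -> ModelDefinition:
    """Construct the surrogate brain model as a ModelDefinition."""
    specs = {s.name: s for s in _parameter_specs()}
    return ModelDefinition(
        name="minibrain",
        state_names=["r", "v_c", "c_O2", "a_ox"],
        differential_flags=[True, True, True, True],
        rhs=_rhs_scalar,
        input_names=["ABP", "SaO2", "PaCO2"],
        output_names=["TOI", "DHbO2", "DHHb", "DHbT", "DHbD", "DCCO", "CBF"],
        outputs=_outputs_scalar,
        parameter_table=specs,
        delta_outputs={"DHbO2", "DHHb", "DHbT", "DHbD", "DCCO"},
        initial_guess=lambda theta, u0: _steady_scalar(theta, u0),
        steady_solver=_steady_scalar,
        rhs_batch=_rhs_batch,
        outputs_batch=_outputs_batch,
        steady_state_batch=_steady_state_batch,
        units={
            "TOI": "%", "DHbO2": "uM", "DHHb": "uM", "DHbT": "uM",
            "DHbD": "uM", "DCCO": "uM", "CBF": "ml/100g/min",
        },
    )


def recalibrate() -> None:
    """Recompute the calibration-derived constants from ``CAL``.

    Called at import; call again after mutating ``CAL`` (testing only).
    """
    global _G, _R0, _CMRO_MAX
    _G = 1.0 / (CAL["r_b"] ** 4 * (_ABP_N - _PV_DEF))
    _R0 = _r0_for_baseline()
    _CMRO_MAX = _o2_rates({})


recalibrate()
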