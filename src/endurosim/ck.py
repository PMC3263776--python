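"""Two-compartment creatine-kinase (CK) model of ATP buffering in muscle.

Working muscle hydrolyses ATP in bursts — during cycling the knee
extensors are active for roughly one third of each pedal stroke — while
mitochondrial ATP production responds far more smoothly.  The CK system
(PCr + ADP + H+ <-> Cr + ATP) buffers these bursts: the myofibrillar
isoform (MM-CK) rephosphorylates ADP from the phosphocreatine store in the
cytosol, and the mitochondrial isoform (Mi-CK), sitting in the
intermembrane space (IMS) behind the mitochondrial outer membrane (MOM),
regenerates PCr next to the ATP source.

State: concentrations (umol per litre of compartment water) of ATP, ADP,
PCr, Cr and Pi in the cytosol and in the IMS.  Processes: oxidative
phosphorylation (ADP + Pi -> ATP, Michaelis-Menten in ADP and Pi, acting
on the IMS pools), reversible random bi-bi CK kinetics in each
compartment, passive MOM permeation of all five metabolites, and a
triangular pulsatile ATP-hydrolysis forcing in the cytosol.  All fluxes
are reported per litre of total cell water.

Glycolytic ATP production and pH dynamics are outside the model's scope;
[H+] enters as a workload-dependent constant that shifts the apparent CK
equilibrium.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve, minimize

__all__ = [
    "SPECIES",
    "KEQ_CK_PER_M",
    "CKParams",
    "CKState",
    "ProtonState",
    "ForcingSpec",
    "SteadyCycleMetrics",
    "CKSimResult",
    "initial_state",
    "triangular_forcing",
    "ck_rate",
    "oxphos_rate",
    "simulate_ck",
    "scan_ck_activity",
    "workload_to_flux",
    "convert_concentration",
    "fit_ck_parameters",
    "load_default_params",
]

SPECIES = ("ATP", "ADP", "PCr", "Cr", "Pi")
#: CK equilibrium constant [ATP][Cr]/([ADP][PCr][H+]), M^-1 (pH-corrected form)
KEQ_CK_PER_M = 1.66e9

_PARAM_NAMES = (
    "mm_vmax", "mm_k_adp", "mm_k_pcr", "mm_k_atp", "mm_k_cr",
    "mi_vmax", "mi_k_adp", "mi_k_pcr", "mi_k_atp", "mi_k_cr",
    "ox_vmax", "ox_k_adp", "ox_k_pi",
    "ps_atp", "ps_adp", "ps_pcr", "ps_cr", "ps_pi",
    "v_cyt", "v_ims",
    "total_creatine", "total_adenine",
)


@dataclass(frozen=True)
class ProtonState:
    """Cytosolic [H+] (mol/l), a workload-dependent constant."""

    h_molar: float = 1.0e-7

    def __post_init__(self) -> None:
        if not (0.5e-7 <= self.h_molar <= 5e-7):
            raise ValueError("[H+] outside the supported 0.5e-7..5e-7 M range")

    @property
    def keq_apparent(self) -> float:
        """Dimensionless apparent CK equilibrium [ATP][Cr]/([ADP][PCr])."""
        return KEQ_CK_PER_M * self.h_molar


@dataclass(frozen=True)
class CKParams:
    """The 22 kinetic constants of the model, with Gaussian log-priors.

    Maximal rates are umol/s per litre cell water; dissociation and
    Michaelis constants are uM; MOM permeability-area products (ps_*) are
    s^-1 referenced to total cell water; volume fractions are l/l cell
    water; pool totals are uM of cell water.
    """

    mm_vmax: float = 60000.0
    mm_k_adp: float = 135.0
    mm_k_pcr: float = 4600.0
    mm_k_atp: float = 3500.0
    mm_k_cr: float = 16000.0
    mi_vmax: float = 10000.0
    mi_k_adp: float = 204.8
    mi_k_pcr: float = 1600.0
    mi_k_atp: float = 750.0
    mi_k_cr: float = 5200.0
    ox_vmax: float = 1600.0
    ox_k_adp: float = 40.0
    ox_k_pi: float = 800.0
    ps_atp: float = 6.0
    ps_adp: float = 6.0
    ps_pcr: float = 50.0
    ps_cr: float = 50.0
    ps_pi: float = 50.0
    v_cyt: float = 0.9375
    v_ims: float = 0.0625
    total_creatine: float = 42500.0
    total_adenine: float = 8230.0
    prior_sd_log: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in _PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES])

    @classmethod
    def from_array(cls, values: np.ndarray, prior_sd_log: dict | None = None) -> "CKParams":
        kw = dict(zip(_PARAM_NAMES, map(float, values)))
        return cls(**kw, prior_sd_log=prior_sd_log or {})

    def with_ck_activity(self, factor: float) -> "CKParams":
        """Scale both CK isoform maximal rates (enzyme inhibition scan)."""
        return replace(self, mm_vmax=self.mm_vmax * factor, mi_vmax=self.mi_vmax * factor)


@dataclass
class CKState:
    """Metabolite concentrations in cytosol and IMS (uM compartment water)."""

    cytosol: np.ndarray
    ims: np.ndarray

    def __post_init__(self) -> None:
        self.cytosol = np.asarray(self.cytosol, float)
        self.ims = np.asarray(self.ims, float)
        if self.cytosol.shape != (5,) or self.ims.shape != (5,):
            raise ValueError("each compartment needs the 5 concentrations " + str(SPECIES))
        if np.any(self.cytosol < 0) or np.any(self.ims < 0):
            raise ValueError("concentrations must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.cytosol, self.ims])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CKState":
        return cls(y[:5].copy(), y[5:].copy())

    def pool_totals(self, p: CKParams) -> dict:
        """Volume-weighted conserved pools (uM cell water)."""
        w = p.v_cyt * self.cytosol + p.v_ims * self.ims
        return {
            "creatine": float(w[2] + w[3]),
            "adenine": float(w[0] + w[1]),
            "phosphate": float(w[4] + w[2] + 2 * w[1] + 3 * w[0]),
        }


def initial_state(p: CKParams, pcr_fraction: float = 0.60,
                  adp_uM: float = 30.0, pi_uM: float = 3000.0) -> CKState:
    """Resting-like initial concentrations, equal across compartments."""
    conc = np.array([
        p.total_adenine - adp_uM,
        adp_uM,
        pcr_fraction * p.total_creatine,
        (1.0 - pcr_fraction) * p.total_creatine,
        pi_uM,
    ])
    return CKState(conc.copy(), conc.copy())


@dataclass(frozen=True)
class ForcingSpec:
    """Pulsatile ATP-hydrolysis demand of rhythmic muscle contraction."""

    cadence_rpm: float = 90.0
    duty_fraction: float = 1.0 / 3.0
    j_avg_uM_per_s: float = 628.0
    shape: str = "triangular"

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_fraction <= 1.0):
            raise ValueError("duty fraction must lie in (0, 1]")
        if self.cadence_rpm <= 0 or self.j_avg_uM_per_s < 0:
            raise ValueError("cadence and average flux must be positive")
        if self.shape != "triangular":
            raise ValueError("only triangular pulses are supported")

    @property
    def period_s(self) -> float:
        return 60.0 / self.cadence_rpm

    @property
    def peak_uM_per_s(self) -> float:
        """Peak = 2 J_avg / duty (6x the average at a one-third duty cycle)."""
        return 2.0 * self.j_avg_uM_per_s / self.duty_fraction


def triangular_forcing(t: float, f: ForcingSpec) -> float:
    """Instantaneous hydrolysis flux (uM/s cell water) at time t."""
    T = f.period_s
    phase = t % T
    active = f.duty_fraction * T
    if phase >= active:
        return 0.0
    return f.peak_uM_per_s * (1.0 - abs(2.0 * phase / active - 1.0))


def ck_rate(
    atp: float, adp: float, pcr: float, cr: float,
    vmax_fwd: float, k_adp: float, k_pcr: float, k_atp: float, k_cr: float,
    keq_apparent: float,
) -> float:
    """Reversible random bi-bi CK rate, positive toward ATP production.

    The reverse maximal rate is tied to the forward one through the
    Haldane relation, so the rate vanishes exactly at the apparent
    equilibrium [ATP][Cr]/([ADP][PCr]) = Keq'.
    """
    vmax_rev = vmax_fwd * (k_atp * k_cr) / (k_adp * k_pcr * keq_apparent)
    num = vmax_fwd * (adp * pcr) / (k_adp * k_pcr) - vmax_rev * (atp * cr) / (k_atp * k_cr)
    den = (
        1.0
        + adp / k_adp + pcr / k_pcr + (adp * pcr) / (k_adp * k_pcr)
        + atp / k_atp + cr / k_cr + (atp * cr) / (k_atp * k_cr)
    )
    return num / den


def oxphos_rate(adp_ims: float, pi_ims: float, p: CKParams) -> float:
    """ATP synthesis flux (uM/s cell water), Michaelis-Menten in ADP and Pi."""
    return (
        p.ox_vmax
        * adp_ims / (adp_ims + p.ox_k_adp)
        * pi_ims / (pi_ims + p.ox_k_pi)
    )


def _fluxes(y: np.ndarray, p: CKParams, keq: float, j_hyd: float) -> tuple[np.ndarray, dict]:
    """Right-hand side (d concentrations/dt) and named total-water fluxes."""
    atp_c, adp_c, pcr_c, cr_c, pi_c = y[:5]
    atp_i, adp_i, pcr_i, cr_i, pi_i = y[5:]

    j_syn = oxphos_rate(adp_i, pi_i, p)
    r_mm = ck_rate(atp_c, adp_c, pcr_c, cr_c,
                   p.mm_vmax, p.mm_k_adp, p.mm_k_pcr, p.mm_k_atp, p.mm_k_cr, keq)
    r_mi = ck_rate(atp_i, adp_i, pcr_i, cr_i,
                   p.mi_vmax, p.mi_k_adp, p.mi_k_pcr, p.mi_k_atp, p.mi_k_cr, keq)
    ps = np.array([p.ps_atp, p.ps_adp, p.ps_pcr, p.ps_cr, p.ps_pi])
    j_mom = ps * (y[:5] - y[5:])  # positive: cytosol -> IMS

    dcyt = np.array([
        r_mm - j_hyd - j_mom[0],
        -r_mm + j_hyd - j_mom[1],
        -r_mm - j_mom[2],
        r_mm - j_mom[3],
        j_hyd - j_mom[4],
    ]) / p.v_cyt
    dims = np.array([
        j_syn + r_mi + j_mom[0],
        -j_syn - r_mi + j_mom[1],
        -r_mi + j_mom[2],
        r_mi + j_mom[3],
        -j_syn + j_mom[4],
    ]) / p.v_ims
    return np.concatenate([dcyt, dims]), {"j_syn": j_syn, "r_mm": r_mm, "r_mi": r_mi}


def steady_state_constant_forcing(
    p: CKParams, j_avg: float, h: ProtonState, state0: CKState | None = None,
    y0_guess: np.ndarray | None = None,
) -> CKState:
    """Steady state under constant (non-pulsatile) hydrolysis at j_avg.

    Conservation of the creatine, adenine and phosphate pools makes the
    raw stationarity system singular, so three rate equations are replaced
    by the pool constraints fixed by the initial state.  ``y0_guess`` warm
    starts the root find (used heavily during fitting).  If the demanded
    flux exceeds the maximal synthesis capacity no steady state exists and
    a RuntimeError is raised rather than integrating the pool depletion.
    """
    if p.ox_vmax <= 1.02 * j_avg:
        raise RuntimeError(
            f"no steady state: demand {j_avg:.0f} uM/s at or above the "
            f"synthesis capacity (ox_vmax {p.ox_vmax:.0f} uM/s)"
        )
    keq = h.keq_apparent
    s0 = state0 or initial_state(p)
    pools = s0.pool_totals(p)

    def resid(y):
        y = np.abs(y)  # stationary concentrations are positive; keep trials in domain
        dydt, _ = _fluxes(y, p, keq, j_avg)
        st = CKState.from_vector(np.abs(y))
        pt = st.pool_totals(p)
        out = dydt.copy()
        out[0] = (pt["adenine"] - pools["adenine"]) / 100.0
        out[2] = (pt["creatine"] - pools["creatine"]) / 100.0
        out[4] = (pt["phosphate"] - pools["phosphate"]) / 100.0
        return out

    for y0 in ([y0_guess] if y0_guess is not None else []) + ["relax"]:
        if isinstance(y0, str):
            y0 = _relax(p, j_avg, h, s0, 60.0)
        with np.errstate(all="ignore"):
            sol, info, ok, _ = fsolve(resid, y0, full_output=True, xtol=1e-12)
            good = (ok == 1 and np.all(np.isfinite(sol)) and np.all(np.abs(sol) > 0)
                    and np.max(np.abs(resid(sol))) < 1e-6)
        if good:
            return CKState.from_vector(np.abs(sol))
    raise RuntimeError(
        "steady-state root find did not converge (parameters may admit no "
        f"steady state at {j_avg:.0f} uM/s)"
    )


def _relax(p: CKParams, j_avg: float, h: ProtonState, s0: CKState, duration: float) -> np.ndarray:
    keq = h.keq_apparent

    def rhs(t, y):
        return _fluxes(y, p, keq, j_avg)[0]

    sol = solve_ivp(rhs, (0.0, duration), s0.as_vector(), method="LSODA",
                    rtol=1e-9, atol=1e-6)
    if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
        raise RuntimeError(f"CK relaxation failed: {sol.message}")
    return sol.y[:, -1]


@dataclass
class SteadyCycleMetrics:
    """Oscillation statistics on the final converged pedal cycle."""

    synthesis_mean: float
    synthesis_min: float
    synthesis_max: float
    synthesis_amplitude: float
    metabolite_mean: dict
    metabolite_amplitude: dict
    periodicity_defect: float  # max relative state gap between last two cycles


@dataclass
class CKSimResult:
    time_s: np.ndarray
    states: np.ndarray  # (n, 10)
    synthesis_uM_per_s: np.ndarray
    hydrolysis_uM_per_s: np.ndarray
    metrics: SteadyCycleMetrics
    final: CKState


def simulate_ck(
    params: CKParams,
    forcing: ForcingSpec,
    h: ProtonState = ProtonState(),
    duration_s: float = 600.0,
    state0: CKState | None = None,
    tail_cycles: int = 200,
    defect_tolerance: float = 0.01,
) -> CKSimResult:
    """Simulate to the periodic steady cycle and measure its amplitudes.

    The slow drift toward the working steady state (pool redistribution
    over hundreds of seconds) is integrated under cycle-averaged forcing;
    the pulsatile forcing is then switched on for the final ``tail_cycles``
    pedal strokes, which is ample for the periodic orbit to establish.
    Metrics are computed on the last full cycle and the cycle-to-cycle
    periodicity defect is reported; a defect above ``defect_tolerance``
    (relative) raises a diagnostic.
    """
    T = forcing.period_s
    if duration_s < 100 * T:
        raise ValueError("duration must cover at least 100 pedal cycles")
    keq = h.keq_apparent
    s0 = state0 or initial_state(params)
    t_switch = duration_s - tail_cycles * T
    y_relaxed = _relax(params, forcing.j_avg_uM_per_s, h, s0, t_switch)

    def rhs(t, y):
        return _fluxes(y, params, keq, triangular_forcing(t, forcing))[0]

    n_per_cycle = 80
    t_eval = t_switch + np.linspace(0.0, tail_cycles * T, tail_cycles * n_per_cycle + 1)
    sol = solve_ivp(rhs, (t_switch, duration_s), y_relaxed, method="LSODA",
                    t_eval=t_eval, max_step=forcing.duty_fraction * T / 8.0,
                    rtol=1e-9, atol=1e-6)
    if not sol.success:
        raise RuntimeError(f"CK pulsatile integration failed: {sol.message}")

    states = sol.y.T
    syn = np.array([oxphos_rate(s[6], s[9], params) for s in states])
    hyd = np.array([triangular_forcing(t, forcing) for t in sol.t])

    last = slice(-n_per_cycle - 1, None)  # 81 samples: one full cycle incl. endpoints
    prev = slice(-2 * n_per_cycle - 1, -n_per_cycle)  # same phases, one cycle earlier
    scale = np.maximum(np.abs(states[last]).mean(axis=0), 1e-9)
    defect = float(np.max(np.abs(states[last] - states[prev]) / scale))
    if defect > defect_tolerance:
        raise RuntimeError(
            f"no periodic steady cycle: defect {defect:.3g} exceeds {defect_tolerance:.3g}"
        )

    syn_last = syn[last]
    w_mean = {}
    w_amp = {}
    for i, name in enumerate(SPECIES):
        mixed = params.v_cyt * states[last][:, i] + params.v_ims * states[last][:, i + 5]
        w_mean[name] = float(np.mean(mixed[:-1]))
        w_amp[name] = float(mixed.max() - mixed.min())
    metrics = SteadyCycleMetrics(
        synthesis_mean=float(np.trapezoid(syn_last, sol.t[last]) / T),
        synthesis_min=float(syn_last.min()),
        synthesis_max=float(syn_last.max()),
        synthesis_amplitude=float(syn_last.max() - syn_last.min()),
        metabolite_mean=w_mean,
        metabolite_amplitude=w_amp,
        periodicity_defect=defect,
    )
    return CKSimResult(sol.t, states, syn, hyd, metrics, CKState.from_vector(states[-1]))


def scan_ck_activity(
    params: CKParams,
    forcing: ForcingSpec,
    h: ProtonState = ProtonState(),
    activities: tuple[float, ...] = (1.0, 0.02),
    duration_s: float = 600.0,
) -> pd.DataFrame:
    """ATP-synthesis oscillation amplitude versus CK enzyme activity."""
    rows = []
    for a in activities:
        res = simulate_ck(params.with_ck_activity(a), forcing, h, duration_s)
        m = res.metrics
        rows.append((a, m.synthesis_mean, m.synthesis_amplitude, m.periodicity_defect))
    return pd.DataFrame(rows, columns=["activity", "synthesis_mean", "synthesis_amplitude", "defect"])


# ---------------------------------------------------------------------------
# Workload conversion and concentration units
# ---------------------------------------------------------------------------

O2_MOLAR_VOLUME_L = 22.4
MUSCLE_WATER_L_PER_KG = 0.67
#: intracellular water per kg dry muscle (for biopsy unit conversion)
WATER_L_PER_KG_DRY = 3.0


def workload_to_flux(
    vo2max_l_per_min: float,
    fraction: float,
    muscle_mass_kg: float = 10.0,
    p_over_o: float = 6.0,
    attribution: float | None = None,
) -> float:
    """Average ATP hydrolysis flux (uM/s cell water) at a workload.

    Whole-body oxygen uptake at the given fraction of VO2max is converted
    to ATP turnover via the P/O ratio and referred to the cell water of the
    active muscle mass.  ``attribution`` is the fraction of whole-body
    uptake attributed to that muscle; the default is calibrated once so
    that 40 % of a 4.1 l/min VO2max in 10 kg of active leg muscle gives
    628 uM/s, and the flux is strictly linear in ``fraction`` thereafter.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if muscle_mass_kg <= 0:
        raise ValueError("muscle mass must be positive")
    if attribution is None:
        attribution = _default_attribution()
    vo2 = fraction * vo2max_l_per_min  # l O2/min
    atp_umol_per_s = vo2 / O2_MOLAR_VOLUME_L * p_over_o * 1e6 / 60.0
    water_l = muscle_mass_kg * MUSCLE_WATER_L_PER_KG
    return attribution * atp_umol_per_s / water_l


def _default_attribution() -> float:
    """Calibrated so flux(4.1 l/min, 40 %, 10 kg, P/O 6) = 628 uM/s."""
    raw = workload_to_flux(4.1, 0.40, 10.0, 6.0, attribution=1.0)
    return 628.0 / raw


def convert_concentration(x: float, to: str = "mM") -> float:
    """Convert between biopsy (mmol/kg dry weight) and cell-water units.

    ``to='mM'``: mmol/kg dw -> mM cell water (divide by 3 l/kg);
    ``to='mmol_per_kg_dw'``: the inverse.
    """
    if x < 0:
        raise ValueError("concentration must be >= 0")
    if to == "mM":
        return x / WATER_L_PER_KG_DRY
    if to == "mmol_per_kg_dw":
        return x * WATER_L_PER_KG_DRY
    raise ValueError("to must be 'mM' or 'mmol_per_kg_dw'")


# ---------------------------------------------------------------------------
# Prior-constrained fitting
# ---------------------------------------------------------------------------

def load_default_params(path: str | Path | None = None) -> CKParams:
    """Load the packaged prior table (name, prior_mean, prior_sd_rel, units)."""
    p = Path(path) if path else Path(importlib.resources.files("endurosim") / "data" / "ck_priors.tsv")
    df = pd.read_csv(p, sep="\t")
    means = dict(zip(df["name"], df["prior_mean"].astype(float)))
    sds = dict(zip(df["name"], df["prior_sd_rel"].astype(float)))
    missing = [n for n in _PARAM_NAMES if n not in means]
    if missing:
        raise ValueError(f"prior table lacks parameters {missing}")
    return CKParams(**{n: means[n] for n in _PARAM_NAMES},
                    prior_sd_log={n: float(sds[n]) for n in _PARAM_NAMES})


def _predict_means(p: CKParams, j_avg: float, h: ProtonState,
                   warm: dict | None = None, key=None) -> dict:
    """Cell-water mean concentrations (mM) at a constant-forcing steady state.

    ``warm`` is an optional cache of previous solutions (keyed per
    condition) used to warm start the root find during fitting.
    """
    guess = warm.get(key) if warm is not None else None
    st = steady_state_constant_forcing(p, j_avg, h, y0_guess=guess)
    if warm is not None:
        warm[key] = st.as_vector()
    w = p.v_cyt * st.cytosol + p.v_ims * st.ims
    return {name: w[i] / 1e3 for i, name in enumerate(SPECIES)}


def fit_ck_parameters(
    data: pd.DataFrame,
    params0: CKParams,
    free: tuple[str, ...] | None = None,
    n_restarts: int = 3,
    seed: int = 1234,
    maxiter: int = 4000,
) -> tuple[CKParams, dict]:
    """Prior-constrained least-squares fit of the kinetic constants.

    ``data`` columns: condition, metabolite (ATP|PCr|Cr), value_mmol_per_kg_dw,
    sd (same units), j_avg_uM_per_s, h_molar.  The cost is the sum of squared
    standardized residuals on the steady-state concentrations plus Gaussian
    prior penalties on the log-parameters; the downhill simplex search runs
    in log space with deterministic seeded restarts.  Returns the fitted
    parameters and a cost decomposition {data, prior, total, n_evals}.
    """
    required = {"condition", "metabolite", "value_mmol_per_kg_dw", "sd", "j_avg_uM_per_s", "h_molar"}
    if not required.issubset(data.columns):
        raise ValueError(f"data needs columns {sorted(required)}")
    conditions = data[["condition", "j_avg_uM_per_s", "h_molar"]].drop_duplicates("condition")
    if len(conditions) < 2:
        raise ValueError("need at least two workload conditions")

    free = tuple(free) if free else _PARAM_NAMES
    base = params0.as_array()
    idx = [_PARAM_NAMES.index(n) for n in free]
    theta0 = np.log(base[idx])
    sd_log = np.array([params0.prior_sd_log.get(n, 0.2) for n in free])

    obs = data.copy()
    obs["value_mM"] = obs["value_mmol_per_kg_dw"].map(convert_concentration)
    obs["sd_mM"] = obs["sd"].map(convert_concentration)
    # flatten the observations once; the cost loop must stay cheap
    cond_list = []
    for _, cond in conditions.iterrows():
        rows = obs[obs["condition"] == cond["condition"]]
        cond_list.append((
            str(cond["condition"]),
            float(cond["j_avg_uM_per_s"]),
            ProtonState(float(cond["h_molar"])),
            [SPECIES.index(m) for m in rows["metabolite"]],
            rows["value_mM"].to_numpy(),
            rows["sd_mM"].to_numpy(),
        ))

    n_evals = [0]
    warm: dict = {}

    def unpack(theta):
        vals = base.copy()
        vals[idx] = np.exp(theta)
        return CKParams.from_array(vals, params0.prior_sd_log)

    theta_ref = np.log(base[idx])
    box = 4.0 * np.where(np.isfinite(sd_log) & (sd_log > 0), sd_log, 1.0)

    def cost_parts(theta):
        n_evals[0] += 1
        # reject parameter vectors far outside the prior support before
        # attempting a (potentially ill-conditioned) steady-state solve
        if np.any(np.abs(theta - theta_ref) > box):
            return np.inf, np.inf
        p = unpack(theta)
        data_cost = 0.0
        try:
            for key, j_avg, h, met_idx, values, sds in cond_list:
                guess = warm.get(key)
                st = steady_state_constant_forcing(p, j_avg, h, y0_guess=guess)
                warm[key] = st.as_vector()
                mixed = (p.v_cyt * st.cytosol + p.v_ims * st.ims) / 1e3
                res = (mixed[met_idx] - values) / sds
                data_cost += float(res @ res)
        except (RuntimeError, FloatingPointError, ValueError):
            return np.inf, np.inf
        finite = np.isfinite(sd_log) & (sd_log > 0)
        prior_cost = float(np.sum(((theta[finite] - np.log(base[idx])[finite]) / sd_log[finite]) ** 2))
        return data_cost, prior_cost

    def cost(theta):
        d, pr = cost_parts(theta)
        return d + pr

    rng = np.random.default_rng(seed)
    best_theta, best_cost = theta0, cost(theta0)
    start = theta0
    for attempt in range(n_restarts):
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-10})
        if res.fun < best_cost:
            best_cost, best_theta = res.fun, res.x
        if res.success and attempt > 0:
            break
        start = best_theta + rng.normal(0.0, 0.02, size=best_theta.shape)
    d, pr = cost_parts(best_theta)
    fitted = unpack(best_theta)
    return fitted, {"data": d, "prior": pr, "total": d + pr, "n_evals": n_evals[0]}
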