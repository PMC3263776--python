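"""25-node whole-body heat transport with a thermoregulatory controller.

The controlled system lumps the body into six segments (head, trunk, arms,
hands, legs, feet), each with four concentric layers (core, muscle, fat,
skin), plus a central-blood node — 25 nodes in total.  Each tissue node has
a heat capacity, a basal metabolic heat production and a basal perfusion;
adjacent layers exchange heat by conduction, every node exchanges heat with
the central blood by perfusion, and skin nodes lose heat to the environment
by radiation, convection and evaporation.  The controlling system senses
the brain (head core) and area-weighted skin temperatures, and drives
sweating, skin vasodilation/vasoconstriction and shivering from the
deviations of those temperatures from their reference values.

The node energy balance is

    C_node dT[N]/dt = Q[N] - BC[N] - TD[N] - (environmental losses),

with conduction TD = TC * (T[N] - T[N+1]) and perfusion heat exchange
BC = BF * C_blood * (T[N] - T_blood); the central blood node receives the
summed counter-flows, so perfusion conserves energy exactly.

Reference temperatures are not free constants: they are *defined* as the
resting steady state of the passive system in a thermoneutral environment
(30 degC, still air), which guarantees that all effector signals vanish
there and that a thermoneutral simulation is stationary.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from endurosim.cycling import body_surface_area

__all__ = [
    "SEGMENTS",
    "LAYERS",
    "N_TISSUE",
    "BLOOD_NODE",
    "Environment",
    "EffectorSignals",
    "ControllerParams",
    "BodyParams",
    "BodyState",
    "BodyModel",
    "BodyTrajectory",
    "PhysiologyWarning",
    "conduction_flow",
    "blood_convection",
    "saturation_vapour_pressure_kPa",
    "skin_exchange",
    "controller_step",
    "load_default_model",
]

SEGMENTS = ("head", "trunk", "arms", "hands", "legs", "feet")
LAYERS = ("core", "muscle", "fat", "skin")
N_TISSUE = 24
BLOOD_NODE = 24
N_NODES = 25


class PhysiologyWarning(UserWarning):
    """Node temperature left the physiological guard band (25-45 degC)."""


def node_index(segment: str, layer: str) -> int:
    return SEGMENTS.index(segment) * 4 + LAYERS.index(layer)


BRAIN = node_index("head", "core")
TRUNK_CORE = node_index("trunk", "core")
SKIN_NODES = np.array([node_index(s, "skin") for s in SEGMENTS])
MUSCLE_NODES = np.array([node_index(s, "muscle") for s in SEGMENTS])


@dataclass(frozen=True)
class Environment:
    """Ambient conditions seen by the skin and airways."""

    air_temperature_C: float = 30.0
    wall_temperature_C: float = 30.0
    relative_humidity: float = 0.30
    air_velocity_m_per_s: float = 0.1
    barometric_pressure_kPa: float = 101.325

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_humidity <= 1.0):
            raise ValueError("relative humidity must lie in [0, 1]")
        if self.barometric_pressure_kPa <= 0:
            raise ValueError("barometric pressure must be positive")


@dataclass(frozen=True)
class EffectorSignals:
    """Controller outputs; all non-negative, all zero at the set points."""

    sweat_command_W: float = 0.0
    vasodilation: float = 0.0
    vasoconstriction: float = 0.0
    shiver_heat_W: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sweat_command_W", "vasodilation", "vasoconstriction", "shiver_heat_W"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ControllerParams:
    """Reference temperatures and linear effector gains."""

    ref_brain_C: float
    ref_skin_mean_C: float
    sweat_brain_W_per_K: float = 372.0
    sweat_skin_W_per_K: float = 33.6
    sweat_product_W_per_K2: float = 0.0
    dilation_brain_per_K: float = 32.5
    dilation_skin_per_K: float = 2.1
    constrict_brain_per_K: float = 10.0
    constrict_skin_per_K: float = 10.0
    shiver_product_W_per_K2: float = 24.4

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if name.startswith(("sweat", "dilation", "constrict", "shiver")):
                if getattr(self, name) < 0:
                    raise ValueError("controller gains must be >= 0")


def controller_step(T_brain: float, T_skin_mean: float, params: ControllerParams) -> EffectorSignals:
    """Effector signals from brain and mean-skin temperature errors.

    Warm errors recruit sweating and vasodilation; cold errors recruit
    vasoconstriction and (as a product of cold brain and cold skin error)
    shivering.  Each output is a clamped linear form, so every signal is
    continuous in the inputs and exactly zero at the reference point.
    """
    eb = T_brain - params.ref_brain_C
    es = T_skin_mean - params.ref_skin_mean_C
    warm_b, warm_s = max(eb, 0.0), max(es, 0.0)
    cold_b, cold_s = max(-eb, 0.0), max(-es, 0.0)
    sweat = max(
        params.sweat_brain_W_per_K * eb
        + params.sweat_skin_W_per_K * es
        + params.sweat_product_W_per_K2 * warm_b * warm_s,
        0.0,
    )
    dilation = max(params.dilation_brain_per_K * eb + params.dilation_skin_per_K * es, 0.0)
    constriction = max(-(params.constrict_brain_per_K * eb + params.constrict_skin_per_K * es), 0.0)
    shiver = params.shiver_product_W_per_K2 * cold_b * cold_s
    return EffectorSignals(sweat, dilation, constriction, shiver)


# ---------------------------------------------------------------------------
# Passive-system primitives
# ---------------------------------------------------------------------------

def conduction_flow(T_inner: float, T_outer: float, TC_W_per_K: float) -> float:
    """Conductive heat flow TC * (T_inner - T_outer); positive = outward."""
    if TC_W_per_K < 0:
        raise ValueError("thermal conductance must be >= 0")
    return TC_W_per_K * (T_inner - T_outer)


def blood_convection(T_node: float, T_blood: float, BF_l_per_s: float, C_blood: float = 3850.0) -> float:
    """Perfusion heat exchange BF * C_blood * (T_node - T_blood), in W.

    Blood equilibrates with tissue before reaching the capillaries, so the
    venous return leaves at tissue temperature; the blood node gains the
    summed negatives, making the exchange exactly conservative.
    """
    if BF_l_per_s < 0:
        raise ValueError("blood flow must be >= 0")
    return BF_l_per_s * C_blood * (T_node - T_blood)


def saturation_vapour_pressure_kPa(T_C: float) -> float:
    """Magnus-type saturated water vapour pressure (kPa)."""
    return 0.61078 * math.exp(17.27 * T_C / (T_C + 237.3))


@dataclass(frozen=True)
class ExchangeCoefficients:
    """Skin-environment heat exchange coefficients (editable defaults)."""

    h_radiative: float = 4.7  # W/m^2/K, linearized
    h_convective_still: float = 3.1  # W/m^2/K natural-convection floor
    h_convective_wind: float = 8.6  # W/m^2/K per sqrt(m/s)
    lewis_ratio: float = 16.5  # K/kPa, h_evap = LR * h_conv
    basal_diffusion_fraction: float = 0.06
    latent_heat_J_per_g: float = 2430.0
    respiratory_fraction: float = 0.08

    def h_convective(self, air_velocity: float) -> float:
        return max(self.h_convective_still, self.h_convective_wind * math.sqrt(max(air_velocity, 0.0)))


def skin_exchange(
    T_skin: float,
    env: Environment,
    skin_area_m2: float,
    evaporative_demand_W: float,
    coeffs: ExchangeCoefficients = ExchangeCoefficients(),
) -> tuple[float, float, float]:
    """(radiative, convective, evaporative) heat loss from one skin node, W.

    Radiation is linear in the skin-wall difference; convection uses a
    square-root-of-velocity forced-convection coefficient with a still-air
    floor.  Evaporation is basal diffusion plus the commanded sweat rate,
    capped by the vapour-pressure gradient between saturated skin and
    ambient air (the physical maximum).
    """
    if evaporative_demand_W < 0:
        raise ValueError("evaporative demand must be >= 0")
    rad = coeffs.h_radiative * skin_area_m2 * (T_skin - env.wall_temperature_C)
    h_c = coeffs.h_convective(env.air_velocity_m_per_s)
    conv = h_c * skin_area_m2 * (T_skin - env.air_temperature_C)
    p_skin = saturation_vapour_pressure_kPa(T_skin)
    p_air = env.relative_humidity * saturation_vapour_pressure_kPa(env.air_temperature_C)
    e_max = max(coeffs.lewis_ratio * h_c * skin_area_m2 * (p_skin - p_air), 0.0)
    evap = min(coeffs.basal_diffusion_fraction * e_max + evaporative_demand_W, e_max)
    return rad, conv, evap


# ---------------------------------------------------------------------------
# Parameter table and model
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["segment", "layer", "mass_kg", "C_J_per_degC", "QB_W",
                "BF_basal_l_per_s", "TC_out_W_per_degC", "area_m2"]


@dataclass(frozen=True)
class BodyParams:
    """Per-node parameter arrays for the 24 tissue nodes plus blood."""

    mass_kg: np.ndarray
    C_J_per_K: np.ndarray  # tissue nodes
    QB_W: np.ndarray
    BF_basal_l_per_s: np.ndarray
    TC_out_W_per_K: np.ndarray  # conductance to next-outer layer; 0 for skin
    area_m2: np.ndarray
    blood_volume_l: float = 2.5
    blood_heat_capacity_J_per_l_K: float = 3850.0

    def __post_init__(self) -> None:
        for name in ("mass_kg", "C_J_per_K", "QB_W", "BF_basal_l_per_s", "TC_out_W_per_K", "area_m2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_TISSUE,):
                raise ValueError(f"{name} must have exactly {N_TISSUE} tissue-node entries")
            object.__setattr__(self, name, arr)
        if np.any(self.mass_kg <= 0) or np.any(self.C_J_per_K <= 0):
            raise ValueError("node masses and heat capacities must be positive")
        if np.any(self.TC_out_W_per_K < 0) or np.any(self.BF_basal_l_per_s < 0):
            raise ValueError("conductances and basal flows must be non-negative")
        skin = np.zeros(N_TISSUE, bool)
        skin[SKIN_NODES] = True
        if np.any(self.area_m2[skin] <= 0) or np.any(self.area_m2[~skin] != 0):
            raise ValueError("skin_area must be positive exactly on skin nodes")

    @property
    def C_blood_node_J_per_K(self) -> float:
        return self.blood_volume_l * self.blood_heat_capacity_J_per_l_K

    @classmethod
    def from_table(cls, df: pd.DataFrame, **blood_kwargs) -> "BodyParams":
        missing = [c for c in _TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"body parameter table lacks columns {missing}")
        order = [(s, l) for s in SEGMENTS for l in LAYERS]
        df = df.set_index(["segment", "layer"]).loc[order].reset_index()
        return cls(
            mass_kg=df["mass_kg"].to_numpy(float),
            C_J_per_K=df["C_J_per_degC"].to_numpy(float),
            QB_W=df["QB_W"].to_numpy(float),
            BF_basal_l_per_s=df["BF_basal_l_per_s"].to_numpy(float),
            TC_out_W_per_K=df["TC_out_W_per_degC"].to_numpy(float),
            area_m2=df["area_m2"].to_numpy(float),
            **blood_kwargs,
        )

    def scaled_to(self, mass_kg: float, height_m: float,
                  ref_mass_kg: float = 74.0, ref_height_m: float = 1.72) -> "BodyParams":
        """Rescale the table to another subject.

        Node masses, heat capacities, basal heat and basal perfusion scale
        with body mass; skin areas and conductances scale with the Du Bois
        body surface area.
        """
        fm = mass_kg / ref_mass_kg
        fa = body_surface_area(mass_kg, height_m) / body_surface_area(ref_mass_kg, ref_height_m)
        return replace(
            self,
            mass_kg=self.mass_kg * fm,
            C_J_per_K=self.C_J_per_K * fm,
            QB_W=self.QB_W * fm,
            BF_basal_l_per_s=self.BF_basal_l_per_s * fm,
            TC_out_W_per_K=self.TC_out_W_per_K * fa,
            area_m2=self.area_m2 * fa,
            blood_volume_l=self.blood_volume_l * fm,
        )


@dataclass
class BodyState:
    """25 node temperatures (degC) plus accumulated sweat loss (kg)."""

    T_C: np.ndarray
    sweat_loss_kg: float = 0.0

    def __post_init__(self) -> None:
        self.T_C = np.asarray(self.T_C, dtype=float)
        if self.T_C.shape != (N_NODES,):
            raise ValueError(f"state needs {N_NODES} temperatures")

    def check_physiological(self) -> None:
        """Warn (do not clip) if any node left the 25-45 degC guard band."""
        bad = np.where((self.T_C < 25.0) | (self.T_C > 45.0))[0]
        if bad.size:
            warnings.warn(
                f"node temperatures outside 25-45 degC at indices {bad.tolist()}: "
                f"{self.T_C[bad].round(2).tolist()}",
                PhysiologyWarning,
                stacklevel=2,
            )

    @property
    def brain_C(self) -> float:
        return float(self.T_C[BRAIN])

    @property
    def blood_C(self) -> float:
        return float(self.T_C[BLOOD_NODE])


@dataclass
class BodyTrajectory:
    """Sampled trajectory plus a cumulative heat-flow ledger."""

    time_s: np.ndarray
    states: np.ndarray  # (n, 25)
    sweat_loss_kg: np.ndarray
    production_J: np.ndarray
    loss_J: np.ndarray
    model: "BodyModel"

    def mean_skin_C(self) -> np.ndarray:
        w = self.model.params.area_m2[SKIN_NODES]
        return self.states[:, SKIN_NODES] @ (w / w.sum())

    def storage_J(self) -> np.ndarray:
        C = np.append(self.model.params.C_J_per_K, self.model.params.C_blood_node_J_per_K)
        return (self.states - self.states[0]) @ C

    def ledger(self) -> dict:
        prod = float(self.production_J[-1])
        loss = float(self.loss_J[-1])
        stored = float(self.storage_J()[-1])
        return {
            "production_J": prod,
            "loss_J": loss,
            "storage_J": stored,
            "residual_J": prod - loss - stored,
            "relative_residual": (prod - loss - stored) / prod if prod else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{s}_{l}" for s in SEGMENTS for l in LAYERS] + ["blood"]
        recs = []
        for i, t in enumerate(self.time_s):
            for j, lab in enumerate(labels):
                recs.append((t, lab, self.states[i, j]))
        return pd.DataFrame(recs, columns=["time_s", "node", "temperature_C"])

    def final_state(self) -> BodyState:
        return BodyState(self.states[-1].copy(), float(self.sweat_loss_kg[-1]))


class BodyModel:
    """Couples the passive 25-node system with the feedback controller."""

    def __init__(
        self,
        params: BodyParams,
        controller: ControllerParams | None = None,
        exchange: ExchangeCoefficients = ExchangeCoefficients(),
        distribution: dict | None = None,
        local_sweat_q10: float = 10.0,
        muscle_bf_l_per_s_per_W: float = 0.00028,
        dilation_bf_l_per_s_per_unit: float = 0.001,
        thermoneutral: Environment = Environment(),
    ) -> None:
        self.params = params
        self.exchange = exchange
        self.local_sweat_q10 = local_sweat_q10
        self.muscle_bf = muscle_bf_l_per_s_per_W
        self.dilation_bf = dilation_bf_l_per_s_per_unit
        self.thermoneutral = thermoneutral
        dist = distribution or {}
        self.skin_sensor_w = np.asarray(dist.get("skin_sensor_weight", self.params.area_m2[SKIN_NODES] / self.params.area_m2[SKIN_NODES].sum()), float)
        self.sweat_frac = np.asarray(dist.get("sweat_fraction", self.skin_sensor_w), float)
        self.dilation_frac = np.asarray(dist.get("dilation_fraction", self.skin_sensor_w), float)
        self.constrict_frac = np.asarray(dist.get("constrict_fraction", self.skin_sensor_w), float)
        self.shiver_frac = np.asarray(dist.get("shiver_fraction", [0.02, 0.85, 0.05, 0.0, 0.08, 0.0]), float)
        for arr in (self.skin_sensor_w, self.sweat_frac, self.dilation_frac, self.constrict_frac, self.shiver_frac):
            if arr.shape != (6,) or abs(arr.sum() - 1.0) > 1e-6:
                raise ValueError("distribution fractions must be 6 per-segment values summing to 1")
        self._controller = controller  # resolved lazily against the set points
        self._set_points: np.ndarray | None = None

    # -- set points -----------------------------------------------------

    @property
    def set_points(self) -> np.ndarray:
        """Reference temperatures: the thermoneutral resting steady state."""
        if self._set_points is None:
            self._set_points = self._solve_passive_steady_state(self.thermoneutral)
        return self._set_points

    @property
    def controller(self) -> ControllerParams:
        if self._controller is None:
            sp = self.set_points
            w = self.skin_sensor_w
            self._controller = ControllerParams(
                ref_brain_C=float(sp[BRAIN]),
                ref_skin_mean_C=float(sp[SKIN_NODES] @ w),
            )
        elif self._controller.ref_brain_C is None:  # pragma: no cover
            raise ValueError("controller reference temperatures unresolved")
        return self._controller

    def mean_skin_C(self, T: np.ndarray) -> float:
        return float(T[SKIN_NODES] @ self.skin_sensor_w)

    def _solve_passive_steady_state(self, env: Environment) -> np.ndarray:
        """Steady state with all effector signals forced to zero."""
        zero = EffectorSignals()

        def resid(T):
            dT, _ = self.derivative(T, env, effectors=zero)
            return dT

        T0 = np.full(N_NODES, 36.0)
        T0[SKIN_NODES] = 33.0
        sol, info, ok, msg = fsolve(resid, T0, full_output=True)
        if ok != 1:
            raise RuntimeError(f"thermoneutral steady state did not converge: {msg}")
        return sol

    # -- effectors and flows --------------------------------------------

    def effectors(self, T: np.ndarray) -> EffectorSignals:
        return controller_step(float(T[BRAIN]), self.mean_skin_C(T), self.controller)

    def blood_flows(self, T: np.ndarray, eff: EffectorSignals,
                    extra_met_W: np.ndarray | None = None) -> np.ndarray:
        """Per-node perfusion (l/s): basal + metabolic scaling + vasomotor tone."""
        bf = self.params.BF_basal_l_per_s.copy()
        if extra_met_W is not None:
            bf[MUSCLE_NODES] += self.muscle_bf * extra_met_W[MUSCLE_NODES]
        if eff.shiver_heat_W > 0:
            bf[MUSCLE_NODES] += self.muscle_bf * eff.shiver_heat_W * self.shiver_frac
        err = self._skin_errors(T)
        local = 2.0 ** (err / self.local_sweat_q10)
        dil = self.dilation_frac * eff.vasodilation * self.dilation_bf
        bf[SKIN_NODES] = (self.params.BF_basal_l_per_s[SKIN_NODES] + dil) / (
            1.0 + self.constrict_frac * eff.vasoconstriction
        ) * local
        return bf

    def _skin_errors(self, T: np.ndarray) -> np.ndarray:
        # zero local error while the set points themselves are being solved
        if self._set_points is None:
            return np.zeros(len(SKIN_NODES))
        return T[SKIN_NODES] - self._set_points[SKIN_NODES]

    def sweat_per_node(self, T: np.ndarray, eff: EffectorSignals) -> np.ndarray:
        err = self._skin_errors(T)
        return self.sweat_frac * eff.sweat_command_W * 2.0 ** (err / self.local_sweat_q10)

    # -- dynamics --------------------------------------------------------

    def derivative(
        self,
        T: np.ndarray,
        env: Environment,
        exercise_heat_W: np.ndarray | None = None,
        extra_met_W: np.ndarray | None = None,
        effectors: EffectorSignals | None = None,
    ) -> tuple[np.ndarray, dict]:
        """dT/dt for all 25 nodes, plus instantaneous heat-flow bookkeeping.

        ``exercise_heat_W`` is the heat deposited per tissue node (metabolic
        minus mechanical work); ``extra_met_W`` is the extra local metabolic
        rate used for perfusion scaling and respiratory loss.  The
        controller is evaluated inside the right-hand side unless explicit
        ``effectors`` are supplied.
        """
        T = np.asarray(T, float)
        p = self.params
        if exercise_heat_W is None:
            exercise_heat_W = np.zeros(N_TISSUE)
        if extra_met_W is None:
            extra_met_W = exercise_heat_W
        eff = effectors if effectors is not None else self.effectors(T)

        Q = p.QB_W + exercise_heat_W
        Q[MUSCLE_NODES] = Q[MUSCLE_NODES] + eff.shiver_heat_W * self.shiver_frac

        # conduction along the core->muscle->fat->skin chain of each segment
        cond_net = np.zeros(N_TISSUE)
        for s in range(6):
            for l in range(3):
                i = 4 * s + l
                f = conduction_flow(T[i], T[i + 1], p.TC_out_W_per_K[i])
                cond_net[i] += f
                cond_net[i + 1] -= f

        bf = self.blood_flows(T, eff, extra_met_W)
        bc = bf * p.blood_heat_capacity_J_per_l_K * (T[:N_TISSUE] - T[BLOOD_NODE])

        # skin losses
        env_loss = np.zeros(N_TISSUE)
        sweat = self.sweat_per_node(T, eff)
        evap_total = 0.0
        for j, i in enumerate(SKIN_NODES):
            rad, conv, evap = skin_exchange(T[i], env, p.area_m2[i], float(sweat[j]), self.exchange)
            env_loss[i] = rad + conv + evap
            evap_total += evap

        total_met = float(p.QB_W.sum() + extra_met_W.sum() + eff.shiver_heat_W)
        resp = self.exchange.respiratory_fraction * total_met
        env_loss[TRUNK_CORE] += resp

        dT = np.empty(N_NODES)
        dT[:N_TISSUE] = (Q - bc - cond_net - env_loss) / p.C_J_per_K
        dT[BLOOD_NODE] = bc.sum() / p.C_blood_node_J_per_K

        aux = {
            "production_W": float(Q.sum()),
            "loss_W": float(env_loss.sum()),
            "evaporative_W": float(evap_total),
            "respiratory_W": float(resp),
            "effectors": eff,
            "blood_flow_l_per_s": bf,
        }
        return dT, aux

    def integrate(
        self,
        state0: BodyState,
        duration_s: float,
        env_schedule,
        load_schedule=None,
        sample_dt_s: float = 1.0,
        max_step_s: float = 1.0,
    ) -> BodyTrajectory:
        """Integrate the coupled system with a stiff-capable adaptive solver.

        ``env_schedule`` is an :class:`Environment` or a callable t ->
        Environment; ``load_schedule`` is None or a callable t ->
        (exercise_heat array, extra_metabolic array).  The returned
        trajectory is sampled at ``sample_dt_s`` and carries a cumulative
        production/loss ledger integrated alongside the temperatures.
        """
        if duration_s <= 0:
            raise ValueError("duration must be positive")
        env_fun = env_schedule if callable(env_schedule) else (lambda t: env_schedule)
        load_fun = load_schedule if callable(load_schedule) else (lambda t: (None, None))

        def rhs(t, y):
            T = y[:N_NODES]
            heat, met = load_fun(t)
            dT, aux = self.derivative(T, env_fun(t), heat, met)
            d_sweat = aux["evaporative_W"] / (self.exchange.latent_heat_J_per_g * 1e3)
            return np.concatenate([dT, [d_sweat, aux["production_W"], aux["loss_W"]]])

        y0 = np.concatenate([state0.T_C, [state0.sweat_loss_kg, 0.0, 0.0]])
        t_eval = np.arange(0.0, duration_s + 0.5 * sample_dt_s, sample_dt_s)
        t_eval[-1] = duration_s
        sol = solve_ivp(rhs, (0.0, duration_s), y0, method="LSODA",
                        t_eval=t_eval, max_step=max_step_s, rtol=1e-7, atol=1e-7)
        if not sol.success:
            last = BodyState(sol.y[:N_NODES, -1], float(sol.y[N_NODES, -1]))
            raise RuntimeError(
                f"body integration failed at t={sol.t[-1]:.1f}s ({sol.message}); "
                f"last state brain={last.brain_C:.2f} degC"
            )
        traj = BodyTrajectory(
            time_s=sol.t,
            states=sol.y[:N_NODES].T.copy(),
            sweat_loss_kg=sol.y[N_NODES].copy(),
            production_J=sol.y[N_NODES + 1].copy(),
            loss_J=sol.y[N_NODES + 2].copy(),
            model=self,
        )
        traj.final_state().check_physiological()
        return traj


# ---------------------------------------------------------------------------
# Loading the packaged parametrization
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("endurosim") / "data" / name)


def load_default_model(
    mass_kg: float | None = None,
    height_m: float | None = None,
    table_path: str | Path | None = None,
    config_path: str | Path | None = None,
) -> BodyModel:
    """Build the packaged 25-node model, optionally rescaled to a subject.

    The parameter table (TSV) and controller configuration (YAML) ship with
    the package and are plain editable files; pass alternative paths to use
    another parametrization.
    """
    table = pd.read_csv(table_path or _data_path("body_nodes.tsv"), sep="\t")
    cfg = yaml.safe_load(Path(config_path or _data_path("controller.yaml")).read_text())
    blood = cfg.get("blood", {})
    params = BodyParams.from_table(
        table,
        blood_volume_l=float(blood.get("volume_l", 2.5)),
        blood_heat_capacity_J_per_l_K=float(blood.get("heat_capacity_J_per_l_K", 3850.0)),
    )
    ref = cfg.get("reference", {})
    if mass_kg is not None or height_m is not None:
        params = params.scaled_to(
            mass_kg or float(ref.get("total_mass_kg", 74.0)),
            height_m or float(ref.get("height_m", 1.72)),
            ref_mass_kg=float(ref.get("total_mass_kg", 74.0)),
            ref_height_m=float(ref.get("height_m", 1.72)),
        )
    ex = cfg.get("environment_exchange", {})
    exchange = ExchangeCoefficients(
        h_radiative=float(ex.get("h_radiative_W_per_m2K", 4.7)),
        h_convective_still=float(ex.get("h_convective_still_W_per_m2K", 3.1)),
        h_convective_wind=float(ex.get("h_convective_wind_W_per_m2K_per_sqrt_mps", 8.6)),
        lewis_ratio=float(ex.get("lewis_ratio_K_per_kPa", 16.5)),
        basal_diffusion_fraction=float(ex.get("basal_skin_diffusion_fraction", 0.06)),
        latent_heat_J_per_g=float(ex.get("latent_heat_J_per_g", 2430.0)),
        respiratory_fraction=float(ex.get("respiratory_fraction", 0.08)),
    )
    tn = ref.get("thermoneutral", {})
    thermoneutral = Environment(
        air_temperature_C=float(tn.get("air_temperature_C", 30.0)),
        wall_temperature_C=float(tn.get("wall_temperature_C", 30.0)),
        relative_humidity=float(tn.get("relative_humidity", 0.30)),
        air_velocity_m_per_s=float(tn.get("air_velocity_m_per_s", 0.1)),
    )
    gains = cfg.get("gains", {})
    model = BodyModel(
        params,
        exchange=exchange,
        distribution=cfg.get("distribution"),
        local_sweat_q10=float(gains.get("local_sweat_q10", 10.0)),
        muscle_bf_l_per_s_per_W=float(cfg.get("muscle_blood_flow_l_per_s_per_W", 0.00028)),
        thermoneutral=thermoneutral,
    )
    # resolve controller gains against the computed set points
    sp = model.set_points
    model._controller = ControllerParams(
        ref_brain_C=float(sp[BRAIN]),
        ref_skin_mean_C=float(sp[SKIN_NODES] @ model.skin_sensor_w),
        sweat_brain_W_per_K=float(gains.get("sweat_brain_W_per_K", 372.0)),
        sweat_skin_W_per_K=float(gains.get("sweat_skin_W_per_K", 33.6)),
        sweat_product_W_per_K2=float(gains.get("sweat_product_W_per_K2", 0.0)),
        dilation_brain_per_K=float(gains.get("dilation_brain_per_K", 32.5)),
        dilation_skin_per_K=float(gains.get("dilation_skin_per_K", 2.1)),
        constrict_brain_per_K=float(gains.get("constrict_brain_per_K", 10.0)),
        constrict_skin_per_K=float(gains.get("constrict_skin_per_K", 10.0)),
        shiver_product_W_per_K2=float(gains.get("shiver_product_W_per_K2", 24.4)),
    )
    return model
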