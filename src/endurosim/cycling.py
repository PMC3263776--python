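"""Bicycle locomotion mechanics and aerobic metabolic power supply.

The rider-bicycle system obeys the power balance

    m dv/dt = F_prop - R_r - R_a - F_g

with rolling resistance R_r = C_Rr (M + M_b) g cos(theta), aerodynamic drag
R_a = k (v + v_w)^2, and the gravity component F_g = (M + M_b) g sin(theta)
on a road of gradient S = tan(theta).  Propulsive force comes from aerobic
metabolism: the rise of oxygen uptake above rest, times the energy
equivalent of oxygen, times the incremental (delta) efficiency, divided by
the current speed.  Altitude enters twice: barometric pressure lowers air
density (and hence the drag factor k) and lowers the oxygen partial
pressure, which reduces the sustainable oxygen uptake of trained athletes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from endurosim.routes import RouteProfile

__all__ = [
    "G",
    "RHO_SEA_LEVEL",
    "SCALE_HEIGHT_M",
    "RiderParams",
    "RideResult",
    "RideStallError",
    "air_density",
    "pO2_fraction",
    "vo2_altitude_factor",
    "rolling_resistance",
    "air_resistance",
    "gravity_force",
    "metabolic_power",
    "body_surface_area",
    "simulate_ride",
]

G = 9.81  # m/s^2
RHO_SEA_LEVEL = 1.225  # kg/m^3 at 15 degC
SCALE_HEIGHT_M = 8434.0  # isothermal barometric scale height
#: sensitivity of trained athletes' maximal O2 uptake to inspired pO2:
#: ~13 % uptake loss per 24 % partial-pressure deficit.
HYPOXIA_SLOPE = 13.0 / 24.0
F_PROP_MAX = 500.0  # N, cap of P/v at low speed (standing start)

_REF_MASS_KG = 72.0
_REF_HEIGHT_M = 1.79


class RideStallError(RuntimeError):
    """Raised when propulsive power cannot keep the rider moving uphill."""


def air_density(altitude_m: float) -> float:
    """Air density (kg/m^3) from an isothermal barometric model."""
    if altitude_m < 0:
        raise ValueError("altitude must be >= 0")
    return RHO_SEA_LEVEL * math.exp(-altitude_m / SCALE_HEIGHT_M)


def pO2_fraction(altitude_m: float) -> float:
    """Oxygen partial pressure at altitude relative to sea level.

    O2 mole fraction is constant in the troposphere, so the ratio follows
    total barometric pressure (~0.80 at 1850 m).
    """
    if altitude_m < 0:
        raise ValueError("altitude must be >= 0")
    return math.exp(-altitude_m / SCALE_HEIGHT_M)


def vo2_altitude_factor(altitude_m: float) -> float:
    """Multiplicative hypoxia factor on sustainable oxygen uptake.

    Trained endurance athletes lose about 13 % of maximal O2 uptake per
    24 % drop in inspired O2 partial pressure; the factor is applied to the
    *current* altitude so uptake falls progressively during a climb.
    """
    return 1.0 - HYPOXIA_SLOPE * (1.0 - pO2_fraction(altitude_m))


def body_surface_area(mass_kg: float, height_m: float) -> float:
    """Du Bois body surface area (m^2)."""
    return 0.007184 * (mass_kg**0.425) * ((height_m * 100.0) ** 0.725)


@dataclass(frozen=True)
class RiderParams:
    """Mechanical and metabolic constants of the athlete.

    ``drag_area_m2`` is the effective drag area (C_d A); the drag factor at
    altitude h is k = 0.5 * rho(h) * C_d A.  When ``scale_drag_with_body``
    is set, C_d A is rescaled by the Du Bois surface-area ratio relative to
    the 72 kg / 1.79 m reference rider, which is how the body-size
    sensitivity experiments change aerodynamics.
    """

    mass_kg: float = 72.0
    bike_mass_kg: float = 8.0
    height_m: float = 1.79
    c_rr: float = 0.003
    drag_area_m2: float = 0.32
    vo2max_sealevel: float = 6.1  # l O2/min
    vo2_rest: float = 0.3  # l O2/min
    delta_efficiency: float = 0.231
    energy_per_litre_o2: float = 20.9  # kJ/l
    brain_push: float = 1.0  # fraction of VO2max voluntarily sustained
    scale_drag_with_body: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.delta_efficiency < 1.0):
            raise ValueError("delta_efficiency must lie in (0, 1)")
        if not (0.0 < self.brain_push <= 1.0):
            raise ValueError("brain_push must lie in (0, 1]")
        if self.mass_kg <= 0 or self.bike_mass_kg <= 0 or self.height_m <= 0:
            raise ValueError("masses and height must be positive")
        if self.c_rr < 0:
            raise ValueError("rolling coefficient must be >= 0")

    @property
    def total_mass_kg(self) -> float:
        return self.mass_kg + self.bike_mass_kg

    @property
    def effective_drag_area_m2(self) -> float:
        if not self.scale_drag_with_body:
            return self.drag_area_m2
        ratio = body_surface_area(self.mass_kg, self.height_m) / body_surface_area(
            _REF_MASS_KG, _REF_HEIGHT_M
        )
        return self.drag_area_m2 * ratio

    def drag_factor(self, altitude_m: float, density_correction: bool = True) -> float:
        """k (N s^2/m^2) at altitude; k is proportional to air density."""
        rho = air_density(altitude_m) if density_correction else RHO_SEA_LEVEL
        return 0.5 * rho * self.effective_drag_area_m2

    def with_(self, **kwargs) -> "RiderParams":
        return replace(self, **kwargs)


def rolling_resistance(S: float, mass_kg: float, bike_mass_kg: float, c_rr: float) -> float:
    """Rolling resistance (N): C_Rr times the road-normal weight component."""
    if c_rr < 0:
        raise ValueError("rolling coefficient must be >= 0")
    cos_theta = 1.0 / math.sqrt(1.0 + S * S)
    return c_rr * (mass_kg + bike_mass_kg) * G * cos_theta


def gravity_force(S: float, mass_kg: float, bike_mass_kg: float) -> float:
    """Road-parallel weight component (N); negative on descents."""
    sin_theta = S / math.sqrt(1.0 + S * S)
    return (mass_kg + bike_mass_kg) * G * sin_theta


def air_resistance(v_ss: float, v_w: float, k: float) -> float:
    """Aerodynamic drag (N): k (v_ss + v_w)^2, head wind positive.

    A tail wind faster than the ground speed would make the relative wind
    propulsive; that contribution is clamped to zero.
    """
    if k < 0:
        raise ValueError("drag factor must be >= 0")
    v_rel = v_ss + v_w
    return k * v_rel * v_rel if v_rel > 0 else 0.0


def metabolic_power(vo2_l_per_min: float, rider: RiderParams) -> tuple[float, float]:
    """(mechanical power W, total metabolic rate W) at an oxygen uptake.

    Mechanical power is the suprabasal oxygen uptake times the energy
    equivalent of O2 times the delta efficiency; the total metabolic rate
    (for the heat budget) is the full uptake times the energy equivalent.
    """
    if vo2_l_per_min < rider.vo2_rest - 1e-12:
        raise ValueError("VO2 below resting level")
    joules_per_litre = rider.energy_per_litre_o2 * 1e3
    total_w = vo2_l_per_min * joules_per_litre / 60.0
    mech_w = (vo2_l_per_min - rider.vo2_rest) * joules_per_litre / 60.0 * rider.delta_efficiency
    return mech_w, total_w


@dataclass
class RideResult:
    """Trajectory and summary of a simulated ride."""

    finish_time_s: float
    series: pd.DataFrame  # t, distance, speed, altitude, power components, vo2

    def summary(self) -> dict:
        s = self.series
        return {
            "finish_time_s": self.finish_time_s,
            "mean_speed_m_per_s": float(s["distance_m"].iloc[-1] / self.finish_time_s),
            "mean_P_gravity_W": float(s["P_gravity_W"].mean()),
            "mean_P_air_W": float(s["P_air_W"].mean()),
            "mean_P_rolling_W": float(s["P_rolling_W"].mean()),
            "mean_P_mech_W": float(s["P_mech_W"].mean()),
        }


def _sustained_vo2(rider: RiderParams, altitude_m: float, hypoxia_on: bool) -> float:
    vo2 = rider.brain_push * rider.vo2max_sealevel
    if hypoxia_on:
        vo2 *= vo2_altitude_factor(altitude_m)
    return max(vo2, rider.vo2_rest)


def simulate_ride(
    route: RouteProfile,
    rider: RiderParams,
    wind_m_per_s: float = 0.0,
    hypoxia_on: bool = False,
    density_correction_on: bool = True,
    v0: float = 1.0,
    sample_dt_s: float = 1.0,
    max_duration_s: float = 4 * 3600.0,
) -> RideResult:
    """Integrate the ride until the route length is covered.

    The state is (distance, speed).  Propulsive force is mechanical power
    over speed, capped at ``F_PROP_MAX`` to remove the standing-start
    singularity; the ride begins at ``v0`` (default 1 m/s).  Gradients are
    piecewise constant, so the solver is restarted at each route breakpoint
    to keep the right-hand side smooth inside every integration interval.
    """
    total = route.length_m
    d0 = float(route.distance_m[0])
    grads = route.gradients
    edges = route.distance_m

    def rhs(t, y, S, k_fun, alt_fun):
        x, v = y
        v = max(v, 1e-3)
        vo2 = _sustained_vo2(rider, alt_fun(x), hypoxia_on)
        p_mech, _ = metabolic_power(vo2, rider)
        f_prop = min(p_mech / v, F_PROP_MAX)
        f = (
            f_prop
            - rolling_resistance(S, rider.mass_kg, rider.bike_mass_kg, rider.c_rr)
            - air_resistance(v, wind_m_per_s, k_fun(x))
            - gravity_force(S, rider.mass_kg, rider.bike_mass_kg)
        )
        return [v, f / rider.total_mass_kg]

    rows: list[tuple] = []
    t = 0.0
    x, v = d0, v0

    def record(tt, xx, vv):
        S = route.gradient_at(min(xx, total - 1e-9))
        alt = route.altitude_at(xx)
        k = rider.drag_factor(alt, density_correction_on)
        vo2 = _sustained_vo2(rider, alt, hypoxia_on)
        p_mech, _ = metabolic_power(vo2, rider)
        f_prop = min(p_mech / max(vv, 1e-3), F_PROP_MAX)
        rows.append(
            (
                tt,
                xx,
                vv,
                alt,
                gravity_force(S, rider.mass_kg, rider.bike_mass_kg) * vv,
                air_resistance(vv, wind_m_per_s, k) * vv,
                rolling_resistance(S, rider.mass_kg, rider.bike_mass_kg, rider.c_rr) * vv,
                f_prop * vv,
                vo2,
            )
        )

    record(t, x, v)
    for i in range(len(grads)):
        if x >= total - 1e-9:
            break
        seg_end = float(edges[i + 1])
        if x >= seg_end - 1e-9:
            continue
        S = float(grads[i])

        def alt_fun(xx):
            return route.altitude_at(xx)

        def k_fun(xx):
            return rider.drag_factor(alt_fun(xx), density_correction_on)

        def reach(tt, y, *args):
            return y[0] - seg_end

        reach.terminal = True
        reach.direction = 1.0

        def stalled(tt, y, *args):
            return y[1] - 0.05

        stalled.terminal = True
        stalled.direction = -1.0

        sol = solve_ivp(
            rhs,
            (t, t + max_duration_s),
            [x, v],
            args=(S, k_fun, alt_fun),
            method="LSODA",
            events=(reach, stalled),
            max_step=5.0,
            rtol=1e-8,
            atol=1e-8,
            dense_output=True,
        )
        if not sol.success:
            raise RuntimeError(f"ride integration failed at t={t:.1f}s: {sol.message}")
        if len(sol.t_events[1]):
            raise RideStallError(
                f"rider stalled at distance {sol.y_events[1][0][0]:.0f} m (gradient {S:.3f}); "
                "propulsive power insufficient for the climb"
            )
        if not len(sol.t_events[0]):
            raise RuntimeError("ride exceeded the maximum simulated duration")
        t_end = float(sol.t_events[0][0])
        for ts in np.arange(math.floor(t / sample_dt_s + 1) * sample_dt_s, t_end, sample_dt_s):
            xx, vv = sol.sol(ts)
            record(float(ts), float(xx), float(vv))
        x, v = float(sol.y_events[0][0][0]), float(sol.y_events[0][0][1])
        t = t_end
    record(t, x, v)

    series = pd.DataFrame(
        rows,
        columns=[
            "t_s",
            "distance_m",
            "speed_m_per_s",
            "altitude_m",
            "P_gravity_W",
            "P_air_W",
            "P_rolling_W",
            "P_mech_W",
            "vo2_l_per_min",
        ],
    )
    return RideResult(finish_time_s=t, series=series)
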