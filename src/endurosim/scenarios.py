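"""Named experiments coupling the cycling and whole-body heat engines.

A scenario describes an environment, a workload source (a route for time
trials, a constant ergometer power, or nothing for passive exposure) and a
rider.  For a time trial the mechanics are integrated first — propulsion
does not depend on temperature — and the resulting speed and oxygen-uptake
profiles then drive the body model: riding speed adds to the air velocity
over the skin, and the part of the metabolic rate not converted to
mechanical work is deposited as heat in the working muscle (85 % in the
legs, 15 % in the trunk).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from endurosim.body import (
    N_TISSUE,
    BRAIN,
    BodyModel,
    BodyState,
    BodyTrajectory,
    Environment,
    load_default_model,
    node_index,
)
from endurosim.cycling import RiderParams, RideResult, metabolic_power, simulate_ride
from endurosim.routes import RouteProfile

__all__ = [
    "Scenario",
    "ScenarioResult",
    "time_trial_scenario",
    "ergometer_scenario",
    "heat_chamber_scenario",
    "run_scenario",
    "invert_for_vo2max",
    "sensitivity_report",
]

LEG_MUSCLE = node_index("legs", "muscle")
TRUNK_MUSCLE = node_index("trunk", "muscle")
#: fraction of exercise heat deposited in the leg muscles during cycling
LEG_FRACTION = 0.85


@dataclass(frozen=True)
class Scenario:
    """Declarative description of one simulated experiment."""

    kind: str  # time_trial | ergometer | heat_chamber | thermoneutral
    rider: RiderParams = field(default_factory=RiderParams)
    environment: Environment = field(default_factory=Environment)
    route: RouteProfile | None = None
    workload_W: float = 0.0
    duration_s: float = 3600.0
    hypoxia_on: bool = False
    density_correction_on: bool = True
    step_environment: Environment | None = None  # for heat_chamber steps
    couple_air_velocity: bool = True

    def __post_init__(self) -> None:
        kinds = ("time_trial", "ergometer", "heat_chamber", "thermoneutral")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.kind == "time_trial" and self.route is None:
            raise ValueError("a time trial needs a route")
        if self.kind != "time_trial" and self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.kind != "time_trial" and self.route is not None:
            raise ValueError("exactly one workload source: route is for time trials")


@dataclass
class ScenarioResult:
    scenario: Scenario
    body: BodyTrajectory
    ride: RideResult | None = None

    @property
    def finish_time_s(self) -> float | None:
        return self.ride.finish_time_s if self.ride is not None else None

    def brain_C(self) -> np.ndarray:
        return self.body.states[:, BRAIN]

    def leg_muscle_C(self) -> np.ndarray:
        return self.body.states[:, LEG_MUSCLE]

    def energy_audit(self) -> dict:
        """Metabolic energy = mechanical work + heat stored + heat lost."""
        ledger = self.body.ledger()
        work_J = 0.0
        if self.ride is not None:
            s = self.ride.series
            work_J = float(np.trapezoid(s["P_mech_W"], s["t_s"]))
        elif self.scenario.kind == "ergometer":
            work_J = self.scenario.workload_W * self.scenario.duration_s
        metabolic_J = ledger["production_J"] + work_J
        residual = metabolic_J - work_J - ledger["storage_J"] - ledger["loss_J"]
        return {
            "metabolic_J": metabolic_J,
            "work_J": work_J,
            "stored_J": ledger["storage_J"],
            "dissipated_J": ledger["loss_J"],
            "relative_residual": residual / metabolic_J if metabolic_J else 0.0,
        }


def time_trial_scenario(
    route: RouteProfile,
    rider: RiderParams,
    environment: Environment | None = None,
    hypoxia_on: bool = False,
    density_correction_on: bool = True,
) -> Scenario:
    """The mountain time-trial defaults: 25 degC, still air, 40 % humidity."""
    env = environment or Environment(25.0, 25.0, 0.40, 0.0)
    return Scenario(
        kind="time_trial",
        rider=rider,
        environment=env,
        route=route,
        hypoxia_on=hypoxia_on,
        density_correction_on=density_correction_on,
    )


def ergometer_scenario(
    workload_W: float = 174.0,
    duration_s: float = 45 * 60.0,
    rider: RiderParams | None = None,
    environment: Environment | None = None,
) -> Scenario:
    """Constant-power indoor cycling; default 20 degC with light fan airflow."""
    return Scenario(
        kind="ergometer",
        rider=rider or RiderParams(mass_kg=74.0, height_m=1.72),
        environment=environment or Environment(20.0, 20.0, 0.40, 1.0),
        workload_W=workload_W,
        duration_s=duration_s,
        couple_air_velocity=False,
    )


def heat_chamber_scenario(
    air_C: float = 48.0,
    duration_s: float = 2 * 3600.0,
    rider: RiderParams | None = None,
    start_env: Environment | None = None,
) -> Scenario:
    """Resting exposure to a step change of air and wall temperature."""
    start = start_env or Environment(30.0, 30.0, 0.30, 0.1)
    return Scenario(
        kind="heat_chamber",
        rider=rider or RiderParams(mass_kg=74.0, height_m=1.72),
        environment=start,
        step_environment=replace(start, air_temperature_C=air_C, wall_temperature_C=air_C),
        duration_s=duration_s,
        couple_air_velocity=False,
    )


def _exercise_load(total_metabolic_W: float, mechanical_W: float, basal_W: float):
    """Split a metabolic rate into per-node heat and metabolism vectors."""
    extra_met = max(total_metabolic_W - basal_W, 0.0)
    extra_heat = max(extra_met - mechanical_W, 0.0)
    heat = np.zeros(N_TISSUE)
    met = np.zeros(N_TISSUE)
    heat[LEG_MUSCLE] = LEG_FRACTION * extra_heat
    heat[TRUNK_MUSCLE] = (1.0 - LEG_FRACTION) * extra_heat
    met[LEG_MUSCLE] = LEG_FRACTION * extra_met
    met[TRUNK_MUSCLE] = (1.0 - LEG_FRACTION) * extra_met
    return heat, met


def run_scenario(s: Scenario, body_model: BodyModel | None = None,
                 sample_dt_s: float = 5.0) -> ScenarioResult:
    """Run one scenario; returns the coupled body (and ride) trajectories.

    The body model is built for the scenario's rider unless an explicit
    model is supplied; integration starts from the thermoneutral reference
    state of that model.
    """
    model = body_model or load_default_model(mass_kg=s.rider.mass_kg, height_m=s.rider.height_m)
    state0 = BodyState(model.set_points.copy())
    basal_W = float(model.params.QB_W.sum())

    if s.kind == "time_trial":
        ride = simulate_ride(
            s.route,
            s.rider,
            wind_m_per_s=s.environment.air_velocity_m_per_s,
            hypoxia_on=s.hypoxia_on,
            density_correction_on=s.density_correction_on,
        )
        t_arr = ride.series["t_s"].to_numpy()
        speed = ride.series["speed_m_per_s"].to_numpy()
        vo2 = ride.series["vo2_l_per_min"].to_numpy()

        def env_fun(t):
            v = float(np.interp(t, t_arr, speed)) if s.couple_air_velocity else 0.0
            return replace(s.environment, air_velocity_m_per_s=s.environment.air_velocity_m_per_s + v)

        def load_fun(t):
            mech, total = metabolic_power(float(np.interp(t, t_arr, vo2)), s.rider)
            return _exercise_load(total, mech, basal_W)

        body = model.integrate(state0, ride.finish_time_s, env_fun, load_fun, sample_dt_s=sample_dt_s)
        return ScenarioResult(s, body, ride)

    if s.kind == "ergometer":
        # oxygen cost of the workload from the delta efficiency + resting uptake
        extra_met = s.workload_W / s.rider.delta_efficiency
        total_met = basal_W + extra_met
        heat, met = _exercise_load(total_met, s.workload_W, basal_W)
        body = model.integrate(state0, s.duration_s, s.environment,
                               lambda t: (heat, met), sample_dt_s=sample_dt_s)
        return ScenarioResult(s, body)

    if s.kind == "heat_chamber":
        step = s.step_environment or s.environment

        def env_fun(t):
            return step if t > 0 else s.environment

        body = model.integrate(state0, s.duration_s, env_fun, sample_dt_s=sample_dt_s)
        return ScenarioResult(s, body)

    # thermoneutral
    body = model.integrate(state0, s.duration_s, model.thermoneutral, sample_dt_s=sample_dt_s)
    return ScenarioResult(s, body)


def invert_for_vo2max(
    target_time_s: float,
    sustained_fraction: float,
    hypoxia_on: bool,
    route: RouteProfile,
    rider_template: RiderParams,
    bracket: tuple[float, float] = (3.0, 9.0),
    tol_s: float = 0.5,
) -> float:
    """Sea-level VO2max whose simulated finish time equals the target.

    Finish time decreases strictly with VO2max, so bisection on the bracket
    has a unique root; iteration stops when the simulated time is within
    ``tol_s`` of the target.
    """

    def finish(vo2max: float) -> float:
        rider = rider_template.with_(vo2max_sealevel=vo2max, brain_push=sustained_fraction)
        return simulate_ride(route, rider, hypoxia_on=hypoxia_on).finish_time_s

    lo, hi = bracket
    f_lo, f_hi = finish(lo), finish(hi)
    if not (f_hi <= target_time_s <= f_lo):
        raise ValueError(
            f"target time {target_time_s:.0f}s outside the bracket's range "
            f"[{f_hi:.0f}, {f_lo:.0f}]s; widen the VO2max bracket"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f_mid = finish(mid)
        if abs(f_mid - target_time_s) <= tol_s:
            return mid
        if f_mid > target_time_s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sensitivity_report(
    route: RouteProfile,
    rider: RiderParams,
    deltas: dict[str, dict] | None = None,
    hypoxia_on: bool = False,
    density_correction_on: bool = True,
) -> pd.DataFrame:
    """Finish-time changes for parameter perturbations, one ride each.

    ``deltas`` maps a label to keyword overrides of :class:`RiderParams`
    (e.g. ``{"heavier": {"mass_kg": 74.4}}``).  The default report contains
    the added-mass and added-height experiments.
    """
    if deltas is None:
        deltas = {
            "+2.4 kg total mass": {"mass_kg": rider.mass_kg + 2.4},
            "+5 cm height": {"height_m": rider.height_m + 0.05},
        }
    base = simulate_ride(route, rider, hypoxia_on=hypoxia_on,
                         density_correction_on=density_correction_on).finish_time_s
    rows = [("baseline", base, 0.0)]
    for label, overrides in deltas.items():
        t = simulate_ride(route, rider.with_(**overrides), hypoxia_on=hypoxia_on,
                          density_correction_on=density_correction_on).finish_time_s
        rows.append((label, t, t - base))
    return pd.DataFrame(rows, columns=["perturbation", "finish_time_s", "delta_s"])
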