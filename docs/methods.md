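# Methods

This note documents the models implemented in `endurosim`, the provenance
and meaning of their parameters, the numerical choices, and what the tests
do and do not demonstrate.

## 1. Cycling mechanics and aerobic power

The rider–bicycle system is a point mass on a road of piecewise-constant
gradient `S` (vertical/horizontal). The equation of motion is

    (M + M_b) dv/dt = F_prop − R_r − R_a − F_g

with

* rolling resistance `R_r = C_Rr (M + M_b) g cosθ`, `θ = arctan S`;
* aerodynamic drag `R_a = k (v + v_w)²`, head wind positive; a tail wind
  faster than the ground speed is clamped to zero drag rather than
  modelled as propulsion (the time-trial scenarios have no wind);
* gravity `F_g = (M + M_b) g sinθ`, negative on descents;
* propulsion `F_prop = P_mech / v`, capped at 500 N to remove the
  standing-start singularity; rides start at 1 m/s.

Mechanical power comes from the suprabasal oxygen uptake:
`P_mech = (V̇O₂ − V̇O₂rest) · e_O₂ · Δefficiency` with the incremental
efficiency Δefficiency = 0.231 measured on an ergometer and an energy
equivalent e_O₂ = 20.9 kJ/l (heavy exercise, RQ near 1). The sustained
uptake is `brain_push × V̇O₂max`, where the brain-push factor is the
fraction of maximal uptake the athlete voluntarily sustains.

Altitude enters twice, through an isothermal barometric model
`p(h)/p(0) = exp(−h/8434 m)`:

* the drag factor `k = ½ ρ(h) C_dA` falls with air density;
* the hypoxia factor on sustainable uptake is
  `1 − (13/24) · (1 − p_O₂(h)/p_O₂(0))` — trained endurance athletes lose
  about 13 % of maximal uptake per 24 % drop in inspired oxygen partial
  pressure. It is applied at the *current* altitude, so uptake falls
  progressively during a climb (≈0.96 at the 720 m start, ≈0.89 at the
  1850 m summit).

Defaults: rider 72 kg / 1.79 m, bicycle 8 kg, `C_Rr = 0.003`,
drag area `C_dA = 0.32 m²`, resting uptake 0.3 l/min. The exact drag and
rolling constants used in the original study are not published; these are
the standard magnitudes for an elite climber in the drops, and they are
calibration inputs, not ground truth — which is why finish-time
reproduction is checked at ±4 %. Body-size experiments rescale the drag
area by the Du Bois body-surface-area ratio
`BSA ∝ M^0.425 H^0.725` relative to the 72 kg / 1.79 m reference.

Numerics: the gradient is piecewise constant, so the ODE is integrated
segment by segment (LSODA, `rtol 1e-8`, max step 5 s) with an exact event
at each breakpoint; this reproduces the transient gravity-power spikes
when the rider enters a steeper kilometre at speed. The trajectory is
sampled at 1 s.

### The reconstructed Alpe d'Huez profile

The route fixture is pinned by the published constraints: 15.5 km long,
720 m → 1850 m (total climb exactly 1130 m), flat first 1.5 km, gradients
known at 1 km resolution, 8–11 % over at least three quarters of the
distance. Within those constraints the per-kilometre verticals are a fixed
deterministic list (55, 92, 90, 89, 88, 87, 86, 85, 84, 84, 83, 82, 80,
45 m): a gentle ramp into the climb, steepest just after it starts, easing
through the final village kilometre. Twelve of the fourteen climbing
kilometres lie in the 8–11 % band.

## 2. The 25-node whole-body heat model

The controlled system lumps the body into head, trunk, arms, hands, legs
and feet, each with core, muscle, fat and skin layers; central blood is
the 25th node. Node `N` obeys

    C_N dT_N/dt = Q_N − BF_N·C_blood·(T_N − T_blood) − TC_N·(T_N − T_{N+1}) − L_N

where `Q_N` is basal plus exercise plus shivering heat, the second term is
perfusion exchange (blood equilibrates with tissue before the capillaries,
so the venous return leaves at tissue temperature and the exchange is
exactly conservative), the third is conduction to the next-outer layer,
and `L_N` collects environmental losses (skin nodes) and respiratory loss
(trunk core, a fixed 8 % of total metabolic rate).

Skin exchange per node: linearized radiation (4.7 W/m²K to the walls),
forced convection `h_c = max(3.1, 8.6 √v) W/m²K` (the classical
square-root-of-velocity law with a still-air floor; riding speed feeds
`v`), and evaporation capped by the vapour-pressure gradient
`E_max = 16.5·h_c·A·(P_sat(T_skin) − RH·P_sat(T_air))` with a Magnus-type
saturation curve and a basal skin diffusion of 6 % of `E_max`. Latent heat
2430 J/g; cumulative sweat mass is integrated alongside the temperatures.

The controlling system senses the brain (head core) and the area-weighted
mean skin temperature. Effector signals are clamped linear forms of the
two errors — sweating (372 W/K brain + 33.6 W/K skin), vasodilation,
vasoconstriction (driven mainly by the *core* cold error; a skin-dominated
constrictor would fight exercise vasodilation and trap heat), and
shivering as a product of cold-brain and cold-skin errors (24.4 W/K²).
Sweat and skin blood flow carry a local `2^(ΔT/10)` skin-temperature
factor. Muscle blood flow scales with local metabolic rate
(2.8·10⁻⁴ l/s per W, i.e. ≈1 l/min of perfusion per 3.5 kJ/min of local
metabolism, matching the normal exercise cardiac-output response).

**Parameter provenance.** The node masses, capacities, conductances,
basal heat productions and basal perfusions follow the classical
multi-segment parametrization in structure and magnitude (printed anchors:
3 kg head core representing brain and skull, 0.4 kg head muscle, ~10 kg
leg muscle; ~74 kg, 1.89 m², ~83 W basal in total), with conductances and
basal skin perfusion calibrated so that the resting thermoneutral steady
state reproduces the validation baselines (brain ≈37.3 °C, mean skin
≈33.5 °C at 30 °C). The table ships as an editable TSV; body mass and
height rescale masses, capacities and flows by mass and areas and
conductances by the Du Bois surface-area ratio.

**Reference temperatures are not free constants.** They are *defined* as
the resting steady state of the passive system (all effector signals
forced to zero) in the thermoneutral environment (30 °C air and walls,
30 % RH, still air), solved once per model. This guarantees that all
effector signals vanish there, that a thermoneutral simulation is
stationary, and that controller continuity holds at the reference point.
Scenario simulations start from this reference state.

Numerics: LSODA with the controller evaluated inside the right-hand side
(no operator splitting), max step 1 s, `rtol 1e-7`. Cumulative production
and loss are integrated as extra states, so the energy ledger
(production − storage − loss) is available for every run; it closes to
well under 1 %. Temperatures outside 25–45 °C raise a diagnostic warning,
never silent clipping; zero masses or capacities are rejected at load.

Validation transients reproduced by the shipped parametrization: a
30 → 48 °C heat-chamber step over 2 h raises mean skin temperature from
33.6 to 36.4 °C (published model response 33.4 → 36.3 °C); 45 min of
174 W ergometer cycling at 20 °C raises brain temperature from 37.26 to
≈38.1 °C (published 37.28 → 37.96 °C). The chamber humidity (30 %) and
the ergometer fan airflow (1 m/s) are not printed in the source
descriptions and are configurable defaults chosen at the centre of the
plausible range.

## 3. Scenario coupling

For a time trial the mechanics are integrated first — propulsion does not
depend on temperature — and the resulting speed and uptake profiles drive
the body model: air velocity over the skin is ambient wind plus riding
speed, and the heat load is total metabolic rate minus mechanical work,
deposited 85 % in the leg muscles and 15 % in the trunk muscle (cycling
recruits mainly the legs; the split is a modelling decision). The coupled
energy audit (metabolic = work + stored + dissipated) closes to <1 %.

`invert_for_vo2max` exploits the strict monotonicity of finish time in
VO₂max: bisection on [3, 9] l/min, stopping when the simulated time is
within 0.5 s of the target. `sensitivity_report` reruns the ride with
perturbed rider parameters and reports signed time differences.

## 4. Creatine-kinase kinetics

Ten states: ATP, ADP, PCr, Cr and Pi in the cytosol (93.75 % of cell
water) and the mitochondrial intermembrane space (6.25 %). Processes:

* **OxPhos** (IMS): `J = V_max · ADP/(ADP+K_ADP) · Pi/(Pi+K_Pi)`,
  `V_max = 1600 µM/s`, `K_ADP = 40 µM`, `K_Pi = 800 µM`.
* **CK**, both isoforms: reversible random bi-bi rate law, positive toward
  ATP production, with the reverse maximal rate tied by the Haldane
  relation to the apparent equilibrium constant
  `K'eq = 1.66·10⁹ M⁻¹ · [H⁺]` — the rate vanishes identically at
  equilibrium, and pH enters through the workload-dependent [H⁺]
  (0.89·10⁻⁷ M at rest to 1.20·10⁻⁷ M at 75 % V̇O₂max).
* **MOM permeation**: passive, `PS·(C_cyt − C_ims)`, with adenine
  nucleotides restricted (6 s⁻¹) and the small metabolites faster
  (50 s⁻¹). The restriction is load-bearing: with a tight MOM the IMS sees
  pulses only through the PCr/Cr shuttle, which is what lets CK buffer the
  mitochondrial ATP production.
* **Forcing**: a triangular ATP→ADP+Pi pulse in the cytosol, active one
  third of each pedal stroke at 90 r.p.m., cycle-average equal to the
  prescribed `J_avg` exactly and peak `2·J_avg/duty` (= 6× average).

All fluxes are referenced to total cell water; compartment concentrations
are divided by their volume fractions, which makes the creatine, adenine
and total-phosphate pools exactly conserved (verified to 10⁻¹⁴).

The 22 parameters (5 kinetic constants per CK isoform, 3 for OxPhos, 5
MOM permeabilities, 2 volume fractions, 2 pool totals) ship as a prior
table. CK kinetic constants come from the published cardiac Mi-CK and
skeletal MM-CK kinetics and carry tight priors (20–30 % log-sd); OxPhos
and MOM parameters have no reported measurement errors and carry weak
default priors (100 % log-sd). The CK maximal rates (60 000 / 10 000
µM/s numerator scale) reflect the very high total CK activity of skeletal
muscle; the denominator of the rate law reduces the effective capacity
roughly tenfold, and the effective forward capacity must exceed the
3768 µM/s peak demand for buffering to work at all.

**Workload→flux conversion.** Whole-body uptake at a fraction of V̇O₂max
is converted to a cell-water ATP flux via P/O = 6 and 10 kg of active leg
muscle (0.67 l cell water per kg). The single attribution constant (the
share of whole-body uptake assigned to that muscle, 0.575) is calibrated
once so that 40 % of a 4.1 l/min V̇O₂max gives 628 µM/s; the 75 % value
(1177.5 ≈ the published 1175 µM/s) then follows from linearity with no
further freedom.

**Steady-cycle analysis.** The slow pool redistribution (hundreds of
seconds) is integrated under cycle-averaged forcing; the pulsatile forcing
is then applied for the final 200 cycles of the 600 s horizon, the metrics
are computed on the last full cycle, and the cycle-to-cycle periodicity
defect is reported (>1 % raises a diagnostic; converged runs reach ~10⁻⁶,
and the cycle-averaged synthesis equals `J_avg` to better than 0.1 %).
With the default parameters, blocking CK to 2 % activity raises the ATP
synthesis oscillation amplitude from ≈104 to ≈908 µM/s (8.7-fold) at the
40 %-V̇O₂max workload, and the steady-state PCr falls (with Cr rising and
ATP nearly constant) as workload increases.

**Fitting.** The cost is Σ(residual/σ)² on steady-state ATP, PCr, Cr at
≥2 workloads plus Gaussian priors on the log-parameters; Nelder–Mead in
log space with seeded restarts (seed 1234). The steady state for each
trial parameter vector is found by a root solve with the three pool
constraints replacing the redundant rate equations, warm-started from the
previous iterate. Glycolytic ATP production and pH dynamics are outside
scope; [H⁺] is an input per workload.

The synthetic biopsy generator produces exactly the structure of
incremental-exercise muscle data (ATP/PCr/Cr per workload, mmol/kg dry
weight via the 3 l/kg water content) from the model's own steady states
with multiplicative Gaussian noise; passing recovery tests therefore
demonstrates identifiability under the model's own assumptions, not
robustness to real-world model error (no glycolysis, constant pH, no
measurement bias).

## 5. Brain flux-balance analysis

A metabolic steady state obeys one Kirchhoff balance per metabolite
(production = consumption); irreversible reactions are constrained to
v ≥ 0, measured uptakes fix the exchange fluxes, and the flux distribution
is found by maximizing the mitochondrial ATP synthase flux with an exact
LP solver (HiGHS). Alternative optima are exposed through flux-variability
ranges rather than hidden. Uniform hit-and-run sampling in the null-space
coordinates explores the feasible polytope (every sample satisfies the
balances to 10⁻⁸; unbounded directions are clipped at a documented box).

The packaged network (~65 reactions, BiGG-style identifiers, TSV) covers
glycolysis, the pentose phosphate pathway, the TCA cycle, oxidative
phosphorylation, the malate–aspartate and glycerol-3-phosphate shuttles,
the citrate/malate antiporter with ATP-citrate lyase feeding lumped
palmitate synthesis (8 acetyl-CoA + 14 NADPH + 7 ATP per palmitate),
alanine synthesis and glutamate/GABA cycling. Protons and water are not
balanced; C, N and P are, and an elemental checker validates every
internal reaction at load (exchanges exempt, missing formulas reported as
unchecked).

The electron-transport chain is made explicit with a proton-motive
pseudo-metabolite: 10 charges per matrix NADH, 6 per FADH₂, and an ATP
synthase consuming 4.8276 charges per ATP. The per-NADH/per-FADH₂ pumping
stoichiometries are the textbook values; the synthase coefficient is the
single calibrated constant (an effective H⁺/ATP including transport
costs), set so that full oxidation of 0.4 mmol/min glucose — 23.2 ATP per
glucose — yields the 9.28 mmol/min rest optimum. It is an explicit
editable number in the reaction TSV.

Case studies (whole-organ mmol/min): at **rest**, glucose uptake 0.4 with
oxygen fixed at the ratio-6 stoichiometry (2.4) gives a maximal synthase
flux of 9.28 and zero pentose-phosphate flux. During **exercise**, fixed
uptakes of 0.8 glucose + 0.53 lactate + 3.2 oxygen force 0.139 mmol/min of
palmitate synthesis — the electron balance (25.6 e⁻-pair equivalents in,
6.4 to oxygen, 46 per palmitate) determines this almost independently of
pathway details — with the PPP activated to supply the NADPH and carbon
closing exactly (in = CO₂ + 16×palmitate). The objective counts the
synthase flux alone, not substrate-level phosphorylation; passing a
different objective reaction id to `brain_scenario` exposes the
alternative reading.

## 6. Known limitations

* The thermal parameter table is a calibrated reconstruction, not the
  original data set; individual-specific parametrization (imaging-based
  volumes, measured drag) is out of scope.
* No oxygen-transport cascade: hypoxia acts directly on sustainable
  uptake, so blood-doping-style interventions cannot be represented.
* No arterial/venous counter-current heat exchange; no drafting,
  braking, cornering or pacing strategy; no fluid-intake dynamics beyond
  cumulative sweat mass.
* The CK model omits glycolytic ATP and pH dynamics; the CK engine and
  the whole-body loop run offline from each other (the workload→flux
  conversion is the only bridge).
* The brain network excludes glycogen turnover and ketone bodies; the
  nitrogen-balance reactions (alanine, glutamate/GABA) are present but
  their exchanges default to zero flux.
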