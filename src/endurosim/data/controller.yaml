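# Thermoregulatory controller parametrization and environmental exchange
# coefficients for the 25-node body model.  Gains follow the magnitudes of
# the classical multi-node controller (sweating driven mainly by the brain
# error, shivering by the product of cold brain and cold skin errors);
# everything here is an editable default.
gains:
  sweat_brain_W_per_K: 372.0        # evaporative demand per K warm brain error
  sweat_skin_W_per_K: 33.6          # per K warm mean-skin error
  sweat_product_W_per_K2: 0.0
  dilation_brain_per_K: 32.5        # skin-blood-flow dilation signal (dimensionless)
  dilation_skin_per_K: 2.1
  constrict_brain_per_K: 35.0
  constrict_skin_per_K: 1.5
  shiver_product_W_per_K2: 24.4     # cold-brain x cold-skin product term
  local_sweat_q10: 10.0             # sweat x 2^(local skin error / q10)
blood:
  volume_l: 2.5
  heat_capacity_J_per_l_K: 3850.0
environment_exchange:
  h_radiative_W_per_m2K: 4.7
  h_convective_still_W_per_m2K: 3.1
  h_convective_wind_W_per_m2K_per_sqrt_mps: 8.6   # h_c = max(still, coef * sqrt(v))
  lewis_ratio_K_per_kPa: 16.5                     # h_e = LR * h_c
  basal_skin_diffusion_fraction: 0.06             # fraction of max evaporation
  latent_heat_J_per_g: 2430.0
  respiratory_fraction: 0.08                      # of total metabolic rate, trunk core
distribution:
  # per-segment fractions: head, trunk, arms, hands, legs, feet
  skin_sensor_weight: [0.07, 0.36, 0.14, 0.05, 0.32, 0.06]
  sweat_fraction:     [0.07, 0.36, 0.14, 0.05, 0.32, 0.06]
  dilation_fraction:  [0.10, 0.30, 0.14, 0.08, 0.30, 0.08]
  constrict_fraction: [0.02, 0.15, 0.12, 0.28, 0.15, 0.28]
  shiver_fraction:    [0.02, 0.85, 0.05, 0.0, 0.08, 0.0]   # to muscle nodes
muscle_blood_flow_l_per_s_per_W: 0.00028   # perfusion per W of extra local metabolism
reference:
  total_mass_kg: 74.0
  total_area_m2: 1.89
  height_m: 1.72
  thermoneutral:
    air_temperature_C: 30.0
    wall_temperature_C: 30.0
    relative_humidity: 0.30
    air_velocity_m_per_s: 0.1
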