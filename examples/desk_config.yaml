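# Declarative configuration for `tundraline simulate --config ...`.
# Both sections are optional; omitted keys take the package defaults
# (see tundraline.params for the full schema, units and meanings).

simulator:
  transect_length_km: 50.0
  transect_width_m: 20.0
  stabilization_years: 200
  repeats: 3
  rng_seed: 1
  initial_seed_count: 1000        # desk scale: full-scale value is 100000
  permanent_seeds_per_200km: 1000
  hinterland_rate: 200.0          # desk scale: full-scale value is 20000
  snapshot_interval: 10

lifecycle:
  g_max_cm: 0.06                  # plateau basal-diameter increment, cm/yr
  t_jul_cold: 9.0                 # no growth below this July temperature, °C
  germination_p0: 0.03
  seed_mortality: 0.45
  age_max: 500.0
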