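# Small synthetic fixture: a 15 x 15 km landscape with a handful of fires
# and up to 12 leks, sized so the full pipeline runs in seconds.
seed: 3
averaging: full
out_dir: results/fixture_small
thresholds:
  island_near_m: 50.0
  small_buffer_max_m: 1500.0
  large_buffer_max_m: 6400.0
  radii_m: [400.0, 1200.0, 3000.0]
  cheat_cover_pct: 8.0
  cheat_elevation_m: 2000.0
  lookback_years: 17
  min_survey_years: 6
synthetic:
  landscape:
    extent_m: [15000.0, 15000.0]
    cell_size_m: 30.0
    cheat_cell_size_m: 250.0
    n_fires: 6
    fire_area_km2_range: [2.0, 10.0]
    unburned_fraction_range: [0.02, 0.78]
    island_fraction_beta: [1.2, 10.0]
    elevation_range_m: [1120.0, 2750.0]
    years: [1984, 2014]
    rng_seed: 0
  n_leks_per_category: 3
  count_years: [1984, 2017]
  survey_prob: 0.8
  base_log_count: 3.5
  fire_year_is_post: true
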