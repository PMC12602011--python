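input_csv: null
simulate:
  taxa:
  - taxon_id: smelt_like
    group: fish
    drift: -0.12
    proc_var: 0.03
    peak_months:
    - 2
    - 3
    - 4
    peak_concentration: 0.85
    detection_prob: 0.9
    base_log_abundance: 5.5
  - taxon_id: anchovy_like
    group: fish
    drift: 0.05
    proc_var: 0.2
    peak_months:
    - 6
    - 7
    - 8
    peak_concentration: 0.8
    detection_prob: 0.9
    base_log_abundance: 6.0
  - taxon_id: herring_like
    group: fish
    drift: -0.05
    proc_var: 0.06
    peak_months:
    - 4
    - 5
    - 6
    peak_concentration: 0.8
    detection_prob: 0.9
    base_log_abundance: 5.8
  - taxon_id: copepod_a
    group: zooplankton
    drift: 0.0
    proc_var: 0.05
    peak_months:
    - 3
    - 4
    - 5
    peak_concentration: 0.6
    detection_prob: 0.95
    base_log_abundance: 6.5
  - taxon_id: copepod_b
    group: zooplankton
    drift: -0.02
    proc_var: 0.1
    peak_months:
    - 5
    - 6
    - 7
    peak_concentration: 0.6
    detection_prob: 0.95
    base_log_abundance: 6.5
  - taxon_id: copepod_c
    group: zooplankton
    drift: 0.02
    proc_var: 0.15
    peak_months:
    - 4
    - 5
    - 6
    peak_concentration: 0.6
    detection_prob: 0.95
    base_log_abundance: 6.5
  - taxon_id: copepod_d
    group: zooplankton
    drift: -0.01
    proc_var: 0.08
    peak_months:
    - 6
    - 7
    - 8
    peak_concentration: 0.6
    detection_prob: 0.95
    base_log_abundance: 6.5
  design:
    years:
    - 1995
    - 2023
    regions:
    - Suisun
    - SanPablo
    stations_per_region: 4
    missing_rate: 0.05
    effort_mean: 1.0
start_year: 1995
min_nonzero_fish: 50
min_nonzero_zoop: 234
min_presence: 0.3
coverage_target: 0.8
max_gap: 1
decline_fraction: 0.9
horizons:
- 1.0
- 2.0
- 3.0
- 4.0
- 5.0
- 6.0
- 7.0
- 8.0
- 9.0
- 10.0
bootstrap_B: 1000
q_floor: 1.0e-10
eps: 1.0e-06
seed: 0
out_dir: phenorisk_out
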