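# Full-pipeline demo: two simulated predator groups, quadrat surveys,
# classification, fitting, comparison, bootstrap, abundance and RIP.
output_dir: demo_out
seed: 123
alpha: 0.05
n_boot: 200            # FR-curve confidence bands
n_boot_feeding_rate: 30  # small ensemble for feeding-rate mean +/- SE
n_draws: 100000
feeding_rate_convention: per_day
trial_simulations:
  - attack_coefficient: 0.85
    handling_time: 0.258
    duration: 1.0
    densities: [2, 4, 6, 8, 10, 15, 20, 40, 70]
    replicates_per_density: 25
    predator_label: large_invader
    prey_label: embryo
  - attack_coefficient: 0.616
    handling_time: 0.459
    duration: 1.0
    densities: [2, 4, 6, 8, 10, 15, 20, 40, 70]
    replicates_per_density: 25
    predator_label: intermediate_invader
    prey_label: embryo
quadrat_simulations:
  - mean_density_per_m2: 14.76
    dispersion: 2.0
    n_sites: 24
    group: large_invader
  - mean_density_per_m2: 83.28
    dispersion: 2.0
    n_sites: 24
    group: intermediate_invader
rip_comparisons:
  - [intermediate_invader, large_invader]
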