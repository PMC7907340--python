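# Simulation config for one predator group at the embryo density design.
attack_coefficient: 0.85     # per day
handling_time: 0.258         # days per prey item
duration: 1.0                # days
densities: [2, 4, 6, 8, 10, 15, 20, 40, 70]
replicates_per_density: 25
seed: 101
predator_label: large_invader
prey_label: embryo
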