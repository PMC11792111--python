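# Simulation config for `toxvar simulate --config <file>`.
# Every key is optional; omitted keys use the defaults shown here
# (keys match the fields of toxvar.SimulationConfig).

# Hill truth curves on the link scale (identity for RGR, logit for herbivory)
rgr_curve: {e0: 0.020, emax: 0.005, ec50: 1.0, n: 2.0}
herbivory_curve: {e0: -0.6190, emax: -2.7515, ec50: 1.5, n: 1.5}

selectivity: 0.5921          # feeding weights ~ exp(-selectivity * dose); 0 = none
mu_low: 0.66                 # cage-mean doses, nmol sinigrin / mg fresh weight
mu_high: 1.89
delta: 0.61                  # within-plant dose offset (leaves get mu +/- delta)
n_cages_per_arm: 103         # per mean x variation treatment arm
leaves_per_plant: 7
noise_sd_rgr: 0.019          # per-hour RGR observation SD (identity link)
noise_sd_herbivory: 0.9      # cage herbivory SD on the logit scale
leaf_noise_sd: 0.9           # leaf herbivory SD on the logit scale
dose_ladder: [0.031, 0.0622, 0.1249, 0.2507, 0.5032, 1.0100, 2.0272, 4.0690, 8.1672, 16.1]
ladder_reps: 6               # cages per ladder dose
seed: 0
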