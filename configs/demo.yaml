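# Demonstration pipeline on a simulated three-cluster population.
# The simulation defaults emulate a small, low-diversity pinniped
# population (86 individuals, 26 microsatellite loci, He ~ 0.35).
seed: 1
input:
  simulate:
    seed: 1
clustering:
  k_min: 1
  k_max: 4
  n_replicates: 5
  burn_in: 300
  reps: 1500
spca:
  n_permutations: 2000
ibd:
  n_permutations: 5000
  classes: [25, 50, 100, 200, 400, 800]
inbreeding:
  estimator: ml
  evaluate: false
ne:
  freq_cutoff: 0.02
hwds:
  window_size: 30
  step: 4
  hwe_mc_reps: 5000
output_dir: demo_out
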