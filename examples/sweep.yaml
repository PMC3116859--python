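# b-sweep at moderate diffusion (desk scale); run with:
#   metarep sweep --config examples/sweep.yaml --crossover --out-dir out/
base:
  L: 100
  generations: 10000
  D: 5.0
  p_d: 0.1
  p_m: 0.01
  g: 1.0
  k_min: 2.0
  k_max: 2.5
  E_max: 10.0
  W_e: 20.0
  seed: 0
axis: b
values: [0.4, 0.6, 1.0, 1.4, 1.67, 2.0]
replicates: 5
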