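# single desk-scale run under a strongly convex E1/E2 trade-off; run with:
#   metarep run --config examples/run.yaml --out-dir out/
L: 100
generations: 10000
D: 5.0
b: 0.4
g: 1.0
p_d: 0.1
p_m: 0.01
k_min: 2.0
k_max: 2.5
E_max: 10.0
W_e: 20.0
seed: 0
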