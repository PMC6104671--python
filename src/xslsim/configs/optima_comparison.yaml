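# Naive vs Ebbinghaus comparison at each policy's optimal parameter
# (optimum = argmin of final mean child error at t = 10^4).
policy: {kind: naive, m: 40}
n_words: 10
t_max: 10000
n_runs: 100
seed: 0
sweep:
  values: [5, 10, 15, 20, 30, 50, 80, 100, 150]
compare_with:
  policy: {kind: ebbinghaus, d0_inv: 0.01, d1: 0.01}
  values: [10, 30, 100, 300, 1000]
exact_n_runs: 100
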