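# Cross-sections of the naive learning curves: final measures as a
# function of m at several developmental time points t_f.  Reduced to
# 200 runs by default; --exact-runs restores the 1000-run ensembles.
policy: {kind: naive, m: 40}
n_words: 10
t_max: 10000
n_runs: 200
seed: 0
sweep:
  values: [5, 8, 11, 14, 17, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100, 120, 150]
  t_f: [100, 1000, 10000]
exact_n_runs: 1000
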