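# Naive-forgetting learning curves: 10-word tri-diagonal lexicon, no
# between-adult diversity, averages over 100 runs, horizon 10^4.
policy: {kind: naive, m: 40}
n_words: 10
t_max: 10000
n_runs: 100
seed: 0
sweep:
  values: [5, 10, 15, 20, 30, 50, 80, 100, 150]
exact_n_runs: 100
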