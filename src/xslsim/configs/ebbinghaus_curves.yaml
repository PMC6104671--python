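# Ebbinghaus-forgetting learning curves over 1/d1, initial forgetting
# rate 1/d0 = 0.01; 10-word tri-diagonal lexicon, 100 runs, horizon 10^4.
policy: {kind: ebbinghaus, d0_inv: 0.01, d1: 0.01}
n_words: 10
t_max: 10000
n_runs: 100
seed: 0
sweep:
  values: [10, 30, 100, 300, 1000]
exact_n_runs: 100
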