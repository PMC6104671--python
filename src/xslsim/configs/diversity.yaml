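# Between-speaker diversity: adult idiolects sampled from the
# tri-diagonal auxiliary lexicon with s samples per referent (lower s =
# more diversity; null = the no-diversity control), scored against the
# group lexicon after 10^4 iterations.  Uniform referent distribution,
# 100 runs.
policy: {kind: naive, m: 40}
n_words: 10
t_max: 10000
n_runs: 100
seed: 0
diversity: {n_adults: 5, samples: 5}
sweep:
  values: [10, 20, 40, 60, 90, 150]
s_values: [1, 5, 10, 100, null]
exact_n_runs: 100
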