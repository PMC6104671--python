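# xslsim — cross-situational word learning with forgetting

`xslsim` simulates a child acquiring a lexicon from ambiguous adult
speech, and asks a counter-intuitive question: **how much forgetting
helps word learning?**  It is aimed at computational cognitive modellers
studying language acquisition, memory, and their interaction.

## The model

An adult lexicon is a row-stochastic matrix `A(r, w) = P(w | r)`: the
probability of uttering word `w` when talking about referent `r`.  Rows
with several non-zero entries encode within-speaker variance; the
default lexicon is a 10×10 tri-diagonal matrix (0.25 / 0.5 / 0.25 bands,
0.75 corners).  Each iteration — one adult–child interaction, so time
equals corpus size — works as follows:

1. pick an adult (uniformly, when the population has several);
2. draw two distinct referents uniformly: a target `R1` and an
   incidental distractor `R2` (referential ambiguity);
3. the adult utters a word `W ~ A(R1, ·)`;
4. the child records one token in both slots `c(R1, W)` and `c(R2, W)`;
5. a forgetting regime removes tokens.

The child's probabilistic lexicon is `C(r, w) = c(r, w) / n(r)`, with
`n(r)` the surviving token count for referent `r`.  Two forgetting
mechanisms are implemented:

* **naive** — every `m` iterations one token is deleted from every
  non-zero slot (`m` is the memory parameter);
* **Ebbinghaus** — every timestep each token is deleted independently
  with probability `d(r, w) = (1/d0) · exp(−(N_rw/N)/d1)`, where `N_rw`
  counts every token ever added to the slot and `N = Σ N_rw`: the decay
  rate of an association falls exponentially with its relative
  repetition count, dropping to `e⁻¹` (≈36%) of the initial rate `1/d0`
  once the slot accounts for a fraction `d1` of all experience.

Progress is scored against the group lexicon `G` (mean of the adults')
with three complementary per-referent measures, averaged over referents:

* child error `E(r) = (1/W0) Σ_{w: G(r,w)=0} C(r, w)` — mass on words
  never used for `r`;
* chi-squared `χ²(r) = Σ_{w: G(r,w)>0} (C−G)²/G`;
* Pearson correlation `P(r)` between `C(r, ·)` and `G(r, ·)`.

Forgetting acts as a high-pass filter: spurious (distractor-born)
associations collect tokens ~5× more slowly than intended ones, so a
loss rate between the two arrival rates deletes the noise and keeps the
signal.  The result is a U-shaped error curve in the memory parameter —
a "Goldilocks" zone of forgetting — with three long-time regimes for the
naive mechanism: a low plateau (`m < M0 ≈ 18`, everything is wiped), a
decaying band (`M0 < m < M1`, errors fall like a power law), and a high
plateau (`m > M1 ≈ 90`, spurious associations freeze in; with no
forgetting at all the error converges to exactly 1/18 for the
tri-diagonal lexicon).

Between-speaker variance is modelled by sampling each adult's idiolect
(`s` word draws per referent) from an auxiliary lexicon: small `s` means
high diversity.

## Worked example

```python
from xslsim import (ExperimentConfig, NaiveForgetting,
                    sweep_memory_parameter, final_measures)

base = ExperimentConfig(policy=NaiveForgetting(40), t_max=10_000,
                        n_runs=100, seed=1)
sweep = sweep_memory_parameter(base, [8, 18, 40, 90, 150])
cross = final_measures(sweep)
print(cross[["param_value", "E_mean", "chi2_mean", "pearson_mean"]]
      .round(4).to_string(index=False))
```

prints

```
 param_value  E_mean  chi2_mean  pearson_mean
         8.0  0.0439     0.9456        0.3560
        18.0  0.0089     0.5963        0.8279
        40.0  0.0012     0.0866        0.9664
        90.0  0.0083     0.0064        0.9979
       150.0  0.0339     0.0626        0.9971
```

Read: after 10⁴ interactions, forgetting every 8 iterations wipes the
signal (high error, low correlation), forgetting every 150 leaves
spurious associations frozen in (error creeping back towards the
no-forgetting plateau of 1/18 ≈ 0.056), and the intermediate `m = 40`
hits the Goldilocks zone — errors down to ~10⁻³ with correlation ≈ 0.97.

The same machinery drives `estimate_regime_boundaries` (classifies each
`m` by the late-time log–log slope of the error and locates `M0`, `M1`),
`compare_optima` (naive vs Ebbinghaus learning curves at each policy's
best parameter) and `diversity_sweep` (optima under between-speaker
variance).

## Command line

```bash
xslsim lexicon --words 10 --kind tridiagonal --out lex.tsv
xslsim run     --config src/xslsim/configs/naive_curves.yaml --out results/run
xslsim sweep   --config src/xslsim/configs/cross_sections.yaml --out results/sweep
xslsim regimes --out results/regimes            # M0/M1 boundary report
xslsim compare --config src/xslsim/configs/optima_comparison.yaml --out results/cmp
xslsim diversity --config src/xslsim/configs/diversity.yaml --out results/div
```

Every command writes a results CSV (17-significant-digit floats; the
same config and seed reproduce it byte for byte) plus a `manifest.json`
with the resolved configuration.  Shipped configs use reduced ensemble
sizes; `--exact-runs` restores the full ones.

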