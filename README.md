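# opvar — ordinal-pattern analysis with magnitude variability

`opvar` characterises univariate digital signals (chaotic-map trajectories,
intracranial EEG exported as numeric series, power-grid frequency
recordings, …) by combining two complementary ordinal-pattern statistics:

* the **Rényi min-entropy** `H∞ = −log₂ maxₐ P(α)` of the ordinal-pattern
  (OP) sequence, a sharper variant of the permutation entropy
  `H = −Σₐ P(α) log₂ P(α)`, which captures how chaotic/unpredictable the
  rank dynamics are; and
* the **magnitude variability** `avgⱼ{⟨log₂ σⱼ⟩}`, where `σⱼ(α)` is the
  standard deviation of the signal magnitudes at component `j` of all
  embedded vectors with OP symbol `α` and
  `⟨log₂ σⱼ⟩ = Σₐ P(α) log₂ σⱼ(α)` — the amplitude information that the
  rank-only OP encoding otherwise discards.

Signals are encoded Bandt–Pompe style with embedding dimension `D` and
delay `τ` over *quasi-non-overlapping* windows (stride `(D−1)τ`, consecutive
windows share exactly one sample), so the whole signal is used with no
redundancy between consecutive patterns. Two signals with nearly identical
`H∞` can differ by an order of magnitude in `avgⱼ{⟨log₂ σⱼ⟩}` (and vice
versa), so the pair separates dynamical regimes — and e.g. sleep–wake
states in EEG — better than entropy alone.

The package also ships the validation apparatus around the statistic:

* simulators for coupled identical logistic maps
  `x_{t+1} = (1−ε)f(x_t) + εf(y_t)`, `f(z) = rz(1−z)`, and the Hénon map
  `x_{t+1} = 1 − ax_t² + y_t`, `y_{t+1} = bx_t`, with transient removal and
  optional additive Gaussian observational noise;
* maximum-Lyapunov-exponent estimators (Benettin tangent-space iteration
  with analytic Jacobians, and a Wolf-style nearest-neighbour divergence
  tracker for measured trajectories);
* a scaling analysis that sweeps `D` and noise strength and fits the
  power-law slope of `avgⱼ{⟨log₂ σⱼ⟩}` versus `log₂(Dτ)`, which
  discriminates deterministic-like from noise-like signals (pure
  observational noise follows a slope near −1/2).

## Worked example

```python
import opvar as ov

# x-coordinate of two weakly coupled logistic maps, the standard setup:
# x1=0.65, y1=0.44, 10^3 transient discarded, 10^6 samples kept
sx, sy = ov.simulate_coupled_logistic(ov.LogisticParams(r=3.8, eps=0.01))

res = ov.summarize(sx, ov.EmbeddingConfig(D=4, tau=1))
print(f"H     = {res.entropy.H:.3f} bits")
print(f"H_inf = {res.entropy.H_inf:.3f} bits")
print(f"avg_j <log2 sigma_j> = {res.variability.avg:.3f}")

lam = ov.mle_wolf((sx, sy))
print(f"MLE   = {lam.mle:.3f} nats/iteration")
```

prints

```
H     = 2.747 bits
H_inf = 2.053 bits
avg_j <log2 sigma_j> = -4.229
MLE   = 0.426 nats/iteration
```

`H∞ ≈ 2.05` bits says the most frequent of the 24 possible `D=4` patterns
appears with probability `2^−2.05 ≈ 0.24`; `avg ≈ −4.23` says the typical
within-pattern magnitude spread is `2^−4.23 ≈ 0.05` in signal units; the
positive Lyapunov exponent confirms the trajectory is chaotic. At
`r=3.6` the same pipeline gives a similar `H∞ ≈ 1.99` but `avg ≈ −5.36` —
an order-of-magnitude smaller within-pattern spread — which is exactly the
kind of dynamical change the entropy alone misses.

The same pipeline is available from the shell:

```bash
opvar simulate logistic --r 3.8 --eps 0.01 -o traj.csv
opvar analyze traj.csv --delimiter , --column 1 --D 4 -o result.json
opvar lyapunov --map henon --a 1.4 --b 0.3
opvar scaling --map henon --a 1.15 --D 3:8 --noise 0,0.1,1 --seed 7
```

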