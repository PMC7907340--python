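# frip — functional responses and Relative Impact Potential

`frip` is a Python package for comparative predator-impact analysis in
invasion ecology. It answers the question ecologists ask when a voracious
invader (here, the amphipod *Dikerogammarus villosus*, the "killer
shrimp") meets vulnerable prey such as amphibian embryos and larvae: **how
much more damage can the invader do than its native analogue
(*Gammarus pulex*), per capita and at realistic field densities?**

The package covers the full analysis chain:

1. **Functional-response (FR) typing.** Logistic regression of the
   proportion of prey consumed against prey density (quasibinomial
   dispersion): a significantly negative first-order term marks a
   hyperbolic **Type II** response; a significant positive first-order
   term superseded by a negative second-order term marks a sigmoid
   **Type III**.
2. **Mechanistic Type II fitting.** Depletion trials (consumed prey are
   not replaced) follow the **Rogers random-predator equation**

   $$N_e = N_0\left(1 - e^{a (N_e h - T)}\right)$$

   solved explicitly with the Lambert W function

   $$N_e = N_0 - \frac{W\!\left(a h N_0\, e^{-a (T - h N_0)}\right)}{a h},$$

   where $a$ is the attack coefficient (day⁻¹), $h$ the handling time
   (days per prey) and $T$ the trial length (days). Parameters are
   estimated by maximum likelihood (binomial likelihood on consumed out
   of offered), giving SEs, Wald $z$ and $p$ per parameter, and the
   maximum feeding rate $1/(Th)$ per experiment or $1/h$ per day.
3. **Group comparison.** Indicator-variable joint fits test differences
   $D_a$, $D_h$ (base − comparator) between predator groups.
4. **Bootstrap uncertainty.** Nonparametric resampling gives 95%
   prediction bands for the FR curve and mean ± SE maximum feeding rates.
5. **Field abundance.** Quadrat counts (0.25 m² frames) and
   literature-derived pseudo-samples are summarised per group and
   compared with a quasi-Poisson GLM (omnibus F, Holm-adjusted pairwise
   Wald tests).
6. **Relative Impact Potential (RIP).** Per-capita effect × abundance,
   invader over native:

   $$\mathrm{RIP} = \frac{FR_A \times N_A}{FR_B \times N_B}$$

   propagated by Monte Carlo (mean/SE-matched lognormal draws), with
   interval summaries and $P(\mathrm{RIP} > 1)$. RIP > 1 predicts
   greater invader impact.

A seeded synthetic-data module simulates both the depletion trials
(renewal-process or model-consistent binomial sampling) and
negative-binomial quadrat surveys, so the entire pipeline runs with no
external data.

## Worked example

```python
import frip

# simulate an embryo-design experiment (densities 2..70, 25 trials each)
cfg = frip.SimulationConfig(
    attack_coefficient=0.85, handling_time=0.258, duration=1.0,
    densities=frip.EMBRYO_DENSITIES, replicates_per_density=25, seed=101,
)
trials = frip.generate_trials(cfg)

print(frip.classify_fr_type(trials).classified_type)   # -> II
res = frip.fit_rogers(trials)
print(res.summary())
```

```
II
Rogers random-predator model: predator
n trials = 225, T = 1 days, log-likelihood = -379.965, converged = True

parameter                  estimate         SE        z      P>|z|
attack coefficient a         0.9408     0.1542    6.101  1.053e-09
handling time h (d)          0.2572     0.0186   13.801  2.499e-43

max feeding rate: 3.8885 prey/experiment (1/(T*h)), 3.8885 prey/day (1/h)
```

The fit recovers the generating parameters (a = 0.85, h = 0.258) within
one standard error; the asymptote says this predator can eat at most
≈3.9 prey per day regardless of how many are offered. Combining feeding
rates with field abundances:

```python
large  = frip.EffectSummary("large_invader", 1.099, 0.047, 14.760, 2.955)
native = frip.EffectSummary("native",        0.157, 0.012, 17.378, 4.486)
print(frip.rip_score(large, native, seed=42).summary())
```

```
RIP large_invader vs native: mean 6.381, 80% CI 4.547-7.999, 60% CI 5.546-6.575, P(RIP>1) = 100.000% (100000 draws, lognormal law)
```

Despite similar field densities, the large invader's seven-fold higher
maximum feeding rate predicts an impact roughly 6.4 times that of the
native amphipod, with essentially no overlap below parity.

## Command line

```sh
frip simulate --config examples/sim_config.yaml --out trials.csv
frip classify trials.csv
frip fit trials.csv
frip run examples/demo_config.yaml      # full pipeline -> CSV tables + log
```

The demo pipeline config (`examples/demo_config.yaml`) simulates two
predator groups and their quadrat surveys, classifies and fits both,
compares them, bootstraps uncertainty, and writes Table-style outputs
(fits, comparisons, abundance, RIP, biplot data) under `demo_out/`.

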