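# agecjs

Age-structured Bayesian Cormack–Jolly–Seber (CJS) survival analysis for
single-site capture–mark–recapture programmes, built around a griffon
vulture (*Gyps fulvus*) population ringed at a landfill feeding site
(2012–2022) across a natural experiment: a waste treatment centre opened
mid-2015 and cut the organic matter dumped at the site by ~96%.

When every capture happens at one feeding site, apparent survival (φ)
confounds mortality with permanent emigration, and two pathologies
dominate: **transients** (one-visit passage birds, whose post-release
apparent survival is zero) and **immediate trap-dependence** (capture at
one occasion changes the probability of capture at the next). This
package implements the full workflow for that setting:

* pooling raw encounters into six-month occasions, deterministic
  calendar-cycle ageing (juvenile 1 y / immature 2–4 y / adult 5+ y),
  and the age/residency (5-category) and trap-response (4-category)
  covariate matrices;
* goodness-of-fit screens for the time-dependent CJS model — transience
  (Test3.SR, positive z) and trap-dependence (Test2.CT, negative z =
  trap-happiness) — as summed per-occasion contingency tests with
  directional N(0,1) statistics;
* the hierarchical Bayesian state-space model, with survival and
  recapture intercepts per category × period and logit-normal individual
  frailty:

      z[i,t+1] | z[i,t] ~ Bernoulli(z[i,t] · φ[A[i,t]])
      y[i,t]   | z[i,t] ~ Bernoulli(z[i,t] · P[T[i,t]])
      logit φ[i,t] = β[A,W] + ε[i,cell],   ε ~ N(0, σ_φ²)
      logit P[i,t] = α[T,W] + ω[i,cell],   ω ~ N(0, σ_P²)

  fitted by a seeded, numba-compiled adaptive Metropolis-within-Gibbs
  sampler on the *marginal* likelihood (latent states summed out by the
  forward/backward recursion), with interweaving moves for the variance
  components and Gelman–Rubin convergence screening;
* derived quantities: the transient proportion τ = 1 − φ′/φ per age
  class and period, later-minus-earlier period contrasts with 95%
  credible intervals, and trap-happy/trap-shy/neutral labels;
* a synthetic-data generator with the exact generative structure the
  model assumes, plus ground truth, powering parameter-recovery and
  operating-characteristic tests end to end (the study's ringing data are
  not publicly deposited).

See `docs/methods.md` for the model, its assumptions, the design choices
and their rationale.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_simulate_study.py --seed 1   # study-scale synthetic dataset
python analysis/02_gof_screen.py                # GOF screen
python analysis/03_fit_survival.py --seed 1     # fit the hierarchical model
python analysis/04_derived_quantities.py        # headline tables
```

Step 01 emulates the ringing programme and reports, for seed 1:

```
simulated 3731 individuals (3414 with known age, 317 unknown-age)
recaptures among known-age individuals: 1539
   juvenile: 637 first captures, 63.6% never recaptured
   immature: 1104 first captures, 71.6% never recaptured
      adult: 1673 first captures, 77.1% never recaptured
```

— 3,414 retained marked birds and ~1,500 recaptures, with roughly
two-thirds to three-quarters of each age class never seen again, the
magnitudes the generator is calibrated to. Step 02 then screens the
time-dependent CJS model:

```
3414 individuals retained (317 unknown-age dropped, 8.5%)
Test3.SR: chi2 = 148.50, df = 20, p = 1.21e-21, z = +11.58
Test2.CT: chi2 = 36.93, df = 19, p = 8.09e-03, z = -1.63
```

The strongly positive Test3.SR z says newly marked birds are never
re-seen far more often than residents — transients — so the model must
separate newly-marked from resident survival; Test2.CT probes immediate
trap-dependence, which the trap-response categories absorb. Step 03 fits
the model (reduced protocol by default, `--full` for the production
3 × 95,000-iteration protocol) and reports convergence honestly — at the
reduced protocol two frailty SDs still flag Gelman–Rubin values of ~1.13,
which the run surfaces as warnings. Step 04 prints the headline tables;
for the seed-1 dataset (posterior mean [95% BCI] for periods 1/2/3):

```
apparent survival:
            resident adult: 0.885 [0.828, 0.939] | 0.946 [0.908, 0.989] | 0.787 [0.751, 0.819]
transient proportion:
                     adult: 0.387 [0.240, 0.504] | 0.451 [0.352, 0.542] | 0.590 [0.486, 0.677]

Period contrasts (later minus earlier):
      resident adult phi P2-P1: +0.061 [-0.012, +0.136] (increase)
      resident adult phi P3-P2: -0.159 [-0.211, -0.106] (decline)
               adult tau P3-P1: +0.203 [+0.044, +0.372] (increase)
```

Read: resident adult semester survival held up (even rose) during the
first after-period, then dropped sharply under extreme food reduction,
while the proportion of transients among newly marked adults climbed —
the pattern the generator encodes, recovered by the fit.

The same machinery is available as a CLI (`agecjs simulate / gof / fit /
report`) for arbitrary encounter CSVs and YAML configs, writing a
manifest with file digests so identical seeds give identical artifacts.

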