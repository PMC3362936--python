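# tolgen — genetics of disease resistance and tolerance via reaction norms

`tolgen` is an analysis package for quantitative geneticists studying how
a production disease reshapes the genetics of performance. The motivating
system is ascites in broiler chickens: heart ratio (right-ventricle weight
as a share of total heart weight, in %) indexes disease severity and hence
*resistance*, while *tolerance* is the reaction-norm slope of 7-week body
weight on severity. Tolerance cannot be measured on an individual bird —
each bird is observed at a single severity — but with a pedigree it is
estimable as a correlated random effect.

The package provides:

* **Pedigree machinery** — validation, inbreeding, relationships, and
  Henderson's sparse A-inverse;
* **A sparse AI-REML engine** — animal models with pedigree-structured,
  unstructured-block and heterogeneous-residual (co)variances, exact
  first derivatives via a Takahashi selected inverse, EM fallback and a
  log-Cholesky quasi-Newton polish; BLUP breeding values and
  delta-method standard errors;
* **The analysis models** — trait-mean animal models for body weights and
  heart ratio; the random-regression tolerance model with a
  plateau-linear severity covariate `RATIOPlat = max(0, RATIO - 29%)`,
  correlated intercept/slope effects at animal and dam level, and five
  severity-class residual variances; bivariate and extended fits for
  genetic/maternal/phenotypic correlations;
* **Covariance functions** — variance, heritability (`h² = V_G/V_P`),
  maternal-ratio and genotype re-ranking trajectories along severity,
  e.g. the genetic correlation between healthy and affected birds
  `r(t) = x₀'G x_t / sqrt(x₀'G x₀ · x_t'G x_t)` with `x_t = (1, t)'`;
* **A matched simulator** — a seeded synthetic population reproducing the
  study design (83 sires × ~15.7 dams, 7,722 offspring, 5 batches × 2
  stables, 11 heart cutters, ~9% mortality) and its published variance
  components, so every stage is testable without the original data;
* **A CLI and numbered analysis scripts** driving the whole sequence.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate the full study design and run the analysis sequence:

```bash
python analysis/01_simulate_population.py --seed 1 --full
python analysis/02_fit_mean_models.py
python analysis/03_fit_tolerance_model.py
python analysis/05_trajectories.py
python analysis/04_threshold_scan.py
```

Output from the run above (seed 1):

```
population: 7722 birds, 83 sires, 633 dams (seed 1)
affected fraction: 44.21%
class-wise raw CV of BW7 (%): 11.8, 11.7, 13.7, 15.4, 20.2
trait counts: {'bw2': 7710, 'bw7': 7037, 'ratio': 6990}

bw2:   V_G=235.1  V_M=69.7   V_P=908.7   h2=0.26+-0.05 m2=0.08+-0.02
bw7:   V_G=8963.0 V_M=2634.0 V_P=64733.4 h2=0.14+-0.03 m2=0.04+-0.01
ratio: V_G=13.7   V_M=0.6    V_P=45.8    h2=0.30+-0.05 m2=0.01+-0.02

model 3: converged=True logL=-48120.45
slope genetic variance: 0.0 +- 40.1 g^2/%^2
population slope: -15.80 g/%
total slope EBVs, sires: n=83 range [-16.15, -15.57] g/%
total slope EBVs, dams:  n=633 range [-20.24, -12.01] g/%

 threshold   model        aic   converged
      27.0 plateau  39995.66        True
      28.0 plateau  39994.42        True
      29.0 plateau  39984.68        True
      30.0 plateau  39999.38        True
       NaN  linear  40006.64        True
selected threshold: 29.0%
```

Reading this: single-trait heritabilities land near their generating
values (0.33, 0.18, 0.34) within one to two SE. The population tolerance
slope is about −15.8 g of 7-week weight per % heart ratio — affected
birds lose weight with severity. The threshold scan recovers the
generating 29% plateau and the plateau model beats the linear one by ~22
AIC points. Note the slope *genetic* variance: on this replicate it sits
on the zero boundary with SE 40 — the variance partition between the
animal and dam slope is the most weakly identified piece of the whole
analysis (the real-data estimate, 57.8 ± 37.5, is itself only 1.5 SE from
zero), and single replicates scatter widely; the replicated recovery
studies below show the estimator is centred correctly.

The same pipeline is available as a console tool
(`tolgen simulate | fit-mean | fit-tolerance | threshold-scan |
trajectories | run-all`), and `analysis/06_correlations.py` adds the
bivariate and trait-by-(intercept, slope) correlation tables.

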