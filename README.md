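# deathscreen

Death-rate-centric analysis of drug response and chemo-genetic CRISPR
screens.

Most measures of drug sensitivity — relative viability, endpoint fold
changes — conflate two very different biological effects: slowing cell
proliferation and actively killing cells. `deathscreen` is built for the
question *does this perturbation change the drug-induced death rate?* It
provides, end to end:

* **FLICK viability metrics** (`deathscreen.flick`): lethal fraction (LF),
  fractional viability (FV = 1 − LF, death-specific), relative viability
  (RV, growth-biased) and the normalized growth-rate inhibition value
  GR = 2^(log₂(L_T/L₀)/log₂(L_U/L₀)) − 1 from plate fluorescence tables.
* **GRADE** (`deathscreen.rates`): a live/dead birth–death model
  (dL/dt = (g·ln2 − d)·L, dD/dt = d·L) and the inversion of an observed
  (GR, LF) pair into a proliferation rate g (doublings/h) and a per-capita
  death rate d (/h). `GradeModel(...).fit()` returns a `GradeResults` with
  per-dose rates, flags and a `summary()`.
* **MEDUSA** (`deathscreen.medusa`): simulation-assisted inversion of
  genome-wide screen fold changes into per-knockout (growth, death) rate
  pairs, removing the growth-rate confound that makes conventional L2FC
  analyses blind to death regulation. `MedusaScreen(counts, library,
  timeline).fit()` returns per-guide inferences plus gene-level death-rate
  and growth-rate tables with z scores, bootstrap empirical p values and
  BH-FDR q values against a non-targeting pseudo-gene null.
* **Conventional screen statistics** (`deathscreen.stats`): abundance
  filtering, median-of-ratios normalization, guide L2FC for
  treated-vs-untreated / essentiality / conditional-essentiality
  contrasts, gene collapse, non-targeting pseudo-genes, bootstrap p,
  BH-FDR, Fisher overlap and ROC utilities.
* **Death-specific synergy** (`deathscreen.synergy`): median-effect fits,
  Chou–Talalay combination index (CI = d₁/Dx₁ + d₂/Dx₂), Loewe isobols,
  Bliss-independence deviation (DBI) — computed on both FV and RV so that
  death synergy and growth synergy can be told apart.
* **Synthetic data** (`deathscreen.simulate`): seed-deterministic
  generators for plate kinetics, pooled screens with known per-gene
  effects, and two-drug surfaces under Loewe/Bliss/synergy reference
  models, so every stage is testable without external downloads.

## Worked example

Decompose a drug response into growth and death rates. Cells that double
every ~33 h (g₀ = 0.03 doublings/h, basal death 0.001/h) are treated for
72 h; the drug halves proliferation and raises the death rate ten-fold:

```python
from deathscreen import RatePair, GradeModel, simulate_live_dead
from deathscreen.flick import gr_value

untreated = RatePair(g=0.03, d=0.001)
treated   = RatePair(g=0.015, d=0.01)

s_u = simulate_live_dead(1.0, 0.0, untreated, 72.0)
s_t = simulate_live_dead(1.0, 0.0, treated, 72.0)
gr = gr_value(s_t.L, 1.0, s_u.L)          # 0.0140
lf = s_t.D / (s_t.L + s_t.D)              # 0.4151

res = GradeModel([gr], [lf], t=72.0, untreated_rates=untreated).fit()
print(res.summary())
```

```
GRADE rate inversion
  assay duration: 72 h
  untreated rates: g0=0.03 doublings/h, d0=0.001 /h

      GR      LF  g_doublings_per_h   d_per_h    k_per_h flags
0.014006 0.41514              0.015      0.01 -0.0001035
```

A GR of 0.014 alone would read as "near-complete cytostasis"; the GRADE
decomposition shows the population is still proliferating at half its
untreated rate while ~40% of cells produced during the window died —
a strongly death-driven response.

The same decomposition at screen scale:

```python
from deathscreen import MedusaScreen, ScreenTimeline
from deathscreen import simulate as dssim

timeline = ScreenTimeline(untreated_rates=untreated, treated_rates=treated)
lib = dssim.random_guide_library(seed=1)            # 1000 genes x 4 + 142 NT
truth = dssim.make_screen_truth(lib, timeline, seed=1)
counts = dssim.simulate_screen(truth, lib, timeline, seed=1)
res = MedusaScreen(counts, lib, timeline).fit(seed=1)
print(res.summary())
```

```
MEDUSA chemo-genetic screen analysis
  guides analysed: 3934 (208 removed by abundance filter)
  growth constraint: proportional_inhibition
  treated window: 72 h; untreated window: 72 h
  death-rate hits (q<0.05): 110
  growth-rate hits (q<0.05): 206
```

`res.gene_death` and `res.gene_growth` hold the per-gene scores, z, p and
q; `res.hits("death")` lists genes whose knockout changes the drug-induced
death rate at q < 0.05.

A CLI mirrors the library: `deathscreen count | flick | grade |
screen-stats | medusa | synergy | simulate` (see `deathscreen --help`).

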