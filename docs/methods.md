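# Methods

## The live/dead birth–death model

All rate inference in the package rests on a two-compartment population
model. Live cells L proliferate at g doublings/hour and die at a
per-capita rate d (fraction of live cells per hour); dead cells D
accumulate and persist:

    dL/dt = k·L,         k = g·ln2 − d
    dD/dt = d·L

with the closed form L(t) = L₀·e^{kt} and
D(t) = D₀ + d·L₀·(e^{kt} − 1)/k (continuously extended through k = 0 via
expm1). Dead cells carry no clearance term: the plate readout being
modelled is cumulative dead-cell fluorescence over assay windows of about
72 h, within which dye-labelled corpses do not disappear. Rates are
constant in time — there is no death-onset lag or drug pharmacokinetics —
so inferred rates are window-averaged effective rates.

The death-rate unit deserves a note: d is a per-capita hazard
(fraction of currently-live cells per hour), not the slope of the lethal
fraction curve. The two coincide only at early times; `GradeResults`
carries d, and the realized LF trajectory can always be regenerated from
the model, so either reading can be compared against kinetic data.

## Viability metrics

From a plate with a T0-lysed total, kinetic dead-cell readings, and an
endpoint-lysed total, live signal is inferred as total − dead (clamped at
0 against noise). The four metrics:

* LF = dead/(live + dead); FV = 1 − LF. FV + LF = 1 holds exactly by
  construction.
* RV = treated live / untreated live.
* GR = 2^(log₂(L_T/L₀) / log₂(L_U/L₀)) − 1; GR = 1 means untreated-like
  growth, 0 cytostasis, negative a shrinking population. GR is undefined
  when the untreated arm did not grow, and is invariant to rescaling all
  fluorescence by a common gain — the assumed fluorescence model is a
  single linear gain per plate with no per-well background term.

Drug-induced LF is vehicle-subtracted and floored at zero,
ΔLF(t) = max(LF_drug − LF_vehicle, 0): background death in a fast-dying
line is not drug-induced, and the subtraction choice is recorded in output
metadata (the raw LF is returned, flagged, when no vehicle series exists).
Note that ΔLF is only approximately zero for a pure growth inhibitor:
slowing growth at a fixed basal death rate inflates the lethal fraction
slightly (fewer live cells dilute the same corpse count), which is why the
cytostatic-control tests allow |ΔLF| up to 0.05 rather than 0.

Dose–response curves use an ordinary 4-parameter logistic least-squares
fit; non-convergent fits fall back to a flagged flat line, near-constant
data are flagged degenerate. Timepoint matching is nearest-neighbour
within 1 h by default.

## GRADE inversion

Given an observed (GR, LF) at time t plus the untreated rates (g₀, d₀):

1. the treated net rate follows algebraically from the GR definition,
   k = k₀·log₂(GR + 1);
2. d is the root of LF_model(d; k, t) = LF. At fixed k, LF(t) is strictly
   increasing in d (asserted numerically in the tests), so the root is
   unique; it is found by Brent bracketing on [0, 1] h⁻¹ with xtol 1e-10;
3. g = (k + d)/ln2, floored at 0 with a flag.

The dead-cell seed D₀ defaults to 0 and can be set from a measured basal
dead fraction. Observed LF at or below the zero-death prediction returns
d = 0 with a flag rather than a negative rate. Round trips over
g ∈ [0, 0.1], d ∈ [0, 0.05] at t = 72 h recover rates to better than
1e-10 absolute.

## MEDUSA

A pooled screen compares four populations: knockout and wild-type cells,
treated and untreated. Under the infinitesimal-clone approximation (every
knockout is a negligible library fraction; the default generator keeps the
largest clone under 1%), live-cell sequencing gives each clone two
observables relative to wild type, both linear in the net rates:

    A = (k_u^KO − k_u^WT)·t_u / ln2          (untreated vs T0)
    B = [(k_T^KO − k_T^WT)·t_T − (k_u^KO − k_u^WT)·t_u] / ln2
                                             (treated vs untreated)

with k_u^KO = φ·g₀·ln2 − d₀ and k_T^KO = g_i·ln2 − d_i. The treated and
untreated windows are separate configuration fields (both default 72 h);
untreated-arm passaging is treated as abundance-preserving.

**Identifiability.** B constrains only the treated net rate, so (g_i, d_i)
are not separable from the fold changes alone. The package closes the
system with a *proportional inhibition* constraint — the drug reduces
every clone's growth by the wild-type factor, g_i = φ·g_T. This is a
modelling assumption, stated in all output metadata, and the constraint is
a pluggable callable so alternatives can be substituted. Its main failure
mode is a knockout that specifically alters drug-induced growth
inhibition; such effects fold into the apparent death rate.

Under the constraint the inversion is closed-form: φ from A (assuming the
knockout keeps the basal death rate d₀ untreated), g_i from φ, d_i from B.
Negative d_i solutions are floored at 0, the unexplained part of B is
reported as a residual, and |residual| > 1 L2FC unit flags a
low-confidence fit. Death rates below the wild-type treated rate are
reported as death rescue, never as negative rates.

A second, simulation-style inversion route precomputes the (A, B)
surfaces over a grid (φ log-spaced over [0.25, 2], 60 steps; d linear over
[0, 5·d_T], 60 steps), and inverts observations by linear interpolation —
A is monotone in φ and B monotone in d, so the lookup is well posed.
Observations outside the grid hull are clamped and flagged. The two routes
agree to machine precision on in-hull cases and serve as mutual oracles in
the tests.

Gene-level tables collapse guide rates by the mean, z-score against
non-targeting pseudo-genes, and attach bootstrap empirical p values
(10,000 iterations by default) and BH-FDR q; the death-rate and
growth-rate axes get separate tables.

## Conventional screen statistics

* **Filtering**: guides in the bottom 5% by base mean (mean normalized
  count over all samples) are removed; base-mean ties break by guide_id
  lexical order so the cut is deterministic.
* **Normalization**: explicit median-of-ratios size factors (the
  DESeq2-style estimator, re-implemented without shrinkage so the
  statistic stays auditable; cross-checked against pydeseq2 in the tests).
  When no guide is nonzero everywhere, total-count scaling is used with a
  warning.
* **L2FC**: log2 of replicate-mean normalized counts with a pseudocount
  of 0.5 on both sides; three contrasts (treated vs untreated, untreated
  vs T0 "essentiality", treated vs T0 "conditional essentiality").
* **Null construction**: non-targeting guides are randomly partitioned
  (seeded) into pseudo-genes of 4; with 142 such guides this yields 35
  pseudo-genes and 2 unassigned guides, which are dropped and logged.
  Gene scores are z-scored with the pseudo-gene mean and sample (n−1) sd.
* **Empirical p**: for a gene with n guides, 10,000 n-guide resamples
  (with replacement) from the non-targeting guide pool are collapsed with
  the same statistic and z-scored identically;
  p = (1 + #{|z_null| ≥ |z_obs|})/(1 + N), two-sided, then BH-FDR. The
  null pool is non-targeting guides only (a deliberate choice; resampling
  all guides would mix real effects into the null). Hits default to
  q < 0.05.

A consequence worth knowing: with only 142 non-targeting guides anchoring
the null, the estimated null mean and sd carry seed-level noise, which
shifts every z in a screen coherently by a few tenths. This is a property
of the screen design, not of the implementation, and it is why
calibration-sensitive tests pool several independent screens.

## Synergy

Effects are affected fractions: 1 − FV for the death-specific analysis,
1 − RV for the conventional one. Single agents are fitted with the
linearised median-effect model log(fa/(1−fa)) = m(log D − log Dm) (points
clipped at 0 or 1 are dropped; ≥ 3 usable points required), giving
equipotent doses Dx = Dm·(x/(1−x))^{1/m}. The combination index at a
level is CI = d₁/Dx₁ + d₂/Dx₂, computed by default at 50% effect from a
median-effect fit of the fixed-ratio (grid-diagonal) combination series;
1/CI is the fold reduction in dose versus additivity. Isobols are
extracted by bilinear contouring of the response surface and compared
with the line joining the single-agent intercepts. DBI is defined as
observed minus Bliss-expected effect (E₁ + E₂ − E₁E₂) per combination
cell, summarised by mean and max — the literature does not fix one DBI
convention, so the choice is recorded in output metadata.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume:
exponential clonal dynamics, multinomial sequencing at fixed depth
(default 500× library coverage; optional gamma overdispersion, off by
default), lognormal plate noise, per-guide efficacy jitter (lognormal,
sd 0.1) so gene collapse is meaningful, and Hill-shaped dose surfaces
under exact Loewe/Bliss references with a potency-shift synergy knob
(κ = 25 shifts the combination Dx 25-fold inside the additive surface).
The default screen is 1,000 genes × 4 guides + 142 non-targeting, with
5% death-suppressors, 5% death-sensitizers, 10% growth-only and 10%
essential genes; class effect sizes are graded (drawn per gene from
ranges) because real knockout phenotypes vary in strength — and because
rank-recovery statements are only meaningful against a truth that
actually varies.

Deliberately not modelled: infection MOI and selection kinetics, clonal
resistance evolution, dead-cell sequencing carryover, clone–clone
competition, dye-signal decay, guide-efficiency weighting and copy-number
artefacts. Passing tests therefore demonstrate correctness of the
inference machinery under the stated model, not robustness to every
artefact of real screens; the treated-growth constraint in particular is
satisfied exactly by the generator, so real-data deviations from
proportional inhibition are not exercised.

## Numerical choices and degenerate inputs

Root finding: Brent on a fixed bracket, xtol 1e-10. expm1 keeps the k → 0
limit exact. Zero-total wells return missing values rather than raising.
Counts are validated non-negative integers; ambiguous reads (Hamming ties
at minimal distance) are dropped and tallied, with exact matches always
out-ranking single-mismatch matches. The FASTQ matcher supports Hamming
distance ≤ 1 via an exhaustive variant index — the screen convention —
rather than an external aligner. All stochastic steps (pseudo-gene
partition, bootstraps, generators) take explicit seeds and are
bit-reproducible.

## Problem sizes used in the test suite

The suite runs the full screen pipeline at its default size (4,142 guides,
5 samples, 500× coverage) with 500–2,000 bootstrap iterations where the
10,000-iteration default would add nothing to the assertion being made;
the iteration count only sharpens the p-value floor, which the affected
tests do not probe. Cross-method inversion checks use 1,000 random cases;
calibration checks pool five independently seeded screens.
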