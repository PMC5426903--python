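# Methods

This note records the models implemented in `memokin`, the assumptions they
make, the defaults and numerical choices, and what the synthetic
benchmarks do and do not establish.

## Chimera replacement models

**Source descriptors.**  The source population (naive CD4, or T_CM when it
is treated as the feeder of T_EM) is described empirically, not
mechanistically: size decays exponentially, S(t) = S0·e^(−Rt), and
normalised chimerism follows a logistic, ρ_S(t) = ρ_max / (1 + e^(−rt)
(ρ_max − ρ_0)/ρ_0).  Normalisation divides each animal's donor fraction by
its DP1-thymocyte donor fraction, removing between-mouse variation in
stem-cell replacement.  All model time runs from host age 98 days (six
weeks after bone-marrow transplant), when thymic chimerism has
stabilised.  Size is fitted on log counts (count noise is multiplicative);
chimerism on its natural scale; uncertainty by nonparametric residual
bootstrap (default 1000 replicates).

**Replacement ODEs.**  The memory pool obeys dM/dt = γ(t)S(t) − λ(M −
M_inc) and dρ_M/dt = γ(t)S(t)/M (ρ_S − ρ_M) − λ M_inc/M ρ_M.  Two
sub-models explain why donor chimerism plateaus below the source's level:
a displacement-resistant incumbent pool (M_inc free, φ = 0) or a waning
per-capita recruitment rate (γ(t) = γ0 e^(−φt), M_inc = 0); "combined"
frees both.  Each sub-model has five free parameters: γ0, λ, one of
M_inc/φ, and the initial conditions M(0), ρ_M(0).

**Likelihood.**  Gaussian residuals on log10 counts and on untransformed
normalised chimerism, each variance profiled out; the joint log-likelihood
is the sum of the two timecourse log-likelihoods.  The model curves are
shared across mice, so mice are treated as exchangeable replicates of a
population-average trajectory.  Optimisation is bounded trust-region least
squares with the two residual blocks reweighted by their profiled standard
deviations (iterated to convergence, which reproduces the concentrated
maximum likelihood), started from 20 seeded Latin-hypercube points.
Bootstrap confidence intervals resample residuals within each timecourse
and simultaneously draw source descriptors from the source bootstrap
(default 500 replicates; raise to 3000 for publication-grade intervals).

**Replacement fractions.**  With ψ = R + φ − λ, the number of immigrants
recruited over (0, t) and surviving is Y(t) = γ0 S0 e^(−λt)(1 −
e^(−ψt))/ψ, and the replaced fraction is f_replace = Y/(X + Y + M_inc)
with X(t) = (M0 − M_inc)e^(−λt); replacement of the displaceable subset
drops M_inc from the denominator.  (e^x − 1)/x is evaluated by a 3-term
series when |ψt| < 1e−6.  The closed form is verified against direct
integration of dY/dt = γ(t)S(t) − λY on every call (1e−6 internal
assertion; the test suite checks 1e−8 agreement).  Age projections
re-apply the closed form with age-shifted S0 and γ0 and the simulated
M(t); ages beyond twice the fitted data range are flagged as
extrapolations.

The quick slope-ratio estimator γS/M ≈ (dρ_M/dt)/(ρ_S − ρ_M) is exposed
separately; it is accurate when memory chimerism is still low and the pool
is near-stationary, and is undefined when the source's chimerism does not
exceed the memory's.

## BrdU × Ki67 labelling model

**State space.**  Each cell carries a subpopulation label (one population
for temporal heterogeneity, TH; fast/slow for kinetic heterogeneity, KH),
a Ki67 level (low, or one of k̂ sequential high stages, each left at rate
k̂β, giving an Erlang(k̂) residence with mean 1/β and CV 1/√k̂), and a
BrdU class (unlabelled, or j = 0…b̂−1 divisions since last uptake; the
b̂-th label-free division returns a cell to BrdU−).  Division removes the
mother and places two daughters in the first high stage; during feeding
both daughters are labelled (class 0) with probability ε per division,
otherwise the class advances.  Ki67-low and Ki67-high cells die at δ− and
δ+.  The source enters the first Ki67-high stage at a constant
N·s_week/7 cells/day, split (1−f_slow, f_slow) between fast and slow, and
is BrdU+ during feeding and for τ days afterwards (a hard switch).  There
are no flows between subpopulations.

Design choices where the biology is underdetermined: both daughters of a
division receive the same BrdU outcome (b̂ absorbs strand-dilution
detail); dividing Ki67-high cells restart at stage 1 (Ki67 expression
restarts at mitosis); source cells enter the first (freshest) high stage;
the ε-uptake rule applies identically at every division during feeding.

**Steady-state resolution.**  Short labelling experiments show no trend in
pool size or Ki67-high fraction, so both are imposed as constraints.  At
the unlabelled equilibrium the high stages form a geometric cascade
(h_g ∝ a^(g−1), a = k̂β/(k̂β + δ+ + α)), which gives closed forms for the
Ki67-high fraction and the stationarity condition.  For KH, each
subpopulation's death rate is solved by scalar root-finding so its size is
stationary (δ+ = ratio·δ−, ratio fixed at 1, 0.1 or 10), and the slow
division rate is solved so the size-weighted Ki67-high fraction equals the
observed κ; free parameters: α_fast, ε, β, τ, q_fast, f_slow (six).  For
TH both death rates are resolved jointly from the two constraints, so the
high/low death-rate ratio is an outcome; free parameters: α, ε, β, τ
(four).  Parameter points with no admissible resolution raise a graded
infeasibility that the fitters use as a smooth rejection penalty.  k̂ and
b̂ are integers, fixed per fit (defaults 12 and 2) and chosen by AIC over
grids when profiled; they are not counted in the AIC parameter number.
Because the two KH subpopulations are exchangeable, fits are
canonicalised so "fast" is the faster-dividing one.

**Forward solution.**  Within each protocol phase (feeding; chase with
labelled source; chase with unlabelled source) the dynamics are affine
with constant coefficients, so the solver propagates the exact matrix
exponential of the augmented system — rates never change across phases,
only division outcomes and the source's label do.  A BDF stiff integrator
(rtol 1e−8, atol 1e−10·N) is retained as an internal cross-check; the two
agree to ~1e−8.  Occupancies are clipped at zero before fractions are
formed, and a negative excursion beyond 1e−8·N is surfaced as an error.

**Inference.**  BrdU+ fractions in both gates, pooled over the 4/7/21-day
protocols, are fitted by least squares on the arcsine-square-root scale
(variance-stabilising for proportions) with the residual variance profiled
out; AIC = 2k + n·ln(RSS/n).  The source magnitude s_week is fixed
externally — from the chimera analysis (0.07/week for T_EM, 0.106 for
T_CM) or a profiling grid over [0, 0.30] — because it is not identifiable
from labelling data alone.  Multistart as above (8 seeded Latin-hypercube
starts by default).  Bootstrap: residuals resampled on the transformed
scale, with s_week optionally redrawn per replicate from a supplied
distribution; replicates that fail to converge are dropped and counted,
with a warning above a 20% drop rate.  AIC ties closer than 0.1 resolve
toward fewer parameters.

**Derived summaries.**  Lifetimes are reciprocal loss rates (for ratio ≠ 1,
the Ki67-high/low occupancy-weighted mean of 1/δ+ and 1/δ−); interdivision
times are reciprocal division-entry rates; pool averages weight fast and
slow by their size fractions; the source share of production is
S/(S + Σ α_p N_p).

## Synthetic data and the stochastic oracle

The generators emulate the two experimental table types at the study's
design: chimera timecourses at 12 ages (98–420 days, 4 mice/age) with
lognormal count noise (σ = 0.15 on log10 counts) and Gaussian chimerism
noise (σ = 0.05); labelling timecourses for the three protocols (~10
sample times each, 5 mice/timepoint) with Gaussian noise of σ = 0.05 on
the transformed scale.  Noise magnitudes were chosen to match the visual
scatter of typical datasets of this kind.  The labelling presets are the
published point estimates for the two subsets under the loss-ratio-1 KH
model; the chimera presets are realistic magnitudes for young adult mice
(the underlying descriptor estimates are not printed in the available
text, so these are the package's own defaults).

The agent simulator realises the identical rules as an exact event-driven
stochastic process.  Because the model is linear (cells do not interact),
per-cell exponential clocks are equivalent to a whole-population Gillespie
simulation; event *rates* are phase-independent, so clocks remain valid
across the feeding/chase switch and only event outcomes consult the
protocol clock.  Monte-Carlo standard errors are estimated across
independent replicate runs, which accounts for within-lineage correlation.
The ODE solver is required to match the oracle within 3 SE at every
sampled time — this is the package's master correctness check.

What passing these benchmarks does **not** show about real data: the
generators assume homoscedastic noise, exchangeable mice, perfectly known
gates and no measurement artifacts (gating drift, spillover), a constant
environment, and that the fitted model family contains the truth.  Power
and coverage measured on them are best-case.

## Problem sizes in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the checks are statistically meaningful: oracle
comparisons use 48,000–60,000 agents in 8 replicates; bootstrap coverage
uses 50 synthetic replicates with 250 bootstrap draws; model-selection
power uses 3 replicates of the full three-protocol design (the observed
AIC margins, 400–700 units, dwarf the 10-unit criterion); the noiseless
recovery experiment uses one mouse per timepoint, which is exact by
construction.

## Known limitations

* The chimera likelihood treats all mice as one population-average
  trajectory; no random effects per animal.
* Lagged transit from source to memory (1–7 day delays through a
  CD25-positive intermediate) is not modelled; the zero-lag models are
  known to give very similar replacement estimates.
* A single model containing both kinetic and temporal heterogeneity is not
  identifiable from these data and is not offered; the fixed death-ratio
  variants (0.1, 1, 10) bracket the temporal dimension within KH.
* s_week enters as a point value (or profile grid); joint fitting of the
  chimera and labelling likelihoods is out of scope.
* Slow-subpopulation rates are weakly identified — expect wide intervals
  for slow interdivision times, as the bootstrap reports.
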