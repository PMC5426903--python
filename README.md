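# memokin

Population dynamics of murine memory CD4 T cells: how fast are central
(T_CM) and effector (T_EM) memory subsets replenished from the naive pool,
and how are division and death distributed within them?

`memokin` implements two complementary inference pipelines for
immunologists and modellers working with steady-state labelling data:

1. **Tonic influx from busulfan-chimera timecourses.**  In busulfan
   chimeras, host haematopoietic stem cells are replaced by congenically
   marked donor marrow while peripheral T cells are left intact, so the
   accumulation of donor cells in a memory subset traces constitutive
   recruitment.  With a source population of size S(t) and normalised
   chimerism ρ_S(t) (donor fraction relative to DP1 thymocytes), the memory
   pool M and its chimerism ρ_M obey

       dM/dt   = γ(t) S(t) − λ (M − M_inc),      γ(t) = γ0 e^(−φt)
       dρ_M/dt = γ(t) S(t)/M (ρ_S − ρ_M) − λ M_inc/M ρ_M

   where M_inc is a displacement-resistant "incumbent" population and λ the
   net loss rate of displaceable memory.  Fitting these models yields the
   daily fractional influx γS/M and closed-form weekly replacement
   fractions, with AIC comparison of source pathways and residual-bootstrap
   confidence intervals.

2. **Division/death kinetics from BrdU × Ki67 pulse-chase timecourses.**
   Mice are fed BrdU for 4, 7 or 21 days and the BrdU+ fractions within the
   Ki67-high and Ki67-low gates are followed through a chase.  The
   compartmental model tracks (subpopulation × Ki67 stage × BrdU dilution
   class): cells enter division at rate α, daughters take up BrdU with
   efficiency ε during feeding and dilute it below detection after b̂
   divisions, Ki67 decays post-mitosis through k̂ sequential stages (Erlang
   residence, mean 1/β), and a source feeds the Ki67-high compartment,
   switching to BrdU− a delay τ after feeding ends.  Steady-state
   constraints (constant pool size, constant Ki67-high fraction κ)
   eliminate the death rates, leaving 4 free parameters for a
   temporally-heterogeneous (TH) single population and 6 for a kinetically
   heterogeneous (KH) fast + slow pair.  Models are compared by AIC.

A synthetic-data module generates both table types with the noise structure
the analyses assume, and an exact stochastic agent-level simulator of the
same rules serves as the correctness oracle for the deterministic solver.

## Worked example

Generate a synthetic effector-memory BrdU × Ki67 experiment (5 mice per
timepoint, realistic noise) and fit the kinetic-heterogeneity model:

```python
from memokin import BrdUKi67Model
from memokin.labelling.spec import resolve_steady_state
from memokin.synthetic import (
    LabellingTruth, generate_labelling_dataset, labelling_spec_preset,
)

spec = labelling_spec_preset("tem")
kappa = resolve_steady_state(spec).kappa_model     # observed Ki67-high fraction
data = generate_labelling_dataset(
    LabellingTruth(spec=spec, sigma=0.05, mice_per_timepoint=5), seed=1
)
fit = BrdUKi67Model(data, structure="KH", s_week=0.07, kappa_obs=kappa).fit(
    seed=1, n_starts=6
)
print(fit.summary())
```

```
BrdU/Ki67 fit: structure=KH, khat=12, bhat=2, death_ratio=1, s_week=0.07
  n=310  k=6  RSS=0.62136  AIC=-1913.85
  free parameters: alpha_fast=0.181, epsilon=0.7499, beta=0.301, tau=2.356, q_fast=0.3635, f_slow=1
  Ki67-high mean residence 1/beta = 3.32 d
  pool-average lifetime 28.5 d, interdivision time 78.8 d
  source fraction of production 0.123
  fast: lifetime 5.52 d, interdiv 5.52 d, Ki67-high 0.68, size 0.36 of pool
  slow: lifetime 41.7 d, interdiv 121 d, Ki67-high 0.10
```

The fit recovers the generating kinetics: a fast subpopulation (~36% of the
pool) dividing and dying every ~5.5 days alongside a slow one living ~42
days and dividing every ~4 months, a ~3.3-day post-mitotic Ki67-high
residence, ~75% BrdU uptake efficiency per division, and a source that
accounts for ~12% of total cell production.  `fit.bootstrap(...)` adds
percentile confidence intervals; fitting `structure="TH"` and comparing
with `compare_labelling_models` quantifies the evidence for kinetic over
temporal heterogeneity.

The chimera side works the same way (`SourceModel`,
`ChimeraReplacementModel`), and a CLI wraps both pipelines:

```bash
memokin synth chimera --preset tem --seed 1 --out chim.csv
memokin chimera fit --data chim.csv --subset TEM --source naive \
    --variant resistant --boot 500 --seed 1
memokin run --config pipeline.yaml     # YAML-configured end-to-end runs
```

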