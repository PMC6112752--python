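# Methods

## The model

`iedose` scores the *intrinsic immunogenicity* of a radiotherapy schedule —
the part of the abscopal (out-of-field, immune-mediated) response that is
attributable to the dosing regimen alone, independent of the immunotherapy
given with it. The mechanistic picture is a cycle of progressive
immuno-stimulation and instantaneous immuno-suppression:

1. each fraction kills a tumour-cell fraction `k_d = 1 − exp(−α d − β d²)`
   (the classic linear-quadratic model);
2. lethally hit cells die gradually and release tumour antigens; the release
   is 50% complete `T_D` days after the fraction;
3. antigen release triggers immune activation (dendritic-cell uptake,
   presentation, lymphocyte priming) that is 50% complete `T_IR` days after
   the release;
4. the *next* fraction kills or disables all immune effectors present in the
   tumour micro-environment, discarding any activation still in progress.

Both kinetic steps use the same sigmoid completion curve
`f(x) = 1 − (1/2)^(x²)` in scaled time (`x = t/T_D` for release, `x = t/T_IR`
for activation), with density `g(x) = f′(x) = 2 ln2 · x · (1/2)^(x²)`. Any
similarly shaped pair would serve; only the half-completion semantics of
`T_D` and `T_IR` matter.

For N fractions of dose `d_i` at times `T_i` the per-fraction immunogenic
yields are

```
E = S Θ K,      E_i = S_ii · (Σ_j θ_ij) · k_{d_i}
```

where `S_ii = Π_{m<i}(1 − k_{d_m})` is the tumour fraction still alive just
before fraction i, `K_i = k_{d_i}`, and the upper-triangular timing matrix Θ
has entries

```
θ_ij = (1/T_D) ∫_{T_j}^{T_{j+1}} g((t − T_i)/T_D) · f((T_{j+1} − t)/T_IR) dt     (i ≤ j < N)
θ_iN = 1 − f((T_N − T_i)/T_D)                                                    (open-ended last window)
θ_ij = 0                                                                          (j < i)
```

θ_ij is the fraction of the antigens from fraction i that are released in
the window between fractions j and j+1 *and* whose immune activation
completes before fraction j+1 sterilises the micro-environment. The `1/T_D`
factor makes `g((t − T_i)/T_D)/T_D` a unit probability density in clock
time, so each row of Θ sums to at most 1; it also makes the open-ended last
window collapse to the closed form above (the activation factor is 1 when no
further fraction follows) and gives the correct slow-death limit: as
`T_D → ∞` all finite windows vanish and the last column tends to 1, so
timing becomes irrelevant and the efficacy equals the total killed fraction.

Two summary metrics follow:

* **IED efficacy** `ΣE ∈ [0, 1)` — the fraction of the tumour volume
  converted into immunogenic antigens (reported as a whole percent);
* **IED** — the single dose at infinitely low dose rate (pure linear kill)
  with the same immunogenic yield: `IED = −ln(1 − ΣE)/α`. For one
  instantaneous dose D this reduces exactly to `D + (β/α) D²`.

BED (`Σ d_i (1 + d_i/(α/β))`, time-free form without a repopulation factor)
and EQD2 (`BED / (1 + 2/(α/β))`) are computed alongside for comparison; they
depend only on fraction sizes, never on timing.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `alpha` | Gy⁻¹ | 0.15 | LQ linear kill coefficient |
| `alpha_beta` | Gy | 4 | LQ α/β ratio; β = α/(α/β) is derived |
| `t_d` | days | 3 | antigen-release half-completion after a lethal hit |
| `t_ir` | days | 7 | immune-activation half-completion after a release |

The defaults are the worked-example values used throughout the reference
tables; all are overridable everywhere (library, CLI flags, YAML config).
`T_IR` can also absorb a micro-environment covariate: colder (more
immunosuppressed) tumours correspond to larger `T_IR`. When only a surviving
fraction at 2 Gy (SF2) is known, `sf2_to_params` converts it via
`SF2 = exp(−2α − 4β)` under an assumed α/β ratio (4 Gy by default) — the
ratio must be assumed because SF2 alone cannot identify both LQ parameters.

## Numerical choices

* **Quadrature.** Finite Θ windows use adaptive Gauss–Kronrod quadrature
  (`scipy.integrate.quad`, absolute and relative tolerance 1e−10). The
  integration interval is clipped to `[max(T_j, T_i), min(T_{j+1}, T_i +
  30·T_D)]`: `g` is identically zero before `T_i` and numerically zero
  (< 2⁻⁹⁰⁰) beyond 30 scaled units, and the clipping keeps the adaptive rule
  from hunting for a narrow release bump inside a months-long window. The
  open-ended last column is evaluated in closed form, never by truncated
  quadrature. The test suite cross-checks every entry against an independent
  fixed-grid trapezoid oracle (10⁵ points per window, tail truncated at
  `T_N + 20·T_D`) to 1e−6 on randomized schedules.
* **Kill fractions** use `expm1` to stay accurate for small doses.
* **Coincident events** (identical times within 1e−9 d) are merged into one
  event with summed dose before evaluation. The LQ model is nonlinear in
  dose, so this is a modelling choice, not an identity; a zero-width window
  would otherwise produce spurious θ = 0 artifacts. Merges across composed
  segments log a warning since they usually indicate an overlap mistake.
* **Efficacy guard.** ΣE < 1 holds mathematically for finite schedules; a
  clamp at 1 − 1e−15 protects the log when users feed extreme inputs, and a
  genuine ΣE ≥ 1 raises `OverflowError`.
* **Rounding.** Human-readable output rounds efficacy to a whole percent
  (the convention of the reference tables); TSV/JSON writers carry full
  precision.
* **Search determinism.** `constrained_search` enumerates its discretized
  candidate space exhaustively, filters on the cheap constraints (BED, EQD2,
  span, max dose/fraction) before any Θ evaluation, and breaks efficacy ties
  lexicographically on the event list, so rankings are reproducible
  bit-for-bit.

## Scheduling conventions

Times are decimal days throughout (6 h = 0.25 d) since `T_D`/`T_IR` are
given in days; only relative times matter (Θ is translation-invariant, which
the suite asserts to 1e−12). Weekday courses start on a Monday-equivalent
day 0 with a 2-day gap after every 5 consecutive treatment days; this is the
only layout under which a 25-fraction course spans exactly 32 days, matching
the classic 5-week normofractionated course. There is no calendar or
timezone handling, and no DICOM-RT parsing.

## Design choices where the design was open

* **Unequal doses.** The source formulation assumes N *equal* doses. The
  implementation generalizes to per-fraction doses via
  `K_i = k_{d_i}` and `S_ii = Π_{m<i}(1 − k_{d_m})`, which reduces exactly
  to the equal-dose formulas; the generalization is required to express
  hybrid schedules that mix 2 Gy and 3 Gy blocks.
* **High-dose validity.** The LQ underpinning is doubtful above ~10 Gy per
  fraction and the model is known to overstate immunogenicity for very large
  fractions. No published correction formula exists, so none is shipped;
  `evaluate`/`ied_efficacy` accept a `dose_transform` hook where a
  user-supplied per-fraction adjustment can be injected.
* **Hybrid reference schedules.** The two published split/bifractionated
  example schedules (reported at 28% and 67%) are under-determined: their
  caption-level dose accounting cannot be reconciled with the stated
  BED/EQD2 equality to the normofractionated reference, and weekend handling
  inside the bifractionated blocks is unstated. `compose_segments` can
  express any plausible reading, but the package deliberately ships no
  canonical fixture for them and does not test against those two
  percentages. The three unambiguous worked examples (74%, 32%, 2%) are
  reproduced instead.
* **Interfraction sweeps** treat the gap as a continuous variable with no
  weekend structure, which is the natural reading of a two-fraction
  experiment.

## What the tests do and do not show

The suite reproduces the published worked examples (74% / 32% / 2%, BED
72/75 Gy, EQD2 48/50 Gy), verifies the kernel calculus (g = f′, ∫g = 1), the
Θ structure (upper-triangular, entries and row sums in [0, 1], translation
invariance), the single-dose closed forms, the slow-death and well-separated
limits against the total-kill product, the drop-and-recovery shape of the
two-fraction gap sweep, and quadrature agreement with an independent
trapezoid oracle. All of this validates the *implementation* of the model,
not the model's biology: the IED rests on untested simplifications (complete
effector wipe-out at every fraction, a single universal release curve,
timing-independent radiosensitivity, no repopulation) and its correlation
with real out-of-field responses is supported by only a handful of
preclinical observations. Scores should be read as a rule-of-thumb screen
for under-performing schedules, not as predicted response probabilities, and
per-fraction doses above 10 Gy are outside the model's trusted range.
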