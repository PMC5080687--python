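# Methods

## Stoichiometric bookkeeping

The balance engine treats one fermentation endpoint — net consumed
substrates and final product titers in g/L over a stated duration — as a
closed accounting problem. Concentrations are converted to millimolar with
registry molar masses and to carbon-millimolar with per-molecule carbon
counts; all derived metrics are ratios of these quantities.

NAD(P)H accounting uses the canonical clostridial coefficients. Substrate
catabolism to acetyl-CoA regenerates 2 mol NAD(P)H per mol of glucose (EMP
glycolysis) and 2 per mol of glycerol (glycerol → DHAP → pyruvate), i.e.
1/3 and 2/3 NAD(P)H per carbon. Product formation from acetyl-CoA consumes
4 mol per mol butanol, 2 per butyric acid, 1 per isopropanol, and 0 for
acetone and acetic acid (their pathways are NAD(P)H-neutral; acetone and
acetate formation actually regenerate ATP/NAD(P)H upstream, which this
single-ledger bookkeeping does not track). The ferredoxin fraction
`max(0, required − generated)/required` attributes any shortfall to
NAD(P)H regenerated from reduced ferredoxin via PFOR; a surplus is clipped
to zero rather than reported negative, reflecting the interpretation that
no Fd-derived NAD(P)H is then needed. Whether PFOR-derived NAD(P)H should
already be folded into the glycerol generation coefficient is not
resolvable from endpoint data; the single coefficient 2 is taken at face
value.

Assumptions: products accumulate extracellularly and are not re-consumed
between sampling and measurement; biomass formation, H₂/CO₂ evolution and
ATP balance are outside the ledger; ethanol is excluded (titers in the
emulated study were below the 0.1 g/L detection limit). The engine
therefore reports *recoveries*, not closed balances — carbon recovery to
all measured products is well under 100% because CO₂ and biomass are
unmeasured.

### Registry constants

Molar masses are fixed registry constants (g/mol): glucose 180.2, glycerol
92.09, butanol 74.12, isopropanol 60.10, acetone 58.08, acetic acid 60.05,
butyric acid 88.11, 1,3-propanediol 76.09, ethanol 46.07, plus the
additional sugars used only for carbon accounting. Glucose is registered
at 180.2 rather than 180.16 because that is the conversion factor the
emulated study's printed mM values imply (21.85 g/L → 121.25 mM); at
180.16 the ×6 carbon totals drift by ~0.16 mM from the printed table.
The 1,3-propanediol NAD(P)H coefficient (1 mol/mol, the net reduction of
the glycerol → 1,3-PDO branch) is marked *extrapolated*: balance
computations refuse it unless explicitly enabled, so no quantity that
reproduces a published number ever depends on it. Sugars other than
glucose (and glycerol) carry no generation coefficient at all — the redox
ledger is defined only for glucose/glycerol cultures — and requesting one
is an error rather than a silent zero.

## Conventions and numerical choices

- **Yields** divide by *total* consumed substrate mass, so mixed glucose–
  glycerol feeds are handled uniformly. Zero total consumption is an error.
- **Productivities** are overall values (final titer / sampling time), not
  instantaneous maxima.
- **B/I** with a zero isopropanol titer is undefined and reported as such
  (None / `—` / JSON null), never as infinity.
- The engine returns full precision; rounding to display precision (2
  decimals by default) happens only in the report layer. Tests that
  compare against published values do so at the tables' printed precision,
  because those tables round their g/L inputs to 0.01 — propagated through
  the 4×-weighted butanol term this alone can shift an NAD(P)H-requirement
  total by up to ~0.47 mM.
- **Per-C-mole productions** default to mol product per C-mol substrate; a
  `per_carbon` switch gives C-mol per C-mol instead, since axis units of
  such plots are ambiguous in parts of the literature. The default is the
  mol basis.
- **Phase classification** is a coarse heuristic: acidogenic when total
  acids (g/L) exceed total solvents, solventogenic otherwise, ties
  counting as solventogenic with a warning.
- Time-course analysis interpolates linearly between samples; consumption
  is first-sample minus value-at-time with small noise-induced negatives
  clipped at zero.

## Synthetic batch generator

The generator emulates the qualitative structure of a biphasic clostridial
batch: logistic biomass growth to a carrying capacity; substrate uptake
proportional to biomass (g substrate/g DCW/h); an acidogenic phase before
`switch_time_h` converting drawn substrate to acetate and butyrate at
fixed mass yields; a solventogenic phase converting drawn substrate to
butanol/isopropanol/acetone (and 1,3-propanediol for glycerol presets)
while re-assimilating acids first-order into butanol (1 g/g by default)
and converting acetone to isopropanol first-order at molar equivalence.
Glucose–glycerol mixtures are co-consumed, glycerol supplying a fixed
fraction of the instantaneous draw while it lasts. pH is emitted as a
descriptive proxy (linear in total acids, clamped to [4.5, 6.2]) for
plotting only; it drives nothing.

Integration is explicit Euler with dt = 0.02 h by default, small enough
that halving dt moves preset endpoint titers by < 0.3% (the error is
dominated by the first-order decay terms, ~T·k²·dt/2 relative). Per-phase
yields must each sum to ≤ 1 on a mass basis, so products can never exceed
consumed substrate. Measurement noise — independent Gaussian per
observation, truncated at 0, the simplest stand-in for replicate scatter —
is applied only to an emitted copy; the latent trajectory is deterministic
and independent of the noise settings, and identical seeds reproduce
identical output.

What the generator does *not* emulate: product inhibition, sporulation,
gas stripping, pH feedback on metabolism, or any mechanistic kinetics of a
real organism. Passing parameter-recovery tests on this generator shows
the analysis pipeline is internally consistent, not that it would recover
parameters from real fermentations, whose noise is neither Gaussian nor
independent.

### Presets

No kinetic parameters are available for the emulated conditions, so the
four presets (`glucose_20`, `glucose_40`, `mix_14_8`, `glycerol_only`)
were calibrated once, by least squares on the noiseless endpoint, to land
within ±15% of the corresponding published endpoint table values
(substrate consumption, solvent and acid titers). The resulting yield and
rate constants are curve fits, not biological measurements, and should not
be interpreted mechanistically. `mix_14_8` uses a fast acetone-conversion
rate so the acetone pool is transient and the endpoint acetone-free;
`glycerol_only` routes solvent yield to butanol + 1,3-propanediol with
slow acid re-assimilation, leaving the high residual butyrate that
glycerol cultures show.

## Problem sizes

All published-number checks run on endpoint records (≤ 9 concentrations
each); simulation-based tests use 28–30 h horizons at dt = 0.02 h (~1400
steps) and 50 seeded replicates for the unbiasedness check. The full test
suite completes in a few seconds on one CPU.

## Known limitations

- The NAD(P)H ledger ignores NADH/NADPH specificity, hydrogenase flux and
  ATP, so the Fd fraction is a bookkeeping residual, not a measured flux.
- Published endpoint tables round to 0.01 g/L; recomputed derived rows can
  legitimately differ from printed ones by the propagated rounding, which
  the tests account for explicitly.
- A handful of published yield cells (e.g. some single-substrate
  conditions) are not recomputable from the printed consumed/titer values
  at all — the original authors evidently used unrounded instrument data.
  The fixtures store the printed concentrations and the tests assert only
  recomputable cells.
- The endpoint estimator from noisy time courses is unbiased only while
  residual substrate stays above the noise floor; once a substrate is
  exhausted, truncation of measurements at zero biases consumption
  slightly downward.
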