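# Methods

`nitracer` implements the rate calculus of a ¹⁵N stable-isotope tracer study
of benthic and bivalve-holobiont nitrogen cycling: net solute fluxes from
closed incubations, isotope-pairing denitrification partitioning with the
revised-technique (r-IPT) validity checks, DNRA and anammox estimation,
¹⁵N₂-fixation incorporation rates, exact small-sample rank inference, and
areal nitrogen-budget upscaling. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Flux model

Incubations are short, dark and closed; solute concentrations are assumed
to change linearly so that a single rate describes the vessel. The flux is
the OLS slope of concentration against time scaled by geometry:

    J = dC/dt · V / A            (cores,      µmol m⁻² h⁻¹)
    J = dC/dt · V / W · 1000     (microcosms, nmol g_SFDW⁻¹ h⁻¹)

with V the water volume (L), A the sediment area (m², from the 8.4 cm
liner inner diameter), W the animal's shell-free dry weight (g). Positive
flux means release to the water. With only two samples the slope is the
finite difference; an endpoint mode is available via `RunConfig.flux_mode`
for comparison with two-point protocols. The ≤20% O₂-drawdown rule — the
linearity guard of the incubation design — is evaluated against the
starting O₂ concentration and reported as a QC flag; flags annotate, they
never suppress a rate, because detection decisions are made separately by
the significance gates. Microcosm rates subtract the slope of the single
water-only control of the treatment; with one control per treatment the
control contributes no standard error (a documented limitation, not an
option). Subsampling withdrawals with water replacement are corrected by a
per-interval mass ledger: each replacement's mixing step is removed from
all later readings so that the corrected series reflects production only;
corrections across several withdrawals compose exactly.

## Isotope pairing

After ¹⁵NO₃⁻ addition the nitrate pool carries ¹⁵N mole fraction ε; random
pairing routes denitrified N₂ pairs as (1−ε)² : 2ε(1−ε) : ε² into
²⁸N₂:²⁹N₂:³⁰N₂. From the ²⁹N₂ and ³⁰N₂ production rates p29, p30:

    D15   = p29 + 2·p30,   D14 = D15 · p29/(2·p30),   D_tot = D14 + D15
    D_w   = D15/ε          (all water-column-NO₃⁻-fuelled denitrification)
    D_n   = D_tot − D_w    (coupled nitrification–denitrification)

The D_w convention (both isotopes, D_w + D_n = D_tot) is adopted and stated
prominently because an alternative ¹⁴N-only reading of D_w exists; this one
keeps the partition additive. Significance gating: the slope regressions
("whole dataset" pooling across replicate vessels when replicates are
supplied) must reach p < 0.05 for both isotopologues, otherwise the panel is
reported as zeros with a `NOT_SIGNIFICANT` flag — a non-detection, not a
dropped vessel, matching how rate ranges starting at zero are reported.
DNRA uses the same machinery at its own gate (p < 0.10). Directly
constructed rates without p-values skip the gate and carry a `P_UNDEFINED`
flag.

### r-IPT validity checks

Two assumptions are checked. (i) Tracer-concentration independence:
relative difference of D_tot (and DNRA when supplied) between the low and
high ¹⁵NO₃⁻ additions must stay within `independence_tolerance` (default
0.25 — generous enough for n = 4 vessels at ~15% between-vessel CV).
(ii) Binomial pairing consistency: for pure denitrification
p29²/(4·p28·p30) = 1 exactly; anammox — which pairs one NH₄⁺-derived and
one NO₂⁻/NO₃⁻-derived atom and never produces ³⁰N₂ — drives the ratio
above 1.

An algebraic point shapes this design: if the anammox ²⁹N₂ contribution
scales with ε (the natural model when anammox draws on the same labeled
NO₃⁻/NO₂⁻ pool), the classical-IPT apparent D_tot equals (2d+a)²/(2d)
(d, a = denitrification and anammox pair rates) — exactly independent of
ε. The concentration comparison alone therefore cannot reveal anammox; the
pairing diagnostic can. Detection uses the non-binomial ²⁹N₂ excess
p29 − 2√(p28·p30), which is identically zero under binomial pairing, with a
one-sided z test at 2×SE (SE by the delta method from the three slope SEs;
a 10⁻⁹ relative floor absorbs float rounding on noiseless input). The k = 2
threshold mirrors the tissue-detection convention below (≈2.3% one-sided
false-positive rate).

Anammox in the ¹⁵NH₄⁺ + ¹⁴NO₃⁻ treatment is estimated from ²⁹N₂ production
alone: AMX = p29/f_a N₂ pairs h⁻¹ (f_a the ¹⁵N fraction of the NH₄⁺ pool),
×2 for N atoms. ³⁰N₂ production in that treatment is reported but not
interpreted. When detected, anammox can optionally correct D_tot
(`RunConfig.anammox_corrects_dtot`, default off since anammox was assumed
negligible for the sediment cores).

## DNRA

DNRA and denitrification draw on the same NO₃⁻ pool, so the measured
¹⁵NH₄⁺ production scales to total DNRA by the total:labeled reduction
ratio: `DNRA_tot = p¹⁵NH₄⁺ · D_tot/D15` (= p¹⁵NH₄⁺/ε for a well-mixed
pool). The identity `DNRA_tot·D15 = p¹⁵NH₄⁺·D_tot` holds exactly.
DNRA:denitrification ratios are aggregated as ratio-of-means by default
(mean-of-ratios available); the two differ on heterogeneous vessels and
both are reported by the pipeline rather than forced to match any single
summary number.

## N₂ fixation

Single-endpoint two-pool mixing: rate = APE/(A_N2 − A_PN0) · PN/(Δt·W)
with APE the tissue atom% ¹⁵N excess over the mean of unlabeled reference
animals, A_N2 the dissolved-N₂ source atom%, PN the tissue N pool (µmol).
Incorporation counts as detected only when APE strictly exceeds 2×SD of the
reference animals (k configurable); under a Gaussian null this admits
≈2.28% false positives one-sided. δ¹⁵N is converted to atom% with the
atmospheric ratio 0.0036765. The source atom% is a measured/configured
input (the wet-chemistry stock preparation is out of scope), and dilution
of the enriched water by animal-carried water is ignored — a stated
assumption that biases rates low if violated.

## Rank inference

Treatment comparisons use a two-sided Mann–Whitney U test made exact by
enumerating all C(n1+n2, n1) group assignments of the pooled, average-ranked
observations (ties conditioned on the observed pattern; two-sided p =
2×min(one-sided), capped at 1, no mid-p). At the study's group sizes
(3–5) the attainable exact levels are coarse — complete separation at
4 vs 4 gives exactly p = 2/70 ≈ 0.0286 — and the normal approximation is
unreliable, which is why enumeration is the default up to a pooled n of 16;
beyond that the tie-corrected asymptotic test takes over. Slope inference
is the OLS t-test, with perfect fits resolved explicitly (zero residuals:
p = 0 for a nonzero slope, p = 1 for a flat series; two points: p
undefined).

## Upscaling and budget

Biomass-specific holobiont rates scale to areal rates by the areal mussel
biomass (g SFDW m⁻², measured 134 ± 38 in the community cores):
µmol m⁻² h⁻¹ = nmol g⁻¹ h⁻¹ × g m⁻² / 1000. Contribution fractions are
plain percentages of unrounded values (printed comparisons mix rounded
inputs, so agreement is expected at the ~2% level, not digit-exact). The
net-N₂ overestimate when fixation is unaccounted is
100·fix/(denit − fix). Density extrapolation multiplies a per-individual
rate (biomass-specific × mean individual SFDW by default, since all inputs
are printed; directly measured per-individual rates also accepted) by
population density, with min/median/max over a scenario set. The budget
table copies every upstream number (trace ids, no silent recomputation) and
carries a per-condition mass-balance residual defined as N inputs
(fixation) minus N outputs (D_w + D_n + net DIN/DON effluxes) — a
diagnostic of how much N the benthic pool itself supplies, zero for a
self-consistent synthetic budget.

## Synthetic-data generator

The generator produces exactly the structure the estimators assume:
constant true rates, linear accumulation, binomial pairing, anammox routed
by the labeled-atom fraction of the relevant pool (ε under ¹⁵NO₃⁻, f_a
under ¹⁵NH₄⁺, never ³⁰N₂), DNRA ¹⁵NH₄⁺ production at ε × rate, tissue
enrichment by the same mixing equation the rate calculation inverts. Noise
is i.i.d. Gaussian on concentrations (instrument error), not on rates,
matching the linearity premise of the short-incubation design.

Defaults emulate the holobiont incubation conditions: 227 mL microcosm,
37 mg SFDW animal, sampling at 0/3/6/8 h, ε = 0.6, f_a = 0.86 (6.3 µM
¹⁵NH₄⁺ over ≈1 µM ambient), true rates 58.4/31.2/21.9 nmol N g⁻¹ h⁻¹
(denitrification/DNRA/fixation) × the animal biomass, no anammox,
measurement SD = 5% of each series' signal span. N₂ isotopologues start
from air-equilibrium backgrounds (480 µM N₂ split at natural abundance).
Values the study does not print were fixed once at realistic magnitudes:
dissolved-N₂ source enrichment 30 atom%, tissue N content 8% of SFDW,
between-animal natural-abundance tissue SD 4×10⁻⁴ atom% (≈1‰ δ¹⁵N spread,
which reproduces both the universal detection outcome and a per-animal
rate scatter close to the reported SEM), fixation incubation 12 h.
Community-core fixtures use plausible synthetic baseline fluxes (the study
reports core fluxes only graphically); they exercise the comparison
workflow, not absolute reproduction.

What passing tests show: the estimators invert their own generative model
exactly at zero noise and without bias at 5% measurement CV, the detection
filters hold their nominal operating characteristics, and the validity
checks discriminate the failure mode they target. What they do not show:
robustness to non-linear dynamics (substrate depletion, lag phases), N₂
ebullition or headspace exchange, NO₂⁻ pools labeled differently from
NO₃⁻, or rate stimulation by the tracer itself — real-data failure modes
outside the model class.

## Numerical choices and degenerate inputs

- Derived concentrations (NO₃⁻ = NOx⁻ − NO₂⁻, DON = TDN − DIN) clip
  negatives to zero with persistent flags instead of erroring: both
  differences are noise-sensitive near zero.
- p30 within 10⁻¹² of p29's magnitude is treated as zero: D14 becomes an
  `UNDEFINED_D14` flag, not a division blow-up.
- The partition identity D_w + D_n = D_tot is enforced bit-wise by a
  complement fix-up loop after rounding; D_tot = D14 + D15 is exact by
  construction. D_n < 0 floors to zero with a flag (identity then
  intentionally broken and flagged).
- Problem sizes: Monte-Carlo checks use 500 replicates (recovery), 10⁵
  draws (detection null), 4-point series — the whole suite runs in well
  under a minute on one CPU.
- Seeds: every stochastic routine derives its stream from an explicit
  integer seed; identical parameters and seed give bit-identical datasets.

## Known limitations

- One control vessel per treatment means control noise is uncorrected.
- The pooled-vs-per-vessel regression ambiguity is resolved as: per-vessel
  slopes for rates, pooled regression for significance gating; both modes
  exist.
- The budget's residual is a bookkeeping diagnostic, not a process model;
  it ignores burial, advection and storage changes.
- Density extrapolation endpoints depend on the per-individual rate basis;
  published per-animal tables are not consumed.
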