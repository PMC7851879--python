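# nitracer

¹⁵N stable-isotope tracer rate inference for benthic and holobiont
incubations: net solute fluxes, isotope-pairing denitrification
partitioning, DNRA and anammox estimation, ¹⁵N₂-fixation incorporation
rates, exact small-sample rank tests, and nitrogen-budget upscaling —
plus a forward simulator so every inference stage can be verified against
known ground truth.

The package is written for aquatic biogeochemists processing incubation
time series: closed sediment cores and single-animal microcosms amended
with ¹⁵NO₃⁻, ¹⁵NH₄⁺ or dissolved ³⁰N₂, sampled over hours and analyzed
for solutes, N₂ isotopologues (²⁸N₂/²⁹N₂/³⁰N₂) and tissue ¹⁵N.

## The core calculus

After ¹⁵NO₃⁻ addition the nitrate pool carries ¹⁵N mole fraction ε, and
random pairing routes denitrified N₂ as (1−ε)² : 2ε(1−ε) : ε² into
²⁸N₂ : ²⁹N₂ : ³⁰N₂. From the production rates p²⁹ and p³⁰:

```
D15   = p29 + 2·p30              denitrification of ¹⁵NO₃⁻ (N atoms)
D14   = D15 · p29 / (2·p30)      denitrification of ¹⁴NO₃⁻
D_tot = D14 + D15                total denitrification
D_w   = D15 / ε                  water-column-NO₃⁻ fuelled
D_n   = D_tot − D_w              coupled nitrification–denitrification
```

Around it: DNRA_tot = p¹⁵NH₄⁺·D_tot/D15; anammox = p29/f_a under
¹⁵NH₄⁺ + ¹⁴NO₃⁻; fixation = APE/(A_N2 − A_PN0)·PN/(Δt·W); and the r-IPT
validity checks (tracer-concentration independence of D_tot, binomial
pairing consistency p29² = 4·p28·p30). Rates are gated by slope-regression
significance (denitrification p < 0.05, DNRA p < 0.10) and fixation by the
2×SD atom%-excess criterion. See `docs/methods.md` for the full model
description, conventions and limitations.

## Worked example

Simulate a noisy holobiont microcosm (227 mL, 37 mg SFDW animal, ε = 0.6,
true denitrification 58.4 nmol N g⁻¹ h⁻¹, 5% measurement CV) and invert it:

```python
from nitracer import (TrueParameters, simulate_n2_series,
                      isotopologue_slopes, ipt_partition, Analyte)

p = TrueParameters(noise_cv=0.05, seed=11)
ser = simulate_n2_series(p)
r = isotopologue_slopes(ser[Analyte.N2_29], ser[Analyte.N2_30], p.vessel)
panel = ipt_partition(r, p.epsilon)
print(f"D15 = {panel.d15:.1f}, D14 = {panel.d14:.1f}, "
      f"D_tot = {panel.d_tot:.1f} nmol N g^-1 h^-1")
```

```
D15 = 34.5, D14 = 23.4, D_tot = 57.9 nmol N g^-1 h^-1
```

One noisy 4-point realization recovers the true total (58.4) to within a
percent; its components split according to the labeling fraction actually
realized in the noise. Upscaling the published holobiont means
(31.2 nmol DNRA, 58.4 denitrification, 21.9 fixation, all per g SFDW per
hour) to the measured colony biomass of 134 g SFDW m⁻²:

```python
from nitracer import (areal_from_specific, contribution_fraction,
                      net_n2_overestimate)

areal_dnra = areal_from_specific(31.2, 134.0)      # 4.18 µmol m⁻² h⁻¹
share = contribution_fraction(areal_dnra, 5.7)     # 73 % of the increment
fix_vs_denit = contribution_fraction(21.9, 58.4)   # 37.5 %
overest = net_n2_overestimate(58.4, 21.9)          # 60.0 %
```

meaning: the mussel holobiont alone accounts for ~4.2 µmol m⁻² h⁻¹ of
DNRA — about three quarters of the whole-community DNRA increase the
mussels cause — its N₂ fixation runs at 37% of its denitrification, and
ignoring that fixation would overstate the holobiont's net N₂ efflux by
60%.

## Command line

Each stage is also a subcommand writing auditable CSVs plus a JSON run
manifest (config snapshot, input digests, seed):

```
nitracer simulate --seed 42 --out-dir fixtures/
nitracer fluxes --input table.csv --geometry geom.csv --out fluxes.csv
nitracer ipt --input n2.csv --geometry geom.csv --tracer tracer.yaml --out panel.csv
nitracer dnra --input nh4.csv --geometry geom.csv --panel panel.csv --out dnra.csv
nitracer fix --tissue tissue.csv --out fixation.csv
nitracer stats --x 1,2,3,4 --y 5,6,7,8
nitracer budget --fluxes fluxes.csv --panels panel.csv --dnra dnra.csv \
                --fix fixation.csv --biomass 134 --out budget.csv
nitracer run --seed 42 --work-dir work/
```

Exit codes: 0 ok, 1 validation error, 2 computation error.

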