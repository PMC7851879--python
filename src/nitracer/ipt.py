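"""Isotope-pairing computation of denitrification, its partition, the
revised-IPT validity checks, and anammox estimation.

After ¹⁵NO₃⁻ addition the nitrate pool carries a ¹⁵N mole fraction ε, and
random (binomial) pairing of the two N atoms of each N₂ molecule produced by
denitrification routes the N₂ pairs as (1−ε)² : 2ε(1−ε) : ε² into
²⁸N₂ : ²⁹N₂ : ³⁰N₂.  From the measured production rates p29 and p30 the
classical pairing calculus gives

    D15   = p29 + 2·p30                (denitrification of ¹⁵NO₃⁻, N atoms)
    D14   = D15 · p29 / (2·p30)        (denitrification of ¹⁴NO₃⁻)
    D_tot = D14 + D15
    D_w   = D15 / ε                    (water-column-NO₃⁻-fuelled, both isotopes)
    D_n   = D_tot − D_w                (coupled nitrification–denitrification)

The revised technique additionally checks the assumptions: rate
independence of the tracer concentration (two addition levels) and binomial
consistency of the isotopologue triplet, p29² / (4·p28·p30) = 1 for pure
denitrification.  Anammox pairs one NH₄⁺-derived with one NO₂⁻/NO₃⁻-derived
atom and therefore produces a non-binomial ²⁹N₂ excess that drives the
ratio above 1 — notably, with an anammox contribution that scales with ε
the apparent D_tot stays exactly ε-invariant (the ε-dependence of D14 and
D15 cancels), so the pairing-consistency diagnostic, not the concentration
comparison, is what detects anammox here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .datamodel import (
    IncubationSeries,
    RunConfig,
    ValidationError,
    VesselGeometry,
    VesselKind,
)
from .stats import pooled_slope_p, slope_test


class PanelFlag(str, enum.Enum):
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
    UNDEFINED_D14 = "UNDEFINED_D14"
    DN_FLOORED = "DN_FLOORED"
    P_UNDEFINED = "P_UNDEFINED"
    CHECK_SKIPPED = "CHECK_SKIPPED"


@dataclass
class IsotopologueRate:
    """One isotopologue production rate with regression inference."""

    rate: float  # N₂ units per hour on the normalizer basis
    se: float
    p_value: float


@dataclass
class IsotopologueRates:
    """Production rates of ²⁹N₂ and ³⁰N₂ (optionally ²⁸N₂).

    Rates are N₂ (pair) units per hour on the vessel's normalizer basis:
    µmol N₂ m⁻² h⁻¹ for cores, nmol N₂ g_SFDW⁻¹ h⁻¹ for microcosms, or raw
    µM N₂ h⁻¹ when no geometry is supplied.  Rates may be negative before
    significance gating.
    """

    p29: IsotopologueRate
    p30: IsotopologueRate
    p28: IsotopologueRate | None = None
    normalizer: str = "volume"  # "areal" | "biomass" | "volume"
    pooled_p: float = math.nan


def _rate_scale(geom: VesselGeometry | None) -> tuple[float, str]:
    if geom is None:
        return 1.0, "volume"
    if geom.kind is VesselKind.CORE:
        return geom.water_volume_l / geom.sediment_area_m2, "areal"
    if geom.biomass_sfdw_g <= 0:
        raise ValidationError("microcosm normalization needs biomass_sfdw_g > 0")
    return geom.water_volume_l / geom.biomass_sfdw_g * 1000.0, "biomass"


def _one_rate(series: IncubationSeries, control: IncubationSeries | None, scale: float) -> IsotopologueRate:
    if series.n < 2:
        raise ValidationError("isotopologue slope needs >= 2 points")
    slope, se, result = slope_test(series.times, series.concentrations)
    if control is not None:
        c_slope, _, _ = slope_test(control.times, control.concentrations)
        slope = slope - c_slope
    return IsotopologueRate(rate=slope * scale, se=se * scale, p_value=result.p_two_sided)


def isotopologue_slopes(
    series29: IncubationSeries,
    series30: IncubationSeries,
    geom: VesselGeometry | None = None,
    control29: IncubationSeries | None = None,
    control30: IncubationSeries | None = None,
    series28: IncubationSeries | None = None,
    replicates29: list[IncubationSeries] | None = None,
    replicates30: list[IncubationSeries] | None = None,
) -> IsotopologueRates:
    """Per-isotopologue regression slopes converted to production rates.

    Each slope is an OLS fit over the vessel's time series (two points: the
    finite difference, with p undefined).  When replicate series are passed,
    a pooled "whole dataset" regression over all their points supplies the
    significance p-value used for gating, while the per-vessel slopes carry
    the rates.
    """
    scale, normalizer = _rate_scale(geom)
    p29 = _one_rate(series29, control29, scale)
    p30 = _one_rate(series30, control30, scale)
    p28 = _one_rate(series28, None, scale) if series28 is not None else None
    pooled = math.nan
    if replicates29 or replicates30:
        pools = []
        if replicates29:
            pools.append(pooled_slope_p(replicates29))
        if replicates30:
            pools.append(pooled_slope_p(replicates30))
        pooled = max(pools)  # both isotopologues must rise significantly
    return IsotopologueRates(p29=p29, p30=p30, p28=p28, normalizer=normalizer, pooled_p=pooled)


@dataclass
class DenitPanel:
    """The IPT output panel: D15, D14, D_tot, D_w, D_n (N-atom rates)."""

    d15: float
    d14: float
    d_tot: float
    d_w: float
    d_n: float
    epsilon_w: float
    significant: bool
    dn_dw_ratio: float = math.nan
    normalizer: str = "volume"
    flags: set[PanelFlag] = field(default_factory=set)


# Below this fraction of |p29|, a ³⁰N₂ slope is numerically zero and D14 is
# undefined rather than a division blow-up.
_P30_GUARD = 1e-12


def ipt_partition(
    rates: IsotopologueRates,
    epsilon_w: float,
    config: RunConfig | None = None,
) -> DenitPanel:
    """Partition total denitrification from the ²⁹/³⁰N₂ production rates.

    A panel whose pooled regression p (when available) is at or above the
    denitrification alpha is marked not significant and reported as zeros
    with a NOT_SIGNIFICANT flag — a non-detection, not a missing vessel.
    """
    config = config or RunConfig()
    if epsilon_w <= 0 or epsilon_w > 1:
        raise ValidationError("epsilon_w must be in (0, 1]")
    p29, p30 = rates.p29.rate, rates.p30.rate
    flags: set[PanelFlag] = set()

    gate_p = rates.pooled_p
    if math.isnan(gate_p):
        candidates = [p for p in (rates.p29.p_value, rates.p30.p_value) if not math.isnan(p)]
        gate_p = max(candidates) if candidates else math.nan
    if math.isnan(gate_p):
        flags.add(PanelFlag.P_UNDEFINED)
        significant = True  # cannot gate without a p-value; annotate instead
    else:
        significant = gate_p < config.significance_alpha_denit

    if not significant:
        flags.add(PanelFlag.NOT_SIGNIFICANT)
        return DenitPanel(0.0, 0.0, 0.0, 0.0, 0.0, epsilon_w, False,
                          dn_dw_ratio=math.nan, normalizer=rates.normalizer, flags=flags)

    d15 = p29 + 2.0 * p30
    if p30 <= _P30_GUARD * abs(p29):
        flags.add(PanelFlag.UNDEFINED_D14)
        return DenitPanel(d15, math.nan, math.nan, math.nan, math.nan, epsilon_w,
                          True, normalizer=rates.normalizer, flags=flags)
    d14 = d15 * p29 / (2.0 * p30)
    d_tot = d14 + d15
    d_w = d15 / epsilon_w
    d_n = d_tot - d_w
    if d_n < 0:
        flags.add(PanelFlag.DN_FLOORED)
        d_n = 0.0
    else:
        # enforce the exact partition identity d_w + d_n == d_tot despite
        # floating-point rounding of the complement
        for _ in range(5):
            if d_w + d_n == d_tot:
                break
            d_w = d_tot - d_n
            d_n = d_tot - d_w
    ratio = d_n / d_w if d_w > 0 else math.nan
    return DenitPanel(d15, d14, d_tot, d_w, d_n, epsilon_w, True,
                      dn_dw_ratio=ratio, normalizer=rates.normalizer, flags=flags)


def pairing_consistency(rates: IsotopologueRates) -> float:
    """Binomial pairing diagnostic p29² / (4·p28·p30).

    Equals 1 for noiseless binomially paired production; a non-binomial
    ²⁹N₂ source (anammox) drives it above 1.  Requires p28.
    """
    if rates.p28 is None:
        raise ValidationError("pairing consistency requires a ²⁸N₂ production rate")
    denom = 4.0 * rates.p28.rate * rates.p30.rate
    if denom <= 0:
        return math.nan
    return rates.p29.rate**2 / denom


# z threshold for declaring the ²⁹N₂ excess non-binomial (one-sided,
# ≈2.3% false-positive rate — the same k = 2 convention the fixation
# detection rule uses).
PAIRING_EXCESS_Z = 2.0


def pairing_excess(rates: IsotopologueRates) -> tuple[float, float]:
    """Non-binomial ²⁹N₂ excess production and its standard error.

    Under binomial pairing p29 = 2·√(p28·p30) exactly, so the excess
    p29 − 2·√(p28·p30) is zero for pure denitrification and equals the
    extra ²⁹N₂ a non-random pairing source (anammox) contributes.  The SE
    propagates the three slope SEs by the delta method.
    """
    if rates.p28 is None:
        raise ValidationError("pairing excess requires a ²⁸N₂ production rate")
    p28, p29, p30 = rates.p28.rate, rates.p29.rate, rates.p30.rate
    if p28 <= 0 or p30 <= 0:
        return math.nan, math.nan
    excess = p29 - 2.0 * math.sqrt(p28 * p30)
    var = (
        rates.p29.se**2
        + (p30 / p28) * rates.p28.se**2
        + (p28 / p30) * rates.p30.se**2
    )
    return excess, math.sqrt(var)


@dataclass
class IndependenceReport:
    """Outcome of the r-IPT validity check across tracer levels."""

    passed: bool
    dtot_rel_diff: float
    dnra_rel_diff: float = math.nan
    pairing_ratio_low: float = math.nan
    pairing_ratio_high: float = math.nan
    flags: set[PanelFlag] = field(default_factory=set)


def independence_check(
    panel_low: DenitPanel,
    panel_high: DenitPanel,
    tol: float | None = None,
    dnra_low: float | None = None,
    dnra_high: float | None = None,
    rates_low: IsotopologueRates | None = None,
    rates_high: IsotopologueRates | None = None,
    config: RunConfig | None = None,
) -> IndependenceReport:
    """Check the r-IPT assumptions between low and high ¹⁵NO₃⁻ additions.

    Passes when |D_tot_low − D_tot_high| / mean ≤ tol (likewise for DNRA
    when supplied) AND, when ²⁸N₂ rates are available, the ²⁹N₂ excess over
    the binomial prediction 2·√(p28·p30) is not detected (one-sided z test
    at 2×SE) in either treatment.  The pairing diagnostic is essential: an
    anammox ²⁹N₂ excess that scales with ε leaves D_tot exactly
    tracer-level-invariant, so the concentration comparison alone cannot
    reveal it.
    """
    config = config or RunConfig()
    tol = config.independence_tolerance if tol is None else tol
    flags: set[PanelFlag] = set()
    if not (panel_low.significant and panel_high.significant):
        flags.add(PanelFlag.CHECK_SKIPPED)
        return IndependenceReport(False, math.nan, flags=flags)

    def rel_diff(a: float, b: float) -> float:
        mean = 0.5 * (a + b)
        if mean == 0:
            return 0.0 if a == b else math.inf
        return abs(a - b) / mean

    d_diff = rel_diff(panel_low.d_tot, panel_high.d_tot)
    passed = d_diff <= tol
    dnra_diff = math.nan
    if dnra_low is not None and dnra_high is not None:
        dnra_diff = rel_diff(dnra_low, dnra_high)
        passed = passed and dnra_diff <= tol
    ratio_low = ratio_high = math.nan
    for which, rates in (("low", rates_low), ("high", rates_high)):
        if rates is None or rates.p28 is None:
            continue
        ratio = pairing_consistency(rates)
        if which == "low":
            ratio_low = ratio
        else:
            ratio_high = ratio
        excess, se = pairing_excess(rates)
        if math.isnan(excess):
            continue
        # one-sided z detection of a non-binomial ²⁹N₂ source; with zero
        # noise any positive excess beyond float rounding fails the
        # binomial assumption
        if excess > max(PAIRING_EXCESS_Z * se, 1e-9 * abs(rates.p29.rate)):
            passed = False
    return IndependenceReport(passed, d_diff, dnra_diff, ratio_low, ratio_high, flags)


@dataclass
class AnammoxResult:
    """Anammox N₂ production attributed from ²⁹N₂ in the ¹⁵NH₄⁺ treatment."""

    rate_n2: float  # N₂ pairs per hour on the normalizer basis
    rate_n: float  # N atoms (2× pairs)
    detected: bool
    p_value: float
    p30_rate: float  # reported, not interpreted (coupled-process diagnostic)


def anammox_rate(
    rates: IsotopologueRates,
    f_a: float,
    config: RunConfig | None = None,
) -> AnammoxResult:
    """Anammox rate from ²⁹N₂ production under ¹⁵NH₄⁺ + ¹⁴NO₃⁻.

    Anammox pairs one NH₄⁺-derived atom (labeled with fraction f_a) with one
    NO₂⁻/NO₃⁻-derived atom (unlabeled), so the total anammox N₂ production
    is p29 / f_a.  Detection requires a significant positive ²⁹N₂ slope;
    otherwise the rate is reported as 0 (a non-detection).
    """
    config = config or RunConfig()
    if f_a <= 0 or f_a > 1:
        raise ValidationError("f_a must be in (0, 1]")
    p29 = rates.p29
    p = rates.pooled_p if not math.isnan(rates.pooled_p) else p29.p_value
    # without a p-value (2-point series or directly constructed rates) the
    # gate cannot be applied; fall back to the sign criterion alone
    detected = p29.rate > 0 and (math.isnan(p) or p < config.significance_alpha_denit)
    pairs = p29.rate / f_a if detected else 0.0
    return AnammoxResult(
        rate_n2=pairs,
        rate_n=2.0 * pairs,
        detected=detected,
        p_value=p,
        p30_rate=rates.p30.rate,
    )
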