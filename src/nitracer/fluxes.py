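"""Net solute and O₂ fluxes from incubation time series.

Sign convention: positive = release to the water column (efflux), negative
= uptake.  Core fluxes are areal (µmol m⁻² h⁻¹); microcosm rates are
biomass-specific (nmol g_SFDW⁻¹ h⁻¹) after subtracting the water-only
control.  Dark incubations are kept short enough that concentrations change
linearly; the ≤20% O₂-drawdown rule guards that assumption and is reported
as a QC flag, never by suppressing the rate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    Analyte,
    FluxMode,
    IncubationSeries,
    RunConfig,
    ValidationError,
    VesselGeometry,
    VesselKind,
)
from .stats import slope_test


class QcFlag(str, enum.Enum):
    O2_DRAWDOWN_EXCEEDED = "O2_DRAWDOWN_EXCEEDED"
    NONLINEAR = "NONLINEAR"
    CONTROL_CORRECTED = "CONTROL_CORRECTED"


@dataclass
class NetFlux:
    """A net flux with its standard error and QC annotations.

    value/se are µmol m⁻² h⁻¹ for cores and nmol g_SFDW⁻¹ h⁻¹ for
    microcosms; positive = efflux.
    """

    analyte: Analyte
    value: float
    se: float
    basis: str  # "areal" | "biomass"
    p_slope: float = math.nan
    qc_flags: set[QcFlag] = field(default_factory=set)


# Fraction of variance a straight line must explain before a >2-point series
# is flagged NONLINEAR (diagnostic only).
_LINEARITY_R2_FLOOR = 0.95


def _series_slope(series: IncubationSeries, mode: FluxMode):
    """Concentration slope (µM h⁻¹), its SE, slope-test p and linearity R²."""
    t, c = series.as_arrays()
    if series.n < 2:
        raise ValidationError(
            f"vessel {series.vessel_id}: rate estimation needs >= 2 samples"
        )
    if series.n == 2 or mode is FluxMode.ENDPOINT:
        slope = (c[-1] - c[0]) / (t[-1] - t[0])
        return float(slope), 0.0, math.nan, 1.0
    slope, se, result = slope_test(t, c)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        resid = c - (c.mean() + slope * (t - t.mean()))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return slope, se, result.p_two_sided, r2


def _o2_drawdown_exceeded(series: IncubationSeries, limit: float) -> bool:
    """True if O₂ changed by more than `limit` relative to the start."""
    c = np.asarray(series.concentrations)
    if c[0] <= 0:
        return True
    return bool(np.max(np.abs(c - c[0])) / c[0] > limit)


def net_flux_core(
    series: IncubationSeries,
    geom: VesselGeometry,
    config: RunConfig | None = None,
) -> NetFlux:
    """Areal net flux across the sediment–water interface of a closed core.

    flux = slope(concentration vs time) × water_volume / sediment_area,
    with the slope from OLS over all samples (finite difference for two).
    The standard error propagates the slope SE through the same scaling.
    """
    config = config or RunConfig()
    if geom.kind is not VesselKind.CORE:
        raise ValidationError("net_flux_core requires a core geometry")
    if not geom.sediment_area_m2:
        raise ValidationError("core sediment area must be > 0")
    slope, se, p, r2 = _series_slope(series, config.flux_mode)
    scale = geom.water_volume_l / geom.sediment_area_m2
    flags: set[QcFlag] = set()
    if series.analyte is Analyte.O2 and _o2_drawdown_exceeded(series, config.o2_drawdown_limit):
        flags.add(QcFlag.O2_DRAWDOWN_EXCEEDED)
    if r2 < _LINEARITY_R2_FLOOR:
        flags.add(QcFlag.NONLINEAR)
    return NetFlux(
        analyte=series.analyte,
        value=slope * scale,
        se=se * scale,
        basis="areal",
        p_slope=p,
        qc_flags=flags,
    )


def net_flux_microcosm(
    series: IncubationSeries,
    geom: VesselGeometry,
    control: IncubationSeries | None = None,
    config: RunConfig | None = None,
) -> NetFlux:
    """Biomass-specific net rate in a sediment-free microcosm.

    rate = (sample slope − control slope) × water_volume / biomass, in
    nmol g_SFDW⁻¹ h⁻¹.  The single shared control contributes no SE (one
    vessel per treatment); negative corrected rates are returned as-is.
    """
    config = config or RunConfig()
    if geom.kind is not VesselKind.MICROCOSM:
        raise ValidationError("net_flux_microcosm requires a microcosm geometry")
    if geom.biomass_sfdw_g <= 0:
        raise ValidationError("microcosm biomass_sfdw_g must be > 0")
    slope, se, p, r2 = _series_slope(series, config.flux_mode)
    flags: set[QcFlag] = set()
    if control is not None and config.control_correct_microcosms:
        c_slope, _, _, _ = _series_slope(control, config.flux_mode)
        slope = slope - c_slope
        flags.add(QcFlag.CONTROL_CORRECTED)
    if r2 < _LINEARITY_R2_FLOOR:
        flags.add(QcFlag.NONLINEAR)
    scale = geom.water_volume_l / geom.biomass_sfdw_g * 1000.0  # µM·L → nmol/g
    return NetFlux(
        analyte=series.analyte,
        value=slope * scale,
        se=se * scale,
        basis="biomass",
        p_slope=p,
        qc_flags=flags,
    )


def dilution_correct(
    series: IncubationSeries,
    withdrawals: list[tuple[float, float, float]],
    vessel_volume_l: float,
) -> IncubationSeries:
    """Correct a series for subsampling withdrawals replaced with new water.

    Each withdrawal is (time_h, volume_removed_L, replacement_concentration_uM)
    and must coincide with a sampling time (the measured concentration is
    taken as the pre-withdrawal state).  The returned series accumulates the
    production-only concentration changes: the step introduced by each
    replacement-water mixing event is removed from every later reading, so a
    regression on the corrected series recovers the production rate.
    """
    if any(v >= vessel_volume_l for _, v, _ in withdrawals):
        raise ValidationError("withdrawal volume must be < vessel volume")
    times = list(series.times)
    raw = list(series.concentrations)
    events = sorted(withdrawals)
    for wt, _, _ in events:
        if wt not in times:
            raise ValidationError(f"withdrawal at t={wt} h is not a sampling time")

    corrected = [raw[0]]
    # Mass ledger: walk sample-to-sample; a withdrawal at t_i resets the
    # post-mixing concentration, and the next increment above that state is
    # pure production.
    post_state = raw[0]
    by_time: dict[float, list[tuple[float, float]]] = {}
    for wt, vol, repl in events:
        by_time.setdefault(wt, []).append((vol, repl))
    for vol, repl in by_time.get(times[0], []):
        f = vol / vessel_volume_l
        post_state = post_state * (1 - f) + repl * f
    for i in range(1, len(times)):
        production = raw[i] - post_state
        corrected.append(corrected[-1] + production)
        post_state = raw[i]
        for vol, repl in by_time.get(times[i], []):
            f = vol / vessel_volume_l
            post_state = post_state * (1 - f) + repl * f
    if min(corrected) < 0:
        corrected = [max(c, 0.0) for c in corrected]
    return IncubationSeries(
        vessel_id=series.vessel_id,
        analyte=series.analyte,
        times=tuple(times),
        concentrations=tuple(corrected),
    )
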