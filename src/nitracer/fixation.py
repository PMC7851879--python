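"""N₂-fixation rates from ¹⁵N₂ incorporation into tissue.

A single-endpoint tracer design: animals incubate in ³⁰N₂-enriched water,
tissue is analyzed for atom% ¹⁵N, and the incorporation rate follows the
standard two-pool mixing calculation

    rate = (A_PN(t) − A_PN(0)) / (A_N2 − A_PN(0)) × PN / Δt

normalized to shell-free dry weight.  Incorporation counts as detected only
when the atom% excess exceeds k×SD of unlabeled reference animals (k = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .datamodel import ValidationError

# Atmospheric ¹⁵N/¹⁴N isotope ratio (air-N₂ standard) used to convert the
# instrument's δ¹⁵N to atom%.
R_AIR_15N14N = 0.0036765


@dataclass(frozen=True)
class FixationSample:
    """Tissue isotope data for one incubated animal.

    a_pn_t: tissue atom% ¹⁵N after incubation; a_pn_0 / sd_unlabeled: mean
    and SD of natural-abundance tissue atom% from unlabeled reference
    animals; a_n2: dissolved-N₂ source atom% ¹⁵N; pn: tissue N pool
    (µmol N); dt: incubation duration (h); sfdw: biomass (g).
    """

    a_pn_t: float
    a_pn_0: float
    sd_unlabeled: float
    a_n2: float
    pn: float
    dt: float
    sfdw: float

    def __post_init__(self) -> None:
        for name in ("a_pn_t", "a_pn_0", "a_n2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must be an atom% in [0, 100]")
        if self.sd_unlabeled < 0:
            raise ValidationError("sd_unlabeled must be >= 0")
        if self.dt <= 0 or self.pn <= 0 or self.sfdw <= 0:
            raise ValidationError("dt, pn and sfdw must be > 0")


def delta15n_to_atom_percent(delta15n: float) -> float:
    """Convert δ¹⁵N (‰ vs air) to atom% ¹⁵N.

    atom% = 100·R/(1+R) with R = (δ/1000 + 1)·R_air.
    """
    r = (delta15n / 1000.0 + 1.0) * R_AIR_15N14N
    return 100.0 * r / (1.0 + r)


def atom_percent_excess(sample: FixationSample) -> float:
    """Tissue atom% ¹⁵N above the unlabeled reference mean (sign preserved)."""
    return sample.a_pn_t - sample.a_pn_0


def detect_incorporation(ape: float, sd_unlabeled: float, k: float = 2.0) -> bool:
    """True iff the atom% excess strictly exceeds k×SD of unlabeled tissue."""
    if sd_unlabeled < 0:
        raise ValidationError("sd_unlabeled must be >= 0")
    return ape > k * sd_unlabeled


def fixation_rate(sample: FixationSample) -> float:
    """¹⁵N₂ incorporation rate in nmol N g_SFDW⁻¹ h⁻¹.

    The source pool must be enriched above tissue natural abundance
    (a_n2 > a_pn_0).  At full equilibration (a_pn_t = a_n2) the rate tops
    out at pn/(dt·sfdw).
    """
    if sample.a_n2 <= sample.a_pn_0:
        raise ValidationError("source N₂ atom% must exceed tissue natural abundance")
    ape = atom_percent_excess(sample)
    rate_umol_per_g_h = ape / (sample.a_n2 - sample.a_pn_0) * sample.pn / sample.dt / sample.sfdw
    return rate_umol_per_g_h * 1000.0  # µmol → nmol


def per_individual_rate(sample: FixationSample) -> float:
    """Rate per animal (nmol N ind⁻¹ h⁻¹): biomass-specific rate × sfdw."""
    return fixation_rate(sample) * sample.sfdw
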