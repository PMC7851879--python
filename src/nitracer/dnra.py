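"""DNRA rate from ¹⁵NH₄⁺ production scaled to the total NO₃⁻ pool.

Dissimilatory nitrate reduction to ammonium draws on the same NO₃⁻ pool as
denitrification, so the measured ¹⁵NH₄⁺ production (the labeled share of
DNRA) scales to the total by the same total:labeled nitrate-reduction ratio
the denitrification panel provides:

    DNRA_tot = p¹⁵NH₄⁺ · D_tot / D15

which for a well-mixed pool equals p¹⁵NH₄⁺ / ε.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .datamodel import RunConfig, ValidationError
from .ipt import DenitPanel


@dataclass
class DnraResult:
    """DNRA rates on the vessel normalizer basis.

    dnra15 is the measured ¹⁵NH₄⁺ production rate; dnra_total the inferred
    total DNRA; significance is gated at the DNRA alpha (default 0.10).
    """

    dnra15: float
    dnra_total: float
    significant: bool
    p_value: float = math.nan
    normalizer: str = "volume"
    flags: set[str] = field(default_factory=set)


def dnra_total(
    p15nh4: float,
    panel: DenitPanel,
    p_value: float = math.nan,
    config: RunConfig | None = None,
) -> DnraResult:
    """Scale measured ¹⁵NH₄⁺ production to total DNRA via D_tot / D15.

    Raises when the panel has no labeled nitrate reduction (D15 = 0) to
    scale by.  A regression p at or above the DNRA alpha zeroes the result
    with a NOT_SIGNIFICANT flag (non-detection).
    """
    config = config or RunConfig()
    if panel.d15 <= 0:
        raise ValidationError("DNRA scaling requires D15 > 0")
    flags: set[str] = set()
    if math.isnan(p_value):
        flags.add("P_UNDEFINED")
        significant = True
    else:
        significant = p_value < config.significance_alpha_dnra
    if not significant:
        flags.add("NOT_SIGNIFICANT")
        return DnraResult(0.0, 0.0, False, p_value, panel.normalizer, flags)
    total = p15nh4 * (panel.d_tot / panel.d15)
    return DnraResult(p15nh4, total, True, p_value, panel.normalizer, flags)


def dnra_to_denit(dnra: DnraResult, panel: DenitPanel) -> float:
    """Ratio of total DNRA to total denitrification (NaN when D_tot = 0)."""
    if not panel.d_tot or math.isnan(panel.d_tot):
        return math.nan
    return dnra.dnra_total / panel.d_tot


def ratio_of_means(dnra_rates, denit_rates) -> float:
    """mean(DNRA) / mean(denitrification) across vessels (default aggregation)."""
    import numpy as np

    d = float(np.mean(np.asarray(list(dnra_rates), dtype=float)))
    w = float(np.mean(np.asarray(list(denit_rates), dtype=float)))
    return d / w if w else math.nan


def mean_of_ratios(dnra_rates, denit_rates) -> float:
    """mean of per-vessel DNRA:denitrification ratios (vessels with zero
    denitrification are excluded)."""
    import numpy as np

    d = np.asarray(list(dnra_rates), dtype=float)
    w = np.asarray(list(denit_rates), dtype=float)
    mask = w != 0
    if not mask.any():
        return math.nan
    return float(np.mean(d[mask] / w[mask]))
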