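"""Percent-variation metrics linking principal components to geometry.

For each retained principal component the ±2σ shapes are reconstructed, the
five geometric parameters are extracted from both, and their spread is
summarized as a percentage of their mean magnitude:

    var% = |p(+2σ) - p(-2σ)| / ((|p(+2σ)| + |p(-2σ)|) / 2) * 100

Variations under 5% are flagged negligible; for each parameter the component
with the largest var% is highlighted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CanalSSMError, FeatureError
from .features import DEFAULT_SPACING_MM, canal_features
from .ssm import DEFAULT_N_PCS, SSMModel, reconstruct_mode

log = logging.getLogger(__name__)

#: Variations below this percentage are considered negligible.
NEGLIGIBLE_PCT = 5.0

PARAMETERS = ("La", "Rc", "ell", "davg", "con")


def percent_variation(p_plus: float, p_minus: float) -> float:
    """Absolute difference over mean magnitude, as a percentage.

    Both values zero (or both at the straight sentinel for Rc) gives 0 by
    convention; one sentinel against a finite value is indeterminate (NaN).
    """
    inf_p, inf_m = math.isinf(p_plus), math.isinf(p_minus)
    if inf_p and inf_m:
        return 0.0
    if inf_p or inf_m:
        return math.nan
    avg = (abs(p_plus) + abs(p_minus)) / 2.0
    if avg == 0.0:          # both zero (or subnormal underflow): no variation
        return 0.0
    return abs(p_plus - p_minus) / avg * 100.0


@dataclass
class VariationTable:
    """Per-PC, per-parameter ±2σ values and percent variations for one segment."""

    fraction: float | None
    table: pd.DataFrame                 # columns: pc, parameter, value_minus, value_plus, range, var_pct, negligible
    highlights: dict = field(default_factory=dict)   # parameter -> PC with max var%
    negligible_pct: float = NEGLIGIBLE_PCT


def variation_table(model: SSMModel, n_pcs: int = DEFAULT_N_PCS,
                    spacing: float = DEFAULT_SPACING_MM,
                    negligible_pct: float = NEGLIGIBLE_PCT) -> VariationTable:
    """Reconstruct ±2σ shapes for the first `n_pcs` components and tabulate
    the variation of the five geometric parameters along each.

    Feature failures on a mode shape leave that PC's cells missing (NaN) but
    still produce a table. Indeterminate Rc cells (straight sentinel against a
    finite radius) are logged and carry NaN var%.
    """
    n_pcs = min(n_pcs, len(model.eigenvalues))
    rows = []
    for pc in range(1, n_pcs + 1):
        feats = {}
        for s, tag in ((-2.0, "minus"), (+2.0, "plus")):
            try:
                feats[tag] = canal_features(reconstruct_mode(model, pc, s),
                                            spacing).as_dict()
            except (FeatureError, CanalSSMError) as exc:
                log.warning("feature extraction failed on PC%d %s2σ shape: %s",
                            pc, tag, exc)
                feats[tag] = None
        for param in PARAMETERS:
            if feats["minus"] is None or feats["plus"] is None:
                vm = vp = rng = var = math.nan
            else:
                vm, vp = feats["minus"][param], feats["plus"][param]
                var = percent_variation(vp, vm)
                rng = abs(vp - vm) if np.isfinite(vp) and np.isfinite(vm) else math.nan
                if math.isnan(var) and param == "Rc":
                    log.warning("PC%d: Rc indeterminate (straight sentinel against "
                                "finite radius); excluded from highlights", pc)
            rows.append({"pc": pc, "parameter": param, "value_minus": vm,
                         "value_plus": vp, "range": rng, "var_pct": var,
                         "negligible": bool(var < negligible_pct)
                         if not math.isnan(var) else False})
    df = pd.DataFrame(rows)
    highlights = {}
    for param in PARAMETERS:
        sub = df[(df.parameter == param) & df.var_pct.notna()]
        if len(sub):
            best = sub.loc[sub.var_pct.idxmax()]
            # ties broken toward the lower PC index by idxmax on the ordered frame
            highlights[param] = int(best.pc)
    return VariationTable(fraction=model.fraction, table=df,
                          highlights=highlights, negligible_pct=negligible_pct)
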