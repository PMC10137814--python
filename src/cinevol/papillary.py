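"""Closed-form papillary-muscle volume estimators.

If the only difference between a contour-surface (KfM) reading and a
pixel-based (PbM) reading of the same ventricle is the papillary muscle
volume PM, then ESV_KfM - PM = ESV_PbM and EDV_KfM - PM = EDV_PbM, the
stroke volumes of the two methods coincide, and PM can be recovered four
ways:

    PM1 = EDV_KfM - SV_KfM / EF_PbM
    PM2 = SV_PbM / EF_KfM - EDV_PbM
    PM3 = EDV_KfM - EDV_PbM
    PM4 = ESV_KfM - ESV_PbM

with EF as a fraction.  On algebraically consistent inputs all four agree
exactly; on measured data their spread reflects measurement error, and the
arithmetic mean is the reported estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .volumetry import FunctionParams

__all__ = ["PMEstimates", "estimate_pm", "aggregate_pm_table", "format_pm_table"]

_FORMULA_COLUMNS = ["PM1", "PM2", "PM3", "PM4"]


@dataclass(frozen=True)
class PMEstimates:
    """The four papillary-volume estimates (mL) and their mean."""

    pm1: float
    pm2: float
    pm3: float
    pm4: float

    @property
    def mean_pm(self) -> float:
        return (self.pm1 + self.pm2 + self.pm3 + self.pm4) / 4.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.pm1, self.pm2, self.pm3, self.pm4)


def estimate_pm(kfm: FunctionParams, pbm: FunctionParams) -> PMEstimates:
    """Papillary muscle volume from paired contour and pixel-based readings."""
    for p in (kfm, pbm):
        if not (0.0 < p.ef <= 1.0):
            raise ValueError(f"EF of {p.method} must be in (0, 1]; got {p.ef}")
        if p.edv_ml < 0 or p.esv_ml < 0:
            raise ValueError("volumes must be non-negative")
    pm1 = kfm.edv_ml - kfm.sv_ml / pbm.ef
    pm2 = pbm.sv_ml / kfm.ef - pbm.edv_ml
    pm3 = kfm.edv_ml - pbm.edv_ml
    pm4 = kfm.esv_ml - pbm.esv_ml
    return PMEstimates(pm1=pm1, pm2=pm2, pm3=pm3, pm4=pm4)


def aggregate_pm_table(
    per_method_estimates: Mapping[str, Sequence[PMEstimates] | PMEstimates],
) -> pd.DataFrame:
    """Per-formula, per-method and grand means of papillary estimates.

    Accepts one or more :class:`PMEstimates` per method (several subjects are
    averaged per formula first).  The returned table has one row per method
    plus a "Mean" row, columns PM1..PM4 plus a "Mean" column; values are
    unrounded — use :func:`format_pm_table` for presentation.
    """
    if not per_method_estimates:
        raise ValueError("need at least one method row")
    rows = {}
    for method, ests in per_method_estimates.items():
        if isinstance(ests, PMEstimates):
            ests = [ests]
        ests = list(ests)
        if not ests:
            raise ValueError(f"method {method!r} has no estimates")
        arr = np.array([e.as_tuple() for e in ests], dtype=float)
        rows[method] = arr.mean(axis=0)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_FORMULA_COLUMNS)
    table["Mean"] = table[_FORMULA_COLUMNS].mean(axis=1)
    mean_row = table.mean(axis=0)
    # grand mean over the per-formula cells, not a mean of row means
    mean_row["Mean"] = float(table[_FORMULA_COLUMNS].to_numpy().mean())
    table.loc["Mean"] = mean_row
    return table


def format_pm_table(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation rounding (banker's/half-even, as float round does)."""
    return table.round(decimals)
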