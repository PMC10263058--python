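"""COD mass accounting for fermentation product streams.

Concentrations measured in g/L are converted to COD equivalents (g COD/L)
through each compound's theoretical oxygen demand; columns already expressed
in COD units can be flagged as such and pass through unchanged.  Recovery
percentages are ratios of summed product COD to a reference COD (feedstock
soluble COD, or effluent soluble COD for the accounted fraction).

Averaging convention: the summary takes the ratio of time-averaged CODs
(matching how per-stream mean concentrations are tabulated); a per-timepoint
mean of ratios is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .netdef import CompoundSpec, MetabolicNetwork
from .community_dynamics import ProductSeries

__all__ = ["CodSummary", "to_cod", "recovery_fraction", "summarize_cod"]


@dataclass(frozen=True)
class CodSummary:
    feedstock_soluble_cod: float
    effluent_soluble_cod: float | None
    product_cod: Mapping[str, float]  # per-compound mean g COD/L
    total_product_cod: float
    recovery_vs_feedstock: float  # percent
    accounted_vs_effluent: float | None  # percent


def to_cod(concentration_g_per_l: float, compound: CompoundSpec) -> float:
    """g/L of a compound → g COD/L via its theoretical oxygen demand."""
    if concentration_g_per_l < 0:
        raise ValueError("concentration must be ≥ 0")
    return concentration_g_per_l * compound.thod


def recovery_fraction(product_cod_sum: float, reference_cod: float) -> float:
    """Summed product COD as a percent of a reference COD."""
    if reference_cod <= 0:
        raise ValueError("reference COD must be positive")
    return 100.0 * product_cod_sum / reference_cod


def summarize_cod(
    series: ProductSeries,
    feedstock_soluble_cod: float,
    effluent_soluble_cod: float | None = None,
    per_timepoint: bool = False,
) -> CodSummary:
    """COD balance of a product time series against feedstock (and effluent).

    ``per_timepoint=True`` averages the per-sample recovery ratios instead of
    taking the ratio of time-averaged CODs.
    """
    cod = series.cod_equivalent[series.product_columns()]
    per_compound = cod.mean(axis=0)
    total = float(per_compound.sum())
    if per_timepoint:
        recovery = float(
            (100.0 * cod.sum(axis=1) / feedstock_soluble_cod).mean()
        )
    else:
        recovery = recovery_fraction(total, feedstock_soluble_cod)
    accounted = None
    if effluent_soluble_cod is not None:
        if per_timepoint:
            accounted = float(
                (100.0 * cod.sum(axis=1) / effluent_soluble_cod).mean()
            )
        else:
            accounted = recovery_fraction(total, effluent_soluble_cod)
    return CodSummary(
        feedstock_soluble_cod=feedstock_soluble_cod,
        effluent_soluble_cod=effluent_soluble_cod,
        product_cod=dict(per_compound),
        total_product_cod=total,
        recovery_vs_feedstock=recovery,
        accounted_vs_effluent=accounted,
    )
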