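"""Relative abundance, MAG ranking, and operational-period segmentation.

Relative abundance is computed over *mapped* reads (each sample's genome
abundances sum to 100%), with the fraction of all reads that mapped reported
separately — mirroring the convention of plotting MAG abundances alongside a
separate mapped-percentage line.  Users comparing against coverage tools run
in unmapped-inclusive mode should expect proportionally larger numbers here.

Operational periods are contiguous runs of sampled days sharing the same
two most abundant fermentation products (by COD equivalents, carbohydrates
excluded).  A new period begins when the unordered top-2 set changes and the
new set persists for at least ``min_persistence`` consecutive samples
(default 2), which smooths single-sample excursions such as sporadic lactic
acid accumulation.  Labels are assigned A, B, C, … in order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .netdef import MetabolicNetwork

__all__ = [
    "AbundanceMatrix",
    "ProductSeries",
    "Period",
    "PeriodSegmentation",
    "relative_abundance",
    "select_top_mags",
    "dominant_products",
    "segment_periods",
    "hydraulic_retention_time",
]


@dataclass
class AbundanceMatrix:
    """Sample × genome relative abundances (percent of mapped reads)."""

    rel_abundance: pd.DataFrame  # index: day, columns: genome_id
    mapped_fraction: pd.Series  # index: day, percent of all reads mapped
    sample_ids: pd.Series  # index: day


@dataclass
class ProductSeries:
    """Analyte concentrations (g/L) per day with COD equivalents (g COD/L)."""

    concentrations: pd.DataFrame  # index: day, columns: analyte
    network: MetabolicNetwork

    def __post_init__(self) -> None:
        if (self.concentrations < 0).any().any():
            raise ValueError("negative concentration")

    @property
    def days(self) -> list[float]:
        return list(self.concentrations.index)

    @property
    def cod_equivalent(self) -> pd.DataFrame:
        factors = {
            c: self.network.compound(c).thod for c in self.concentrations.columns
        }
        return self.concentrations.mul(pd.Series(factors), axis=1)

    def product_columns(self) -> list[str]:
        """Analytes that are fermentation products (carbohydrates excluded)."""
        return [
            c
            for c in self.concentrations.columns
            if self.network.compound(c).category == "fermentation_product"
        ]

    @classmethod
    def from_csv(cls, path: str | Path, network: MetabolicNetwork) -> "ProductSeries":
        """Long-format CSV with columns day, analyte, g_per_L."""
        df = pd.read_csv(path)
        wide = df.pivot_table(index="day", columns="analyte", values="g_per_L")
        wide = wide.sort_index().fillna(0.0)
        wide.columns.name = None
        return cls(concentrations=wide, network=network)


@dataclass(frozen=True)
class Period:
    label: str
    start_day: float
    end_day: float
    top2_products: tuple[str, str]


@dataclass
class PeriodSegmentation:
    periods: list[Period]


def relative_abundance(
    coverage: pd.DataFrame,
    sample_reads: pd.DataFrame,
) -> AbundanceMatrix:
    """Build an :class:`AbundanceMatrix` from a coverage table.

    ``coverage`` columns: sample_id, day, genome_id, mapped_reads (and
    optionally mean_coverage); ``sample_reads`` columns: sample_id, day,
    total_reads, unmapped_reads.  Genome abundance is that genome's mapped
    reads as a percent of all mapped reads in the sample.
    """
    totals = coverage.groupby("sample_id")["mapped_reads"].sum()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample with zero mapped reads: {', '.join(map(str, zero.index))}")
    cov = coverage.merge(totals.rename("sample_mapped"), on="sample_id")
    cov["pct"] = 100.0 * cov["mapped_reads"] / cov["sample_mapped"]
    wide = cov.pivot_table(index="day", columns="genome_id", values="pct").sort_index()
    wide = wide.fillna(0.0)
    wide.columns.name = None
    sr = sample_reads.set_index("day").sort_index()
    mapped_fraction = 100.0 * (sr["total_reads"] - sr["unmapped_reads"]) / sr["total_reads"]
    sample_ids = sr["sample_id"]
    return AbundanceMatrix(
        rel_abundance=wide,
        mapped_fraction=mapped_fraction.rename("mapped_fraction"),
        sample_ids=sample_ids,
    )


def select_top_mags(matrix: AbundanceMatrix, n: int = 10) -> pd.DataFrame:
    """Rank genomes by maximum observed relative abundance (descending).

    Ties break by mean abundance (descending), then genome_id (ascending).
    Returns the first ``min(n, #genomes)`` rows with columns
    (genome_id, max_abundance, mean_abundance).
    """
    if n < 0:
        raise ValueError("n must be ≥ 0")
    df = pd.DataFrame(
        {
            "genome_id": matrix.rel_abundance.columns,
            "max_abundance": matrix.rel_abundance.max(axis=0).values,
            "mean_abundance": matrix.rel_abundance.mean(axis=0).values,
        }
    )
    df = df.sort_values(
        ["max_abundance", "mean_abundance", "genome_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df.head(n)


def dominant_products(
    series: ProductSeries,
    start_day: float,
    end_day: float,
) -> tuple[tuple[str, str], bool]:
    """Ordered top-2 fermentation products by mean COD over a day window.

    Carbohydrates are excluded.  Returns ``((first, second), tie_flagged)``;
    a single-product series yields ``(product, "none")``.  Exact ties break
    lexicographically and set the flag.
    """
    cod = series.cod_equivalent.loc[
        (series.cod_equivalent.index >= start_day)
        & (series.cod_equivalent.index <= end_day),
        series.product_columns(),
    ]
    if cod.empty:
        raise ValueError(f"no samples in day range [{start_day}, {end_day}]")
    means = cod.mean(axis=0)
    # primary: mean COD descending; ties: analyte name ascending
    ranked = means.iloc[np.lexsort((means.index.to_numpy(), -means.to_numpy()))]
    if len(ranked) == 1:
        return (str(ranked.index[0]), "none"), False
    top2 = (str(ranked.index[0]), str(ranked.index[1]))
    tie = len(ranked) > 2 and bool(np.isclose(ranked.iloc[1], ranked.iloc[2]))
    return top2, tie


def segment_periods(series: ProductSeries, min_persistence: int = 2) -> PeriodSegmentation:
    """Segment sampled days into periods by the unordered top-2 product set.

    A new period starts at the first of ``min_persistence`` consecutive
    samples sharing a top-2 set different from the current period's; shorter
    excursions are treated as blips and absorbed.  Periods are contiguous
    over sampled days and labelled alphabetically.
    """
    days = series.days
    if len(days) < min_persistence:
        raise ValueError("fewer samples than min_persistence")
    top2_sets = []
    for day in days:
        (a, b), _ = dominant_products(series, day, day)
        top2_sets.append(frozenset((a, b)))
    starts = [0]
    current = top2_sets[0]
    i = 1
    while i < len(days):
        s = top2_sets[i]
        if s != current and all(
            top2_sets[k] == s for k in range(i, min(i + min_persistence, len(days)))
        ) and i + min_persistence <= len(days):
            starts.append(i)
            current = s
        i += 1
    periods = []
    for idx, start in enumerate(starts):
        end = starts[idx + 1] - 1 if idx + 1 < len(starts) else len(days) - 1
        (a, b), _ = dominant_products(series, days[start], days[end])
        periods.append(
            Period(
                label=chr(ord("A") + idx),
                start_day=days[start],
                end_day=days[end],
                top2_products=(a, b),
            )
        )
    return PeriodSegmentation(periods=periods)


def hydraulic_retention_time(volume_l: float, flow_l_per_day: float) -> float:
    """Hydraulic retention time in days: working volume / volumetric flow."""
    if volume_l <= 0 or flow_l_per_day <= 0:
        raise ValueError("volume and flow must be positive")
    return volume_l / flow_l_per_day
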