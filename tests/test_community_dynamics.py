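"""Abundance, ranking, product dominance and period segmentation."""

import numpy as np
import pandas as pd
import pytest

from lactoferm.community_dynamics import (
    AbundanceMatrix,
    ProductSeries,
    dominant_products,
    hydraulic_retention_time,
    relative_abundance,
    segment_periods,
    select_top_mags,
)


def cov_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "day", "genome_id", "mapped_reads"])


def reads_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "day", "total_reads", "unmapped_reads"])


def test_relative_abundance_is_proportion_of_mapped_reads():
    m = relative_abundance(
        cov_table([("S1", 0, "A", 75), ("S1", 0, "B", 25)]),
        reads_table([("S1", 0, 200, 100)]),
    )
    assert m.rel_abundance.loc[0, "A"] == 75.0
    assert m.rel_abundance.loc[0, "B"] == 25.0
    assert m.mapped_fraction.loc[0] == 50.0


def test_relative_abundance_single_genome_is_100():
    m = relative_abundance(cov_table([("S1", 0, "A", 10)]),
                           reads_table([("S1", 0, 10, 0)]))
    assert m.rel_abundance.loc[0, "A"] == 100.0


def test_relative_abundance_rejects_zero_mapped_sample():
    with pytest.raises(ValueError, match="S1"):
        relative_abundance(cov_table([("S1", 0, "A", 0)]),
                           reads_table([("S1", 0, 10, 10)]))


def test_abundance_rows_sum_to_100_on_fixture(pipeline_result):
    sums = pipeline_result.abundance.rel_abundance.sum(axis=1)
    assert np.allclose(sums, 100.0, atol=0.01)


def matrix_from(df):
    return AbundanceMatrix(
        rel_abundance=df,
        mapped_fraction=pd.Series(80.0, index=df.index),
        sample_ids=pd.Series([f"S{i}" for i in range(len(df))], index=df.index),
    )


def test_select_top_mags_ranks_by_peak_abundance():
    df = pd.DataFrame({"steady": [30.0, 30, 30], "peaky": [61.5, 5, 5],
                       "rest": [8.5, 65, 65]}, index=[0, 6, 12])
    top = select_top_mags(matrix_from(df), n=2)
    assert list(top.genome_id) == ["rest", "peaky"]
    assert top.iloc[1].max_abundance == 61.5


def test_select_top_mags_tie_broken_by_genome_id():
    df = pd.DataFrame({"b": [50.0, 50], "a": [50.0, 50]}, index=[0, 6])
    top = select_top_mags(matrix_from(df), n=2)
    assert list(top.genome_id) == ["a", "b"]


def test_select_top_mags_n_zero_and_full_permutation():
    df = pd.DataFrame({"a": [10.0], "b": [90.0]}, index=[0])
    assert select_top_mags(matrix_from(df), n=0).empty
    full = select_top_mags(matrix_from(df), n=2)
    assert sorted(full.genome_id) == ["a", "b"]


def series(data, network, days=None):
    df = pd.DataFrame(data, index=days if days is not None else range(len(next(iter(data.values())))))
    df.index.name = "day"
    return ProductSeries(concentrations=df.astype(float), network=network)


def test_dominant_products_by_mean_cod_excluding_carbohydrates(network):
    s = series({"butyric": [10 / 1.8164], "acetic": [8 / 1.0657],
                "lactose": [50.0], "ethanol": [1.0]}, network)
    (top2, tie) = dominant_products(s, 0, 0)
    assert top2 == ("butyric", "acetic") and not tie


def test_dominant_products_single_product(network):
    s = series({"acetic": [5.0]}, network)
    assert dominant_products(s, 0, 0)[0] == ("acetic", "none")


def test_dominant_products_tie_flagged_lexicographic(network):
    # butyric first; acetic and lactic tie exactly for second in COD units
    s = series({"butyric": [10.0], "acetic": [2.0], "lactic": [2.0]}, network)
    (top2, tie) = dominant_products(s, 0, 0)
    assert top2 == ("butyric", "acetic") and tie  # same ThOD for acetic/lactic


def test_dominant_products_empty_range_rejected(network):
    s = series({"acetic": [5.0]}, network)
    with pytest.raises(ValueError):
        dominant_products(s, 10, 20)


def test_segment_constant_series_is_single_period(network):
    s = series({"butyric": [9.0] * 6, "acetic": [5.0] * 6}, network,
               days=[0, 6, 12, 18, 24, 30])
    seg = segment_periods(s)
    assert len(seg.periods) == 1
    assert seg.periods[0].label == "A"
    assert (seg.periods[0].start_day, seg.periods[0].end_day) == (0, 30)


def test_segment_single_sample_blip_absorbed(network):
    butyric = [9, 9, 9, 0.5, 9, 9]
    ethanol = [0.5, 0.5, 0.5, 9, 0.5, 0.5]
    s = series({"butyric": butyric, "ethanol": ethanol, "acetic": [5] * 6},
               network, days=[0, 6, 12, 18, 24, 30])
    assert len(segment_periods(s, min_persistence=2).periods) == 1


def test_segment_detects_persistent_regime_change(network):
    butyric = [9, 9, 9, 0.5, 0.5, 0.5]
    ethanol = [0.5, 0.5, 0.5, 9, 9, 9]
    s = series({"butyric": butyric, "ethanol": ethanol, "acetic": [5] * 6},
               network, days=[0, 6, 12, 18, 24, 30])
    seg = segment_periods(s, min_persistence=2)
    assert [p.label for p in seg.periods] == ["A", "B"]
    assert seg.periods[1].start_day == 18
    assert seg.periods[0].end_day == 12


def test_segmentation_invariant_to_uniform_rescaling(network):
    rng = np.random.default_rng(2)
    days = list(range(0, 60, 6))
    data = {"butyric": rng.uniform(0, 10, len(days)),
            "acetic": rng.uniform(0, 10, len(days)),
            "ethanol": rng.uniform(0, 10, len(days))}
    s1 = series(data, network, days=days)
    s2 = series({k: v * 7.3 for k, v in data.items()}, network, days=days)
    p1 = [(p.start_day, p.top2_products) for p in segment_periods(s1).periods]
    p2 = [(p.start_day, p.top2_products) for p in segment_periods(s2).periods]
    assert p1 == p2


def test_hydraulic_retention_time():
    assert hydraulic_retention_time(3.0, 0.5) == 6.0
    assert hydraulic_retention_time(1.0, 1.0) == 1.0
    with pytest.raises(ValueError):
        hydraulic_retention_time(3.0, 0)
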