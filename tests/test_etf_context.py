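"""EtfAB pair detection, neighborhood context, alignment and clusters."""

import numpy as np
import pytest

from lactoferm.annotate_io import GeneAnnotation
from lactoferm.etf_context import (
    EtfLocus,
    EtfReference,
    _nw_stats,
    assign_cluster,
    classify_neighborhood,
    default_references,
    etf_function_call,
    find_etf_pairs,
    global_identity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
ETFA = "electron transfer flavoprotein subunit alpha"
ETFB = "electron transfer flavoprotein subunit beta"


def gene(locus, start, end, product="", genome="G1", contig="c1", strand="+"):
    return GeneAnnotation(genome, contig, start, end, strand, locus, product=product)


def pair_with_neighbor(product, dist, window_side="down"):
    """An etfAB pair spanning 1000..3000 with one neighbor at a given
    edge-to-edge distance."""
    anns = [
        gene("a", 1000, 2000, ETFA),
        gene("b", 2100, 3000, ETFB),
    ]
    if window_side == "down":
        anns.append(gene("n", 3000 + dist, 3000 + dist + 800, product))
    else:
        anns.append(gene("n", 1000 - dist - 800, 1000 - dist, product))
    locus = EtfLocus("G1", "c1", "a", "b", 1000, 3000)
    return locus, anns


def test_find_etf_pairs_adjacent_either_order():
    anns = [gene("a", 1000, 2000, ETFA), gene("b", 2100, 3000, ETFB)]
    pairs = find_etf_pairs(anns)
    assert len(pairs) == 1
    assert (pairs[0].etfA_locus, pairs[0].etfB_locus) == ("a", "b")
    flipped = [gene("b", 1000, 2000, ETFB), gene("a", 2100, 3000, ETFA)]
    assert len(find_etf_pairs(flipped)) == 1


def test_find_etf_pairs_requires_both_subunits_and_small_gap():
    assert find_etf_pairs([gene("b", 1000, 2000, ETFB)]) == []
    distant = [gene("a", 1000, 2000, ETFA), gene("b", 2600, 3500, ETFB)]
    assert find_etf_pairs(distant, max_gap=500) == []


def test_find_etf_pairs_recovers_planted_pairs(scenario_bundle, pipeline_result):
    planted = {}
    for row in scenario_bundle.manifest.etf_calls:
        planted[row["genome_id"]] = planted.get(row["genome_id"], 0) + 1
    found = {g: len(v) for g, v in pipeline_result.etf_loci.items() if v}
    assert found == planted
    assert found["CLOS1L"] == 3  # multiple pairs in the lactate elongator


@pytest.mark.parametrize(
    "product, expected",
    [
        ("lactate permease", "lactate_utilization"),
        ("acyl-CoA dehydrogenase", "reverse_beta_oxidation"),
        ("ribosomal protein", "unknown"),
    ],
)
def test_classify_neighborhood_role_signals(network, product, expected):
    locus, anns = pair_with_neighbor(product, 200)
    assert classify_neighborhood(locus, anns, network).context == expected


def test_classify_neighborhood_both_signals_ambiguous(network):
    locus, anns = pair_with_neighbor("acyl-CoA dehydrogenase", 100)
    anns.append(gene("m", 5000, 5800, "lactate permease"))  # upstream-ish inside window
    assert classify_neighborhood(locus, anns, network).context == "ambiguous_both"


@pytest.mark.parametrize("dist, expected", [(5000, "reverse_beta_oxidation"), (5001, "unknown")])
def test_classify_neighborhood_window_boundary_inclusive(network, dist, expected):
    locus, anns = pair_with_neighbor("acyl-CoA dehydrogenase", dist)
    assert classify_neighborhood(locus, anns, network, window=5000).context == expected


def test_classify_neighborhood_rejects_nonpositive_window(network):
    locus, anns = pair_with_neighbor("lactate permease", 100)
    with pytest.raises(ValueError):
        classify_neighborhood(locus, anns, network, window=0)


def mirror(anns, contig_len):
    out = []
    for a in anns:
        out.append(
            GeneAnnotation(
                a.genome_id, a.contig_id,
                contig_len - a.end + 1, contig_len - a.start + 1,
                "-" if a.strand == "+" else "+", a.locus_tag, product=a.product,
            )
        )
    return out


def test_neighborhood_invariant_under_coordinate_mirroring(network):
    """Mirroring a contig's coordinate system never changes the context."""
    rng = np.random.default_rng(5)
    products = ["lactate permease", "acyl-CoA dehydrogenase",
                "enoyl-CoA hydratase", "ribosomal protein", ""]
    L = 40_000
    for _ in range(25):
        anns = [gene("a", 15_000, 15_900, ETFA), gene("b", 16_000, 16_900, ETFB)]
        for i in range(int(rng.integers(1, 6))):
            start = int(rng.integers(1, L - 1000))
            if 14_000 <= start <= 18_000:  # keep the pair adjacent
                continue
            anns.append(
                gene(f"n{i}", start, start + 800,
                     products[int(rng.integers(len(products)))])
            )
        fwd = find_etf_pairs(sorted(anns, key=lambda x: x.start))
        rev = find_etf_pairs(sorted(mirror(anns, L), key=lambda x: x.start))
        assert len(fwd) == len(rev) == 1
        ctx_f = classify_neighborhood(fwd[0], anns, network).context
        ctx_r = classify_neighborhood(rev[0], mirror(anns, L), network).context
        assert ctx_f == ctx_r


def brute_force_alignment(a, b):
    """Exhaustive enumeration of every global alignment; returns the
    lexicographic best (score, identities, -columns)."""
    from lactoferm.etf_context import _BLOSUM62

    best = [None]

    def rec(i, j, last, score, ident, cols):
        if i == len(a) and j == len(b):
            cand = (score, ident, -cols)
            if best[0] is None or cand > best[0]:
                best[0] = cand
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + _BLOSUM62[a[i], b[j]],
                ident + (a[i] == b[j]), cols + 1)
        if i < len(a):
            rec(i + 1, j, "X", score + (-1 if last == "X" else -12), ident, cols + 1)
        if j < len(b):
            rec(i, j + 1, "Y", score + (-1 if last == "Y" else -12), ident, cols + 1)

    rec(0, 0, None, 0.0, 0, 0)
    return best[0]


def test_alignment_statistics_match_enumeration_oracle():
    rng = np.random.default_rng(11)
    for _ in range(15):
        a = "".join(rng.choice(list(AA), int(rng.integers(1, 7))))
        b = "".join(rng.choice(list(AA), int(rng.integers(1, 7))))
        score, ident, cols = _nw_stats(a, b)
        assert (score, ident, -cols) == brute_force_alignment(a, b)


def test_global_identity_symmetric_and_reflexive():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = "".join(rng.choice(list(AA), int(rng.integers(3, 30))))
        b = "".join(rng.choice(list(AA), int(rng.integers(3, 30))))
        assert global_identity(a, b) == pytest.approx(global_identity(b, a))
        assert global_identity(a, a) == 100.0


def test_global_identity_rejects_empty_sequence():
    with pytest.raises(ValueError):
        global_identity("A", "")


def refs():
    lac = "".join(AA[i % 20] for i in range(60))
    rbo = "".join(AA[(7 * i + 3) % 20] for i in range(60))
    return [
        EtfReference("lacR", lac, "lactate_cluster"),
        EtfReference("rboR", rbo, "rbo_cluster"),
    ]


def test_assign_cluster_identical_sequence():
    r = refs()
    out = assign_cluster(r[0].sequence, r)
    assert out.cluster == "lactate_cluster" and out.identity == 100.0


def test_assign_cluster_tie_is_unresolved():
    r = refs()
    out = assign_cluster(r[0].sequence, [r[0], EtfReference("rboR", r[0].sequence, "rbo_cluster")])
    assert out.cluster == "unresolved"


def test_assign_cluster_requires_both_clusters():
    r = refs()
    with pytest.raises(ValueError):
        assign_cluster(r[0].sequence, [r[0]])
    with pytest.raises(ValueError):
        assign_cluster(r[0].sequence, [])


def mutate(seq, frac, rng):
    s = list(seq)
    for i in rng.choice(len(s), int(len(s) * frac), replace=False):
        s[i] = rng.choice([c for c in AA if c != s[i]])
    return "".join(s)


def test_assign_cluster_recovers_planted_labels_under_mutation():
    """≥95% of EtfBs mutated ≤20% from a reference recover its cluster."""
    references = default_references()
    rng = np.random.default_rng(17)
    correct = total = 0
    for ref in references:
        for frac in (0.05, 0.10, 0.20):
            for _ in range(4):
                seq = mutate(ref.sequence, frac, rng)
                out = assign_cluster(seq, references)
                total += 1
                correct += out.cluster == ref.known_cluster
    assert correct / total >= 0.95


@pytest.mark.parametrize(
    "context, cluster, expected",
    [
        ("lactate_utilization", "lactate_cluster", "lactate_utilization"),
        ("ambiguous_both", "unresolved", "both_possible"),
        ("ambiguous_both", "rbo_cluster", "reverse_beta_oxidation"),
        ("unknown", "rbo_cluster", "reverse_beta_oxidation"),
        ("reverse_beta_oxidation", "unresolved", "reverse_beta_oxidation"),
        ("lactate_utilization", "rbo_cluster", "both_possible"),  # conflict
        ("unknown", "unresolved", "unknown"),
    ],
)
def test_etf_function_call_combinations(context, cluster, expected):
    locus = EtfLocus("G", "c", "a", "b", 1, 2, context=context, cluster=cluster)
    assert etf_function_call(locus) == expected
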