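"""Step presence and pathway completeness calling."""

import numpy as np
import pytest

from lactoferm.annotate_io import GeneAnnotation
from lactoferm.pathway_presence import (
    STATUS_ORDER,
    call_pathway,
    call_step,
    pathway_hole_report,
    presence_matrix,
    succinate_route_report,
)


def gene(locus, start=100, ec=None, ko=None, product="", genome="G1", contig="c1"):
    return GeneAnnotation(
        genome_id=genome,
        contig_id=contig,
        start=start,
        end=start + 899,
        strand="+",
        locus_tag=locus,
        product=product,
        ec_numbers=frozenset([ec] if ec else []),
        ko_ids=frozenset([ko] if ko else []),
    )


def steps_for(network, annotations, genome="G1", ev=None):
    return {
        sid: call_step(annotations, s, ev, genome_id=genome)
        for sid, s in network.steps.items()
    }


def test_call_step_by_ec(network):
    call = call_step([gene("L1", ec="3.2.1.23")], network.steps["BGS"])
    assert call.present and ("L1", "ec") in call.evidence


def test_call_step_by_homology_hit_only(network):
    ev = {"G1": {"ecLDH_Awoodii": ["L5"]}}
    anns = [gene("L5", product="hypothetical protein")]
    call = call_step(anns, network.steps["ecLDH"], ev, genome_id="G1")
    assert call.present and call.evidence == (("L5", "homology_hit"),)


def test_call_step_empty_genome(network):
    call = call_step([], network.steps["BGS"], genome_id="G1")
    assert not call.present and call.evidence == ()


def test_call_pathway_statuses(network):
    leloir = network.pathways["leloir"]
    full = [gene(f"L{i}", start=100 + 1000 * i, ec=sorted(network.steps[s].ec_numbers)[0])
            for i, s in enumerate(leloir.steps)]
    calls = steps_for(network, full)
    assert call_pathway(calls, leloir, "G1").status == "complete"
    calls = steps_for(network, full[:-1])
    near = call_pathway(calls, leloir, "G1")
    assert near.status == "near_complete" and near.missing_steps == ("GALE",)
    calls = steps_for(network, full[:2])
    assert call_pathway(calls, leloir, "G1").status == "incomplete"
    calls = steps_for(network, [])
    assert call_pathway(calls, leloir, "G1").status == "absent"


def test_presence_matrix_identical_genomes_identical_rows(network):
    anns = [gene("A_1", ec="3.2.1.23", genome="A")]
    anns_b = [gene("B_1", ec="3.2.1.23", genome="B")]
    matrix, _, _ = presence_matrix({"A": anns, "B": anns_b}, network)
    assert (matrix.loc["A"] == matrix.loc["B"]).all()
    assert matrix.loc["A", "BGS"]


def test_presence_matrix_empty_genome_all_false(network):
    matrix, _, _ = presence_matrix({"E": []}, network)
    assert not matrix.loc["E"].any()


def test_presence_matrix_reports_each_step_once(network):
    matrix, _, _ = presence_matrix({"E": []}, network)
    assert matrix.columns.is_unique and set(matrix.columns) == set(network.steps)


@pytest.mark.parametrize(
    "ecs, complete_variant",
    [
        (["4.1.1.32", "1.1.1.37", "4.2.1.2", "1.3.5.1"], "succinate_route_pepck_md"),
        (["1.1.1.38", "4.2.1.2", "1.3.5.1"], "succinate_route_me"),
    ],
)
def test_succinate_route_variants(network, ecs, complete_variant):
    anns = [gene(f"L{i}", start=100 + 1000 * i, ec=ec) for i, ec in enumerate(ecs)]
    calls = steps_for(network, anns)
    report = {c.pathway_id: c.status for c in succinate_route_report(calls, network, "G1")}
    assert report[complete_variant] == "complete"
    assert all(s != "complete" for p, s in report.items() if p != complete_variant)


def test_succinate_routes_absent_without_genes(network):
    calls = steps_for(network, [])
    report = succinate_route_report(calls, network, "G1")
    assert all(c.status == "absent" for c in report)


def test_pathway_hole_report_lists_single_holes(network, pipeline_result):
    holes = pathway_hole_report(pipeline_result.pathway_table)
    bif18 = holes[(holes.genome_id == "BIF18L") & (holes.pathway_id == "phosphoketolase")]
    assert len(bif18) == 1 and bif18.iloc[0].missing_steps == "R5PE"


def test_pathway_hole_report_empty_for_all_absent(network):
    _, table, _ = presence_matrix({"E": []}, network)
    assert pathway_hole_report(table).empty


def test_community_fixture_reproduces_expected_lactose_calls(pipeline_result):
    """Qualitative checks of the community fixture: the lactose-elongator
    genome completes the Leloir route, bifid-shunt genomes lack PFK (EMP
    incomplete), and no genome completes the tagatose-6-phosphate route."""
    table = pipeline_result.pathway_table.set_index(["genome_id", "pathway_id"])
    assert table.loc[("LCO1L", "leloir"), "status"] == "complete"
    for g in ("BIF2L", "BIF11L", "BIF18L"):
        assert table.loc[(g, "bifid_shunt"), "status"] == "complete"
        assert table.loc[(g, "emp_glycolysis"), "status"] != "complete"
        assert "PFK" in table.loc[(g, "emp_glycolysis"), "missing_steps"]
    tag = table.xs("tagatose6p", level="pathway_id")["status"]
    assert (tag != "complete").all()


def random_genome(rng, network, n_genes):
    """A genome annotated with a random subset of network step identifiers."""
    step_ids = list(network.steps)
    anns = []
    for i in range(n_genes):
        sid = step_ids[int(rng.integers(len(step_ids)))]
        step = network.steps[sid]
        ec = sorted(step.ec_numbers)[0] if step.ec_numbers else None
        product = step.display_name if not ec else ""
        anns.append(gene(f"R{i}", start=100 + 1000 * i, ec=ec, product=product))
    return anns


def test_pathway_status_never_demoted_by_added_annotations(network):
    """Adding annotations moves pathway status only towards completeness."""
    rank = {s: i for i, s in enumerate(STATUS_ORDER)}
    rng = np.random.default_rng(123)
    for _ in range(30):
        base = random_genome(rng, network, int(rng.integers(0, 10)))
        extra = base + random_genome(rng, network, int(rng.integers(1, 8)))
        before = steps_for(network, base)
        after = steps_for(network, extra)
        for pw in network.pathways.values():
            s0 = call_pathway(before, pw, "G1").status
            s1 = call_pathway(after, pw, "G1").status
            assert rank[s1] >= rank[s0], pw.pathway_id
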