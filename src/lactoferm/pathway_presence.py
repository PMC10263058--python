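"""Per-step gene presence and per-pathway completeness calls.

A step is present in a genome when any annotation matches any of its
identifier sets (EC/KO/COG exact, product pattern as case-insensitive
substring) or when a threshold-filtered homology hit for one of the step's
reference queries lands on a locus of that genome.  Evidence records every
supporting locus with its source, so presence is auditable and monotone:
adding annotations can only add evidence.

Pathway status follows the completeness ladder
``absent < incomplete < near_complete < complete``:  complete means no
missing steps, near_complete means at most ``near_complete_max_missing``
(default exactly 1) missing, absent means every step missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotate_io import GeneAnnotation
from .netdef import MetabolicNetwork, PathwayDefinition, ReactionStep

__all__ = [
    "StepCall",
    "PathwayCall",
    "STATUS_ORDER",
    "call_step",
    "call_pathway",
    "presence_matrix",
    "succinate_route_report",
    "pathway_hole_report",
]

STATUS_ORDER = ("absent", "incomplete", "near_complete", "complete")


@dataclass(frozen=True)
class StepCall:
    genome_id: str
    step_id: str
    present: bool
    evidence: tuple[tuple[str, str], ...] = ()  # (locus_tag, source)

    def __post_init__(self) -> None:
        assert self.present == bool(self.evidence)


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    pathway_id: str
    status: str
    missing_steps: tuple[str, ...] = ()


def _match_annotation(ann: GeneAnnotation, step: ReactionStep) -> list[str]:
    """Sources under which one annotation supports one step."""
    sources: list[str] = []
    if step.ec_numbers & ann.ec_numbers:
        sources.append("ec")
    if step.ko_ids & ann.ko_ids:
        sources.append("ko")
    if step.cog_ids & ann.cog_ids:
        sources.append("cog")
    if ann.product:
        low = ann.product.lower()
        if any(pat.lower() in low for pat in step.product_patterns):
            sources.append("product_pattern")
    return sources


def call_step(
    annotations: Sequence[GeneAnnotation],
    step: ReactionStep,
    evidence_idx: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    genome_id: str | None = None,
) -> StepCall:
    """Call one step for one genome's annotations (plus optional hit evidence)."""
    if genome_id is None:
        if annotations:
            genome_id = annotations[0].genome_id
        else:
            genome_id = ""
    evidence: list[tuple[str, str]] = []
    for ann in annotations:
        for source in _match_annotation(ann, step):
            evidence.append((ann.locus_tag, source))
    if evidence_idx is not None:
        per_genome = evidence_idx.get(genome_id, {})
        for query in sorted(step.homology_queries):
            for locus in per_genome.get(query, []):
                evidence.append((locus, "homology_hit"))
    # deterministic, de-duplicated
    evidence = sorted(set(evidence))
    return StepCall(
        genome_id=genome_id,
        step_id=step.step_id,
        present=bool(evidence),
        evidence=tuple(evidence),
    )


def _status(n_steps: int, n_missing: int, near_max: int) -> str:
    if n_missing == 0:
        return "complete"
    if n_missing == n_steps:
        return "absent"
    if n_missing <= near_max:
        return "near_complete"
    return "incomplete"


def call_pathway(
    step_calls: Mapping[str, StepCall],
    pathway: PathwayDefinition,
    genome_id: str,
    near_complete_max_missing: int = 1,
) -> PathwayCall:
    """Pathway status from a genome's per-step calls (keyed by step_id)."""
    missing = tuple(s for s in pathway.steps if not step_calls[s].present)
    return PathwayCall(
        genome_id=genome_id,
        pathway_id=pathway.pathway_id,
        status=_status(len(pathway.steps), len(missing), near_complete_max_missing),
        missing_steps=missing,
    )


def _steps_for_genome(
    annotations: Sequence[GeneAnnotation],
    network: MetabolicNetwork,
    evidence_idx,
    genome_id: str,
) -> dict[str, StepCall]:
    return {
        step_id: call_step(annotations, step, evidence_idx, genome_id=genome_id)
        for step_id, step in network.steps.items()
    }


def presence_matrix(
    genomes: Mapping[str, Sequence[GeneAnnotation]],
    network: MetabolicNetwork,
    evidence_idx: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    near_complete_max_missing: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, StepCall]]]:
    """Genome × step boolean presence matrix plus the pathway-call table.

    Rows follow the genome mapping order, columns the network's step registry
    order; a step shared by several pathways appears once.  Returns
    ``(matrix, pathway_table, step_calls)`` where ``pathway_table`` has
    columns (genome_id, pathway_id, status, missing_steps).
    """
    if not genomes:
        raise ValueError("at least one genome required")
    step_ids = list(network.steps)
    all_calls: dict[str, dict[str, StepCall]] = {}
    rows = []
    pw_rows = []
    for genome_id, anns in genomes.items():
        calls = _steps_for_genome(anns, network, evidence_idx, genome_id)
        all_calls[genome_id] = calls
        rows.append([calls[s].present for s in step_ids])
        for pw in network.pathways.values():
            call = call_pathway(calls, pw, genome_id, near_complete_max_missing)
            pw_rows.append(
                (genome_id, pw.pathway_id, call.status, ",".join(call.missing_steps))
            )
    matrix = pd.DataFrame(rows, index=list(genomes), columns=step_ids, dtype=bool)
    matrix.index.name = "genome_id"
    pathway_table = pd.DataFrame(
        pw_rows, columns=["genome_id", "pathway_id", "status", "missing_steps"]
    )
    return matrix, pathway_table, all_calls


def succinate_route_report(
    step_calls: Mapping[str, StepCall],
    network: MetabolicNetwork,
    genome_id: str,
    near_complete_max_missing: int = 1,
) -> list[PathwayCall]:
    """One call per succinate-route variant; a genome can produce succinate
    iff at least one variant is complete."""
    variants = network.variant_pathways("succinate")
    if not variants:
        raise ValueError("no succinate variants defined in network")
    return [
        call_pathway(step_calls, pw, genome_id, near_complete_max_missing)
        for pw in variants
    ]


def pathway_hole_report(pathway_table: pd.DataFrame) -> pd.DataFrame:
    """All near-complete pathways with their missing step(s) — a simple
    missing-step report standing in for automated pathway-hole filling."""
    holes = pathway_table[pathway_table["status"] == "near_complete"]
    return holes[["genome_id", "pathway_id", "missing_steps"]].reset_index(drop=True)
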