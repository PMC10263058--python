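"""End-to-end driver: from generated (or real) study files to role calls.

Reads per-genome GFF3 annotations, the EtfB protein sidecar FASTA, the hit
table, coverage tables and the product time series from one directory laid
out as :func:`lactoferm.synthetic_data.generate` writes it, then runs the
full inference chain: hit filtering → step/pathway presence → etfAB
neighborhood + cluster calls → substrate and role inference → abundance,
period segmentation, and the community report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotate_io import (
    GeneAnnotation,
    evidence_index,
    filter_hits,
    parse_gff,
    read_hit_table,
)
from .community_dynamics import (
    AbundanceMatrix,
    PeriodSegmentation,
    ProductSeries,
    relative_abundance,
    segment_periods,
    select_top_mags,
)
from .etf_context import (
    EtfLocus,
    EtfReference,
    assign_cluster,
    classify_neighborhood,
    default_references,
    find_etf_pairs,
    read_protein_fasta,
)
from .netdef import MetabolicNetwork, default_network
from .pathway_presence import PathwayCall, StepCall, presence_matrix
from .role_inference import (
    CommunityRole,
    SubstrateInference,
    assign_roles,
    community_report,
    infer_substrate,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    step_matrix: pd.DataFrame  # genome × step booleans
    pathway_table: pd.DataFrame
    step_calls: dict[str, dict[str, StepCall]]
    etf_loci: dict[str, list[EtfLocus]]
    etf_functions: dict[str, list[str]]
    substrates: dict[str, SubstrateInference]
    roles: dict[str, CommunityRole]
    abundance: AbundanceMatrix | None
    top_mags: pd.DataFrame | None
    segmentation: PeriodSegmentation | None
    report: pd.DataFrame | None


def run_pipeline(
    datadir: str | Path,
    network: MetabolicNetwork | None = None,
    references: Sequence[EtfReference] | None = None,
    min_pid: float = 25.0,
    min_qcov: float = 75.0,
    neighborhood_window: int = 5000,
    cluster_margin: float = 5.0,
    abundance_threshold: float = 10.0,
) -> PipelineResult:
    """Run the whole inference chain on one study directory."""
    datadir = Path(datadir)
    if network is None:
        network = default_network()
    if references is None:
        references = default_references()

    genomes: dict[str, list[GeneAnnotation]] = {}
    for gff in sorted(datadir.glob("*.gff")):
        genomes[gff.stem] = parse_gff(gff)

    hits_path = datadir / "hits.tsv"
    kept = []
    if hits_path.exists():
        all_anns = [a for anns in genomes.values() for a in anns]
        kept = filter_hits(read_hit_table(hits_path), min_pid, min_qcov)
        ev_idx = evidence_index(all_anns, kept)
    else:
        ev_idx = {}

    step_matrix, pathway_table, step_calls = presence_matrix(genomes, network, ev_idx)

    etfb_seqs: dict[str, str] = {}
    fasta = datadir / "etfb_proteins.fasta"
    if fasta.exists():
        etfb_seqs = read_protein_fasta(fasta)

    etf_loci: dict[str, list[EtfLocus]] = {}
    etf_functions: dict[str, list[str]] = {}
    from .etf_context import etf_function_call

    for genome_id, anns in genomes.items():
        loci = find_etf_pairs(anns)
        for locus in loci:
            classify_neighborhood(locus, anns, network, window=neighborhood_window)
            seq = etfb_seqs.get(locus.etfB_locus)
            if seq:
                assignment = assign_cluster(seq, references, margin=cluster_margin)
                locus.cluster = assignment.cluster
                locus.nearest_ref = assignment.nearest_ref
                locus.nearest_identity = assignment.identity
            else:
                locus.cluster = "unresolved"
        etf_loci[genome_id] = loci
        etf_functions[genome_id] = [etf_function_call(l) for l in loci]

    pw_by_genome: dict[str, dict[str, PathwayCall]] = {}
    for row in pathway_table.itertuples(index=False):
        pw_by_genome.setdefault(row.genome_id, {})[row.pathway_id] = PathwayCall(
            genome_id=row.genome_id,
            pathway_id=row.pathway_id,
            status=row.status,
            missing_steps=tuple(row.missing_steps.split(",")) if row.missing_steps else (),
        )

    substrates: dict[str, SubstrateInference] = {}
    roles: dict[str, CommunityRole] = {}
    for genome_id in genomes:
        sub = infer_substrate(
            genome_id, pw_by_genome[genome_id], step_calls[genome_id],
            etf_loci[genome_id],
        )
        substrates[genome_id] = sub
        roles[genome_id] = assign_roles(
            genome_id, pw_by_genome[genome_id], step_calls[genome_id], sub
        )

    abundance = top = segmentation = report = None
    cov_path = datadir / "coverage.tsv"
    reads_path = datadir / "sample_reads.tsv"
    if cov_path.exists() and reads_path.exists():
        abundance = relative_abundance(
            pd.read_csv(cov_path, sep="\t"), pd.read_csv(reads_path, sep="\t")
        )
        top = select_top_mags(abundance, n=10)
    prod_path = datadir / "products.csv"
    if prod_path.exists():
        series = ProductSeries.from_csv(prod_path, network)
        segmentation = segment_periods(series)
    if abundance is not None and segmentation is not None:
        report = community_report(
            roles, substrates, abundance.rel_abundance,
            segmentation.periods, threshold=abundance_threshold,
        )

    return PipelineResult(
        step_matrix=step_matrix,
        pathway_table=pathway_table,
        step_calls=step_calls,
        etf_loci=etf_loci,
        etf_functions=etf_functions,
        substrates=substrates,
        roles=roles,
        abundance=abundance,
        top_mags=top,
        segmentation=segmentation,
        report=report,
    )
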