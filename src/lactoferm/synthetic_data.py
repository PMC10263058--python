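"""Seeded generator of a complete synthetic study.

Emits everything the pipeline consumes — per-genome GFF3 annotations with
planted pathways and *etfAB* gene neighborhoods, an EtfB protein sidecar
FASTA, tblastn-style hit tables, per-sample coverage tables, and a
fermentation-product time series — together with a :class:`PlantingManifest`
recording the exact generative truth, so every inference module is testable
end-to-end without any external download.

The default scenario emulates a ten-member lactose-fermenting bioreactor
community: three heterofermentative lactose fermenters (BIF-like), one
bifid-shunt fermenter lacking a recognised lactose transporter (ATO-like),
one homofermenter that also produces succinate via the PEPCK+MD route
(ACT-like), one ethanol-producing homofermenter (SPH-like), three chain
elongators using lactose, lactic acid, and (putatively) ethanol
(LCO/CLOS/ACID-like), and one background genome with housekeeping genes
only.  The product time series realises five operational regimes whose
two most abundant products switch over time, and each genome's abundance
peaks in its role-consistent regime.

Product concentrations are generated phenomenologically (regime means plus
seeded Gaussian jitter, clamped at zero), not by kinetic modelling: the
pipeline only consumes concentrations.  Gene placement is non-overlapping
with configured spacing; *etfAB* neighborhoods are placed at exact planted
edge-to-edge distances, including boundary cases at exactly 5000 and
5001 bp.  EtfB sequences arise by seeded point substitution from the shipped
synthetic reference set.  A fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate_io import HomologyHit, write_hit_table, HIT_TABLE_COLUMNS
from .netdef import MetabolicNetwork, default_network

__all__ = [
    "EtfPairPlan",
    "GenomePlan",
    "RegimePlan",
    "ScenarioConfig",
    "PlantingManifest",
    "GeneratedBundle",
    "default_scenario",
    "generate",
    "generate_boundary_hits",
    "BOUNDARY_HIT_CASES",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_GENE_LEN = 900
_ETF_GAP = 100  # bp between etfA and etfB within a planted pair


@dataclass(frozen=True)
class EtfPairPlan:
    """One planted etfA/etfB pair with its neighborhood and sequence origin."""

    pair_id: str
    neighbors: tuple[tuple[str, int], ...]  # (role step_id, edge distance bp)
    etfb_ref: str  # reference the EtfB sequence is mutated from
    mutation_frac: float
    expected_context: str
    expected_cluster: str
    expected_function: str


@dataclass(frozen=True)
class GenomePlan:
    genome_id: str
    role: str  # descriptive label of the emulated community member
    steps: tuple[str, ...]  # network steps planted as annotated genes
    etf_pairs: tuple[EtfPairPlan, ...] = ()
    expected_roles: frozenset[str] = frozenset()
    expected_substrate: str | None = None
    spacing_bp: int = 200


@dataclass(frozen=True)
class RegimePlan:
    label: str
    days: tuple[float, ...]  # sampled days belonging to this regime
    product_means: Mapping[str, float]  # g/L per analyte
    abundance_weights: Mapping[str, float]  # relative weight per genome


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    genomes: tuple[GenomePlan, ...]
    regimes: tuple[RegimePlan, ...]
    abundance_jitter_sd: float = 0.08  # lognormal sigma on abundance weights
    concentration_jitter_sd: float = 0.3  # g/L additive noise, clamped at 0
    mapped_reads_per_sample: int = 100_000
    total_reads_per_sample: int = 120_000
    hit_rows: tuple[tuple[str, str, str, float, float], ...] = ()
    # (query_id, genome_id, step_id whose locus the hit targets, pid, qcov)


@dataclass
class PlantingManifest:
    """The exact generative truth behind one generated dataset."""

    step_presence: dict[str, frozenset[str]] = field(default_factory=dict)
    pathway_status: dict[str, dict[str, str]] = field(default_factory=dict)
    roles: dict[str, frozenset[str]] = field(default_factory=dict)
    substrates: dict[str, str | None] = field(default_factory=dict)
    etf_calls: list[dict] = field(default_factory=list)
    regimes: list[dict] = field(default_factory=list)
    true_abundance: pd.DataFrame | None = None
    locus_of_step: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass
class GeneratedBundle:
    outdir: Path
    gff_paths: dict[str, Path]
    etfb_fasta: Path
    hits_tsv: Path
    coverage_tsv: Path
    sample_reads_tsv: Path
    products_csv: Path
    manifest: PlantingManifest


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

_LELOIR = ("BGS", "GALM", "GALK", "GALT", "GALE")
_EMP_NO_PFK = ("PGI", "FBA", "GAPDH", "PGK", "ENO", "PYK")
_EMP = ("PGI", "PFK", "FBA", "GAPDH", "PGK", "ENO", "PYK")
_BIFID = ("F6PPK", "TAL", "TKT", "ACK", "PTA", "LDH")
_PK_EXTRA = ("XFP", "RPI", "R5PE")  # ACK, LDH shared with the bifid shunt
_RBO = ("ACAT", "HAD", "ECoAH", "ACD")

_HET = frozenset({"lactose_fermenter_heterofermentative"})
_HOMO = frozenset({"lactose_fermenter_homofermentative"})


def default_scenario(seed: int = 42) -> ScenarioConfig:
    """The deterministic ten-genome community emulating the study system."""
    genomes = (
        GenomePlan(
            "BIF2L", "heterofermentative lactose fermenter",
            ("LacS", *_LELOIR, *_BIFID, *_PK_EXTRA, *_EMP_NO_PFK),
            expected_roles=_HET,
        ),
        GenomePlan(
            "BIF11L", "heterofermentative lactose fermenter",
            ("LacS", *_LELOIR, *_BIFID, *_PK_EXTRA, *_EMP_NO_PFK),
            expected_roles=_HET,
        ),
        GenomePlan(
            "BIF18L", "heterofermentative lactose fermenter (phosphoketolase hole)",
            (*_LELOIR, *_BIFID, "XFP", "RPI", *_EMP_NO_PFK),
            expected_roles=_HET,
        ),
        GenomePlan(
            "ATO3L", "bifid-shunt fermenter without recognised transporter",
            (*_LELOIR, *_BIFID, *_EMP_NO_PFK),
            expected_roles=_HET,
        ),
        GenomePlan(
            "ACT2L", "homofermenter and succinate producer (PEPCK+MD route)",
            ("LacS", *_LELOIR, *_EMP, "PEPCK", "MD", "FUM", "FRD"),
            expected_roles=_HOMO | {"succinate_producer"},
        ),
        GenomePlan(
            "SPH2L", "ethanol-producing homofermenter",
            (*_LELOIR, *_EMP, "ADA", "ADH"),
            expected_roles=_HOMO | {"ethanol_producer"},
        ),
        GenomePlan(
            "LCO1L", "chain elongator using lactose",
            ("LacS", *_LELOIR, *_EMP, *_RBO),
            etf_pairs=(
                EtfPairPlan(
                    "p1", (("ACD", 300),), "EtfB_rbo_ckluyveri_like", 0.10,
                    "reverse_beta_oxidation", "rbo_cluster", "reverse_beta_oxidation",
                ),
            ),
            expected_roles=_HOMO | {"chain_elongator"},
            expected_substrate="carbohydrate:lactose",
        ),
        GenomePlan(
            "CLOS1L", "chain elongator using lactic acid",
            _RBO,
            etf_pairs=(
                EtfPairPlan(
                    "p1", (("LacT", 200), ("ecLDH", 1200)),
                    "EtfB_lactate_awo0871_like", 0.08,
                    "lactate_utilization", "lactate_cluster", "lactate_utilization",
                ),
                EtfPairPlan(
                    "p2", (("ecLDH", 800),), "EtfB_lactate_melsdenii_like", 0.10,
                    "lactate_utilization", "lactate_cluster", "lactate_utilization",
                ),
                EtfPairPlan(
                    "p3", (("ACD", 150),), "EtfB_rbo_ckluyveri_like", 0.10,
                    "reverse_beta_oxidation", "rbo_cluster", "reverse_beta_oxidation",
                ),
            ),
            expected_roles=frozenset({"chain_elongator"}),
            expected_substrate="lactic_acid",
        ),
        GenomePlan(
            "ACID1L", "chain elongator putatively using ethanol",
            (*_RBO, "ADA", "ADH", "BCK", "ecLDH"),
            etf_pairs=(
                EtfPairPlan(
                    "p1", (("ACD", 400),), "EtfB_rbo_ckluyveri_like", 0.12,
                    "reverse_beta_oxidation", "rbo_cluster", "reverse_beta_oxidation",
                ),
            ),
            expected_roles=frozenset({"chain_elongator"}),
            expected_substrate="ethanol_putative",
        ),
        GenomePlan(
            "BACK1", "background genome (housekeeping only)",
            ("GAPDH", "PGK"),
            etf_pairs=(
                # boundary cases: a role gene at exactly the 5-kb window edge
                # is counted; one base farther is not
                EtfPairPlan(
                    "pb1", (("ACD", 5000),), "EtfB_rbo_ckluyveri_like", 0.10,
                    "reverse_beta_oxidation", "rbo_cluster", "reverse_beta_oxidation",
                ),
                EtfPairPlan(
                    "pb2", (("LacT", 5001),), "EtfB_lactate_awo0871_like", 0.10,
                    "unknown", "lactate_cluster", "lactate_utilization",
                ),
            ),
            expected_roles=frozenset(),
        ),
    )
    regimes = (
        RegimePlan(
            "A", (0, 6, 12, 18, 24, 30, 36),
            {"acetic": 8.0, "butyric": 5.0, "hexanoic": 1.2, "lactic": 0.4,
             "succinic": 0.2, "ethanol": 0.2, "octanoic": 0.1, "lactose": 0.3,
             "galactose": 0.1},
            {"BIF2L": 16, "BIF11L": 9, "BIF18L": 8, "ATO3L": 2, "ACT2L": 2,
             "SPH2L": 4, "LCO1L": 18, "CLOS1L": 3, "ACID1L": 3, "BACK1": 2},
        ),
        RegimePlan(
            "B", (44, 50),
            {"ethanol": 6.0, "acetic": 6.0, "lactic": 2.0, "hexanoic": 1.0,
             "octanoic": 0.8, "butyric": 0.8, "succinic": 0.2, "lactose": 0.1,
             "galactose": 0.1},
            {"BIF2L": 6, "BIF11L": 8, "BIF18L": 5, "ATO3L": 35, "ACT2L": 3,
             "SPH2L": 16, "LCO1L": 3, "CLOS1L": 2, "ACID1L": 2, "BACK1": 2},
        ),
        RegimePlan(
            "C", (60, 66, 72, 78, 84),
            {"lactic": 12.0, "acetic": 5.0, "ethanol": 1.0, "butyric": 0.8,
             "hexanoic": 0.3, "lactose": 0.1, "galactose": 0.2},
            {"BIF2L": 5, "BIF11L": 6, "BIF18L": 4, "ATO3L": 60, "ACT2L": 4,
             "SPH2L": 5, "LCO1L": 2, "CLOS1L": 2, "ACID1L": 2, "BACK1": 2},
        ),
        RegimePlan(
            "D", (91, 96, 102, 108),
            {"butyric": 6.0, "succinic": 7.0, "acetic": 3.0, "lactic": 1.0,
             "lactose": 0.1},
            {"BIF2L": 6, "BIF11L": 5, "BIF18L": 4, "ATO3L": 8, "ACT2L": 30,
             "SPH2L": 3, "LCO1L": 2, "CLOS1L": 10, "ACID1L": 8, "BACK1": 2},
        ),
        RegimePlan(
            "E", (114, 132, 150, 200, 250, 282),
            {"butyric": 7.0, "acetic": 6.0, "lactic": 0.8, "hexanoic": 0.8,
             "octanoic": 0.3, "lactose": 0.1},
            {"BIF2L": 6, "BIF11L": 5, "BIF18L": 3, "ATO3L": 6, "ACT2L": 4,
             "SPH2L": 3, "LCO1L": 3, "CLOS1L": 45, "ACID1L": 11, "BACK1": 2},
        ),
    )
    hit_rows = (
        # supra-threshold homologue hits onto planted loci
        ("ecLDH_Awoodii", "ACID1L", "ecLDH", 42.5, 88.0),
        ("ecLDH_Awoodii", "CLOS1L", "ecLDH", 55.0, 92.0),
        ("LacT_ref", "CLOS1L", "LacT", 48.0, 85.0),
        ("LacS_ref", "LCO1L", "LacS", 60.0, 90.0),
        ("LacS_ref", "ACT2L", "LacS", 58.0, 91.0),
        ("LacS_ref", "BIF2L", "LacS", 52.0, 89.0),
        ("LacS_ref", "BIF11L", "LacS", 51.0, 88.0),
        # sub-threshold decoys the filter must drop
        ("ecLDH_Awoodii", "BACK1", "GAPDH", 24.0, 80.0),
        ("LacS_ref", "ATO3L", "BGS", 30.0, 60.0),
    )
    return ScenarioConfig(seed=seed, genomes=genomes, regimes=regimes, hit_rows=hit_rows)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _mutate(seq: str, frac: float, rng: np.random.Generator) -> str:
    s = list(seq)
    n_mut = int(round(len(s) * frac))
    idx = rng.choice(len(s), size=n_mut, replace=False)
    for i in sorted(idx):
        alternatives = [a for a in _AA if a != s[i]]
        s[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(s)


def _gff_attrs(network: MetabolicNetwork, step_id: str, locus: str) -> str:
    step = network.steps[step_id]
    parts = [f"ID={locus}", f"locus_tag={locus}", f"product={step.display_name}"]
    if step.ec_numbers:
        parts.append("ec_number=" + ",".join(sorted(step.ec_numbers)))
    if step.ko_ids:
        parts.append("ko=" + ",".join(sorted(step.ko_ids)))
    if step.cog_ids:
        parts.append("cog=" + ",".join(sorted(step.cog_ids)))
    return ";".join(parts)


_ETF_PRODUCTS = {
    "A": "electron transfer flavoprotein subunit alpha",
    "B": "electron transfer flavoprotein subunit beta",
}


class _GenomeWriter:
    """Accumulates GFF3 lines for one genome with non-overlapping placement."""

    def __init__(self, genome_id: str, network: MetabolicNetwork, spacing: int):
        self.genome_id = genome_id
        self.network = network
        self.spacing = spacing
        self.lines: list[tuple[str, int, str]] = []  # (contig, start, gff line)
        self.counter = 0
        self.planted_steps: set[str] = set()
        self.locus_of_step: dict[str, str] = {}

    def _next_locus(self) -> str:
        self.counter += 1
        return f"{self.genome_id}_{self.counter:05d}"

    def add_gene(self, contig: str, start: int, step_id: str | None,
                 product: str | None = None) -> str:
        end = start + _GENE_LEN - 1
        locus = self._next_locus()
        strand = "+" if self.counter % 2 else "-"
        if step_id is not None:
            attrs = _gff_attrs(self.network, step_id, locus)
            self.planted_steps.add(step_id)
            self.locus_of_step.setdefault(step_id, locus)
        else:
            attrs = f"ID={locus};locus_tag={locus};product={product}"
        self.lines.append(
            (contig, start,
             f"{contig}\tlactoferm_synth\tCDS\t{start}\t{end}\t.\t{strand}\t0\t{attrs}")
        )
        return locus

    def render(self) -> str:
        contigs = sorted({c for c, _, _ in self.lines})
        out = ["##gff-version 3"]
        for c in contigs:
            out.append(f"##sequence-region {c} 1 500000")
        for _, _, line in sorted(self.lines, key=lambda t: (t[0], t[1])):
            out.append(line)
        return "\n".join(out) + "\n"


def _plant_genome(
    plan: GenomePlan,
    network: MetabolicNetwork,
    rng: np.random.Generator,
    ref_seqs: Mapping[str, str],
) -> tuple[_GenomeWriter, list[dict], dict[str, str]]:
    """Write one genome's genes; returns (writer, etf truth rows, etfb seqs)."""
    w = _GenomeWriter(plan.genome_id, network, plan.spacing_bp)
    contig0 = f"{plan.genome_id}_c1"
    cursor = 201
    for step_id in plan.steps:
        w.add_gene(contig0, cursor, step_id)
        cursor += _GENE_LEN + plan.spacing_bp

    etf_rows: list[dict] = []
    etfb_seqs: dict[str, str] = {}
    for k, pair in enumerate(plan.etf_pairs, start=2):
        contig = f"{plan.genome_id}_c{k}"
        # leave upstream room for window-distance neighbors
        span_start = 20001
        # subunit-specific products; they match the generic EtfAB step
        # pattern too, so the pair also evidences the EtfAB step
        a_locus = w.add_gene(contig, span_start, None, _ETF_PRODUCTS["A"])
        b_start = span_start + _GENE_LEN + _ETF_GAP
        b_locus = w.add_gene(contig, b_start, None, _ETF_PRODUCTS["B"])
        w.planted_steps.add("EtfAB")
        w.locus_of_step.setdefault("EtfAB", a_locus)
        span_end = b_start + _GENE_LEN - 1
        down_cursor = span_end  # next free edge downstream
        up_cursor = span_start  # next free edge upstream
        for step_id, dist in pair.neighbors:
            start_down = span_end + dist
            if start_down > down_cursor:
                w.add_gene(contig, start_down, step_id)
                down_cursor = start_down + _GENE_LEN - 1
            else:  # place upstream: gene end at span_start - dist
                end_up = span_start - dist
                w.add_gene(contig, end_up - _GENE_LEN + 1, step_id)
                up_cursor = end_up - _GENE_LEN + 1
        seq = _mutate(ref_seqs[pair.etfb_ref], pair.mutation_frac, rng)
        etfb_seqs[b_locus] = seq
        etf_rows.append(
            {
                "genome_id": plan.genome_id,
                "contig_id": contig,
                "etfA_locus": a_locus,
                "etfB_locus": b_locus,
                "context": pair.expected_context,
                "cluster": pair.expected_cluster,
                "function": pair.expected_function,
            }
        )
    return w, etf_rows, etfb_seqs


def _pathway_status_from_steps(
    present: frozenset[str], network: MetabolicNetwork, near_max: int = 1
) -> dict[str, str]:
    out = {}
    for pw in network.pathways.values():
        missing = [s for s in pw.steps if s not in present]
        if not missing:
            out[pw.pathway_id] = "complete"
        elif len(missing) == len(pw.steps):
            out[pw.pathway_id] = "absent"
        elif len(missing) <= near_max:
            out[pw.pathway_id] = "near_complete"
        else:
            out[pw.pathway_id] = "incomplete"
    return out


def generate(
    config: ScenarioConfig,
    outdir: str | Path,
    network: MetabolicNetwork | None = None,
) -> GeneratedBundle:
    """Generate all study files plus the planting manifest into ``outdir``."""
    from .etf_context import default_references  # deferred: avoids cycle at import

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if network is None:
        network = default_network()
    for plan in config.genomes:
        unknown = [s for s in plan.steps if s not in network.steps]
        if unknown:
            raise ValueError(f"{plan.genome_id}: planted steps not in network: {unknown}")
    rng = np.random.default_rng(config.seed)
    ref_seqs = {r.ref_id: r.sequence for r in default_references()}

    manifest = PlantingManifest()
    gff_paths: dict[str, Path] = {}
    etfb_all: dict[str, str] = {}
    locus_lookup: dict[tuple[str, str], str] = {}

    for plan in config.genomes:
        writer, etf_rows, etfb_seqs = _plant_genome(plan, network, rng, ref_seqs)
        path = outdir / f"{plan.genome_id}.gff"
        path.write_text(writer.render())
        gff_paths[plan.genome_id] = path
        etfb_all.update(etfb_seqs)
        manifest.etf_calls.extend(etf_rows)
        manifest.step_presence[plan.genome_id] = frozenset(writer.planted_steps)
        manifest.pathway_status[plan.genome_id] = _pathway_status_from_steps(
            frozenset(writer.planted_steps), network
        )
        manifest.roles[plan.genome_id] = plan.expected_roles
        manifest.substrates[plan.genome_id] = plan.expected_substrate
        for step_id, locus in writer.locus_of_step.items():
            locus_lookup[(plan.genome_id, step_id)] = locus
    manifest.locus_of_step = locus_lookup

    etfb_fasta = outdir / "etfb_proteins.fasta"
    with etfb_fasta.open("w") as fh:
        for locus in sorted(etfb_all):
            fh.write(f">{locus}\n{etfb_all[locus]}\n")

    hits = [
        HomologyHit(q, g, locus_lookup[(g, step)], pid, qcov)
        for (q, g, step, pid, qcov) in config.hit_rows
    ]
    hits_tsv = outdir / "hits.tsv"
    write_hit_table(hits, hits_tsv)

    # --- abundance and products over the sampled timeline -----------------
    genome_ids = [p.genome_id for p in config.genomes]
    analytes = sorted({a for r in config.regimes for a in r.product_means})
    cov_rows, sample_rows, prod_rows, abund_rows = [], [], [], []
    days: list[float] = []
    for regime in config.regimes:
        for day in regime.days:
            days.append(day)
            sample_id = f"S{int(day):03d}"
            if genome_ids:
                weights = np.array(
                    [regime.abundance_weights.get(g, 0.0) for g in genome_ids],
                    dtype=float,
                )
                jitter = rng.lognormal(0.0, config.abundance_jitter_sd, len(weights))
                weights = weights * jitter
                frac = weights / weights.sum()
                counts = np.rint(frac * config.mapped_reads_per_sample).astype(int)
                counts[int(np.argmax(counts))] += config.mapped_reads_per_sample - counts.sum()
                for g, c in zip(genome_ids, counts):
                    cov_rows.append((sample_id, day, g, int(c), round(c / 1000.0, 3)))
                abund_rows.append(
                    100.0 * counts / config.mapped_reads_per_sample
                )
            sample_rows.append(
                (sample_id, day, config.total_reads_per_sample,
                 config.total_reads_per_sample - config.mapped_reads_per_sample)
            )
            for analyte in analytes:
                mean = regime.product_means.get(analyte, 0.0)
                val = max(0.0, mean + rng.normal(0.0, config.concentration_jitter_sd))
                prod_rows.append((day, analyte, round(val, 4)))

    coverage_tsv = outdir / "coverage.tsv"
    pd.DataFrame(
        cov_rows,
        columns=["sample_id", "day", "genome_id", "mapped_reads", "mean_coverage"],
    ).to_csv(coverage_tsv, sep="\t", index=False)
    sample_reads_tsv = outdir / "sample_reads.tsv"
    pd.DataFrame(
        sample_rows, columns=["sample_id", "day", "total_reads", "unmapped_reads"]
    ).to_csv(sample_reads_tsv, sep="\t", index=False)
    products_csv = outdir / "products.csv"
    pd.DataFrame(prod_rows, columns=["day", "analyte", "g_per_L"]).to_csv(
        products_csv, index=False
    )

    if genome_ids and abund_rows:
        manifest.true_abundance = pd.DataFrame(
            abund_rows, index=pd.Index(days, name="day"), columns=genome_ids
        )
    for regime in config.regimes:
        cod_means = {
            a: m * network.compound(a).thod
            for a, m in regime.product_means.items()
            if network.compound(a).category == "fermentation_product"
        }
        top2 = sorted(cod_means, key=lambda a: (-cod_means[a], a))[:2]
        manifest.regimes.append(
            {
                "label": regime.label,
                "start_day": min(regime.days),
                "end_day": max(regime.days),
                "top2_products": tuple(top2),
            }
        )

    _write_manifest_json(manifest, outdir / "manifest.json")
    return GeneratedBundle(
        outdir=outdir,
        gff_paths=gff_paths,
        etfb_fasta=etfb_fasta,
        hits_tsv=hits_tsv,
        coverage_tsv=coverage_tsv,
        sample_reads_tsv=sample_reads_tsv,
        products_csv=products_csv,
        manifest=manifest,
    )


def _write_manifest_json(manifest: PlantingManifest, path: Path) -> None:
    doc = {
        "step_presence": {g: sorted(s) for g, s in manifest.step_presence.items()},
        "pathway_status": manifest.pathway_status,
        "roles": {g: sorted(r) for g, r in manifest.roles.items()},
        "substrates": manifest.substrates,
        "etf_calls": manifest.etf_calls,
        "regimes": [
            {**r, "top2_products": list(r["top2_products"])} for r in manifest.regimes
        ],
        "true_abundance": (
            {
                str(day): {g: round(v, 6) for g, v in row.items()}
                for day, row in manifest.true_abundance.iterrows()
            }
            if manifest.true_abundance is not None
            else {}
        ),
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# threshold-boundary hit fixture
# ---------------------------------------------------------------------------

#: (percent_identity, query_coverage, expected keep under pid≥25, qcov≥75)
BOUNDARY_HIT_CASES: tuple[tuple[float, float, bool], ...] = (
    (24.9, 75.0, False),
    (25.0, 75.0, True),
    (25.1, 74.9, False),
    (90.0, 75.0, True),
)


def generate_boundary_hits(
    outdir: str | Path | None = None,
    empty: bool = False,
) -> tuple[list[HomologyHit], list[bool]]:
    """Hit fixture straddling the 25% identity / 75% coverage thresholds.

    Returns (hits, expected_keep) per :data:`BOUNDARY_HIT_CASES`; when
    ``outdir`` is given also writes ``boundary_hits.tsv`` (header-only when
    ``empty``).
    """
    hits: list[HomologyHit] = []
    expected: list[bool] = []
    if not empty:
        for i, (pid, qcov, keep) in enumerate(BOUNDARY_HIT_CASES, start=1):
            hits.append(
                HomologyHit(
                    query_id="ecLDH_Awoodii",
                    genome_id="BOUNDARY",
                    subject_locus=f"BOUNDARY_{i:05d}",
                    percent_identity=pid,
                    query_coverage=qcov,
                )
            )
            expected.append(keep)
    if outdir is not None:
        write_hit_table(hits, Path(outdir) / "boundary_hits.tsv")
    return hits, expected
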