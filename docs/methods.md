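# Methods

## The inference problem

A continuously fed, pH-controlled acidogenic bioreactor converting a
lactose-rich dairy coproduct accumulates a shifting mixture of organic acids
and ethanol. Given (i) per-genome functional annotations for the abundant
community members, (ii) homology hit tables for a few marker proteins,
(iii) per-sample read-mapping coverage, and (iv) the product time series,
the package infers each genome's functional role — lactose fermenter
(hetero- or homofermentative), succinate producer, ethanol producer, chain
elongator — and, for chain elongators, the most plausible growth substrate.
All reasoning is presence/absence genomics plus abundance–product
co-occurrence; no expression or flux information is used.

## Metabolic network and presence calling

The network is a declarative document (`data/network.yaml`): ~40 enzymatic
steps, each with EC/KO/COG identifier sets, case-insensitive product-name
patterns and, where relevant, names of homology reference queries; and
twelve pathways composed from those steps, with variant groups for the two
anaerobic succinate routes (PEPCK+MD; malic-enzyme) and the two
butyrate-terminal alternatives (thioesterase; PBT+BCK). The step→identifier
curation uses standard assignments (e.g. β-galactosidase EC 3.2.1.23,
galactokinase EC 2.7.1.6, 6-phosphofructokinase EC 2.7.1.11, butyrate
kinase EC 2.7.2.7); the document is user-replaceable so a different
curation needs no code change.

A step is *present* in a genome when any annotation matches any identifier
set, or a threshold-filtered homology hit for one of the step's reference
queries lands on an annotated locus. Any single source suffices; evidence
records every supporting locus and source, so presence is monotone in the
annotation set — a property the test suite checks on random genomes.
Pathway status is graded by missing-step count: `complete` (0), `near_complete`
(≤1 by default; configurable, since "nearly complete" is a judgment call),
`incomplete`, `absent` (all steps missing). Near-complete pathways are
surfaced in a missing-step report rather than being auto-filled.

Hit filtering keeps hits with percent identity ≥25 and query coverage ≥75,
both boundaries inclusive. These are the only filters applied; upstream
search parameters are the caller's business.

## *etfAB* function calls

Adjacent *etfA*/*etfB* genes (consecutive loci, either order, intergenic
gap ≤500 bp) form a candidate pair. Two corroborating signals decide its
function:

1. **Neighborhood context.** Genes whose nearest edge lies within 5 kb
   (inclusive, edge-to-edge from the pair's span, strand ignored) are
   scanned for role genes: LacT or ecLDH → lactate-utilization signal;
   ACD, ACAT, HAD or ECoAH → β-oxidation signal; both → ambiguous;
   neither → unknown. The call is invariant under mirroring the contig's
   coordinate system.
2. **EtfB sequence cluster.** The EtfB is assigned the cluster
   (lactate-utilizing vs β-oxidising) of its nearest reference by global
   Needleman–Wunsch identity — BLOSUM62, affine gaps with a run of length
   *k* costing 11 + *k*, end gaps penalised. Identity is defined as the
   maximal number of identical aligned pairs among score-optimal
   alignments divided by that alignment's columns (ties then minimise
   columns); this makes the statistic symmetric and deterministic, and the
   DP that computes it is cross-checked in tests against an independent
   suffix-recursion oracle and against Biopython's optimal score. If the
   two clusters' best identities differ by less than 5 percentage points
   (a tunable margin) the cluster is `unresolved`.

The nearest-reference proxy deliberately replaces a bootstrapped
maximum-likelihood tree: at the scale of a handful of EtfBs per genome the
cluster question is "which characterised reference is this most like", the
neighborhood remains the primary signal, and the proxy is swappable for a
real tree through the same interface. The shipped reference set is
synthetic (three 120-aa stand-ins labelled after the characterised
proteins they emulate — see `data/etf_references_synthetic.fasta`); real
reference sequences drop in via the same FASTA + metadata interface.

Combining the signals: agreement yields the shared function; a single
informative signal decides alone; an ambiguous context with a resolved
cluster follows the cluster; a genuine conflict, or ambiguity on both
sides, yields `both_possible`.

## Substrate and role rules

For each genome, ordered rules produce at most one substrate label:
(i) it is a chain elongator iff reverse β-oxidation is complete or
near-complete *and* some EtfAB pair serves β-oxidation (or both functions);
(ii) substrate `lactic_acid` iff LacT, ecLDH and a lactate-type EtfAB pair
are all present; (iii) else `carbohydrate:<sugar>` iff a complete
carbohydrate route exists (lactose: Leloir plus any of glycolysis, bifid
shunt or phosphoketolase; the tagatose-6P route alone also qualifies);
(iv) else `ethanol_putative` iff ADA and ADH are present — always with a
caveat, because both enzymes are widespread and reversible; (v) else
`unresolved`. Ablation of any rule-(ii) feature provably drops the genome
to a later rule.

Roles may co-occur. Heterofermentative lactose fermenter: complete Leloir
plus a complete/near-complete bifid shunt or phosphoketolase arm.
Homofermentative: complete Leloir and glycolysis without such an arm.
Succinate producer: any succinate variant complete. Ethanol producer:
ADA+ADH plus a complete sugar route. A fermenter lacking a recognised
lactose transporter keeps its role with the caveat "transporter not
identified" — missing transporters are a known artefact of incomplete MAGs,
and excluding such genomes would discard members whose abundance dynamics
clearly track lactose consumption. By default `near_complete` pathways
qualify for roles (strict mode restricts to `complete`).

## Community dynamics and COD accounting

Relative abundance is each genome's mapped reads over all mapped reads per
sample (rows sum to 100%); the mapped fraction of total reads is reported
separately rather than folded in. Genomes rank by maximum observed
abundance, ties by mean then by id. Operational periods: per sample, the
two most abundant fermentation products by COD equivalents (carbohydrates
excluded; exact ties break lexicographically and are flagged); a new
period starts when the unordered top-2 set changes and persists for ≥2
consecutive samples, which absorbs single-sample excursions. Periods are
labelled A, B, C… and span contiguous sampled days, so segmentation is
invariant to uniform rescaling of all concentrations.

ThOD: for C_aH_bO_cN_d, moles O₂ = a + b/4 − c/2 − 3d/4 (nitrogen leaves
as ammonia — the standard convention for fermentation broths, where
nitrification is absent), clamped at zero for fully oxidised species;
g COD/g = 32·nO₂/molar mass. Recovery percentages are ratios of summed
product COD to a reference COD; the summary uses the ratio of time
averages (matching how stream tables are built), with a per-timepoint mean
available as an option. Hydraulic retention time is volume/flow.

## Synthetic-data generator

The generator emulates the study conditions the pipeline is meant for: ten
genomes — three heterofermentative lactose fermenters (one of them with a
phosphoketolase hole at R5PE), a transporterless bifid-shunt fermenter, a
homofermenter/succinate producer (PEPCK+MD route), an ethanol-producing
homofermenter, three chain elongators with substrates lactose / lactic
acid / ethanol, and a background genome — with 24 samples over days 0–282
across five product regimes (butyric+acetic; ethanol+acetic;
lactic+acetic; butyric+succinic; butyric+acetic), each genome's abundance
peaking in its role-consistent regime. Genes are 900 bp, non-overlapping,
default spacing 200 bp; each *etfAB* pair sits on its own contig so
neighborhoods cannot contaminate each other, with role genes at exact
planted edge distances including 5000 and 5001 bp boundary cases. EtfB
sequences arise by seeded point substitution (8–12%) from the shipped
references; mutation is substitution-only so planted identities are
predictable. Hit tables mix supra-threshold homologue hits with
sub-threshold decoys (including a below-threshold lactose-permease hit on
the transporterless fermenter). Abundances are drawn from per-regime
weights with lognormal jitter (σ = 0.08) and converted to integer read
counts out of 100 000 mapped (total 120 000) per sample; concentrations
are regime means plus Gaussian noise (σ = 0.3 g/L, clamped at 0).
Concentration noise and top-2 separations are sized so regime identity is
stable at any seed; products are phenomenological — no kinetics, no
carbon closure over time — so passing tests demonstrate correct inference
logic, not robustness to assembly error, chimeric bins, annotation noise,
or ambiguous real-world neighborhoods. A fixed seed yields byte-identical
files; the planted truth (manifest) is seed-independent.

## Numerical and design notes

- Coordinates are 1-based inclusive (GFF3) throughout; the only half-open
  arithmetic is internal to placement.
- The alignment DP is exact, pure Python, O(nm) with three affine states;
  at the 120-aa scale of EtfB comparisons this is milliseconds per pair.
- Degenerate inputs fail loudly: empty sequences, zero mapped reads,
  non-positive windows/volumes/flows, dangling hit loci and dangling
  network step references all raise with the offending name.
- Problem sizes in tests and the acceptance script (ten genomes, 24
  samples, ≤12-residue oracle alignments, 100-genome property sweeps) were
  chosen as the smallest sizes that still exercise every decision branch
  of the scenario.

## Known limitations

- Absence of a gene is weak evidence in draft MAGs; the role rules encode
  caveats (transporter, ethanol) but cannot repair missing annotations.
- No prediction of terminal chain length (butyrate vs hexanoate vs
  octanoate): the evidence there is abundance–product co-occurrence, not a
  genomic feature, and the package reports the co-occurrence only.
- The two-cluster EtfB model leaves genuinely divergent EtfBs (a possible
  third, dual-function cluster) as `unresolved`/`both_possible` rather than
  forcing a call; adding a third reference cluster is a data change, not a
  code change.
- Multi-subunit steps (PTS components, EtfAB) are satisfied by any matching
  subunit; strict co-localisation of subunits is not enforced.
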