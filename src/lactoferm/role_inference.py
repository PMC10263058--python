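"""Community-role assignment and chain-elongation substrate inference.

The decision rules turn per-genome pathway calls, step presence and EtfAB
function calls into the genome's functional role(s) in a lactose-fermenting
community, and, for chain elongators, the inferred growth substrate.  Five
diagnostic genomic features drive the substrate inference: (1) carbohydrate
utilization pathways, (2) the reverse β-oxidation pathway with its
ACD-complexing EtfAB, (3) LacT + ecLDH + an ecLDH-complexing EtfAB pair,
(4) ADA + ADH, and (5) the predicted *absence* of the features diagnostic of
other substrates.  The rules are applied strictly in order so every chain
elongator gets exactly one substrate label:

    (i)   chain elongator iff reverse β-oxidation is complete/near-complete
          and at least one EtfAB pair serves β-oxidation (or both functions);
    (ii)  lactic acid iff LacT and ecLDH are present and at least one EtfAB
          pair serves lactate utilization (or both);
    (iii) a carbohydrate iff a complete carbohydrate route exists and (ii)
          failed;
    (iv)  ethanol (putative, always flagged) iff ADA and ADH are present and
          (ii) and (iii) failed;
    (v)   otherwise unresolved.

ADA/ADH are common to many non-elongating taxa and work in both directions,
hence the mandatory caveat on rule (iv).

Roles may co-occur (a homofermentative lactose fermenter can also be a
succinate producer); only the substrate label is exclusive.  A genome with a
complete Leloir route and β-galactosidase but no recognised lactose
transporter is still labelled a lactose fermenter, with the caveat
"transporter not identified" — incomplete assembly or a missed gene
prediction can hide a transporter, and abundance during lactose-consuming
periods argues for the capability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .netdef import MetabolicNetwork
from .pathway_presence import PathwayCall, StepCall
from .etf_context import EtfLocus, etf_function_call

__all__ = [
    "SubstrateInference",
    "CommunityRole",
    "infer_substrate",
    "assign_roles",
    "community_report",
]

#: carbohydrate-utilization routes: sugar -> pathway combinations, any of
#: which (all members complete) evidences utilization of that sugar
CARBOHYDRATE_ROUTES: dict[str, tuple[tuple[str, ...], ...]] = {
    "lactose": (
        ("leloir", "emp_glycolysis"),
        ("leloir", "bifid_shunt"),
        ("leloir", "phosphoketolase"),
        ("tagatose6p",),
    ),
    "glucose": (("emp_glycolysis",),),
}

_OK_FOR_ROLE = ("complete", "near_complete")


@dataclass(frozen=True)
class SubstrateInference:
    genome_id: str
    is_chain_elongator: bool
    substrate: str | None  # lactic_acid | carbohydrate:<sugar> | ethanol_putative | unresolved
    evidence: tuple[tuple[str, bool], ...] = ()
    caveats: tuple[str, ...] = ()


@dataclass(frozen=True)
class CommunityRole:
    genome_id: str
    roles: frozenset[str]
    notes: tuple[str, ...] = ()


def _pw_status(pathway_calls: Mapping[str, PathwayCall], pathway_id: str) -> str:
    call = pathway_calls.get(pathway_id)
    return call.status if call is not None else "absent"


def _present(step_calls: Mapping[str, StepCall], step_id: str) -> bool:
    call = step_calls.get(step_id)
    return bool(call and call.present)


def _complete_carb_routes(pathway_calls: Mapping[str, PathwayCall]) -> list[str]:
    sugars = []
    for sugar, combos in CARBOHYDRATE_ROUTES.items():
        for combo in combos:
            if all(_pw_status(pathway_calls, p) == "complete" for p in combo):
                sugars.append(sugar)
                break
    return sugars


def infer_substrate(
    genome_id: str,
    pathway_calls: Mapping[str, PathwayCall],
    step_calls: Mapping[str, StepCall],
    etf_loci: Sequence[EtfLocus],
    allow_near_complete: bool = True,
) -> SubstrateInference:
    """Apply the ordered diagnostic-feature rules to one genome."""
    rbo_status = _pw_status(pathway_calls, "rbo_chain_elongation")
    ok_statuses = _OK_FOR_ROLE if allow_near_complete else ("complete",)
    etf_functions = [etf_function_call(l) for l in etf_loci]
    has_rbo_etf = any(f in ("reverse_beta_oxidation", "both_possible") for f in etf_functions)
    has_lactate_etf = any(f in ("lactate_utilization", "both_possible") for f in etf_functions)
    lact = _present(step_calls, "LacT")
    ecldh = _present(step_calls, "ecLDH")
    ada = _present(step_calls, "ADA")
    adh = _present(step_calls, "ADH")
    carb_sugars = _complete_carb_routes(pathway_calls)

    evidence = (
        ("carbohydrate_route_complete", bool(carb_sugars)),
        ("rbo_pathway", rbo_status in ok_statuses),
        ("rbo_etfab", has_rbo_etf),
        ("lact_present", lact),
        ("ecldh_present", ecldh),
        ("lactate_etfab", has_lactate_etf),
        ("ada_adh_present", ada and adh),
    )

    is_elongator = rbo_status in ok_statuses and has_rbo_etf
    if not is_elongator:
        return SubstrateInference(genome_id, False, None, evidence)

    caveats: list[str] = []
    if lact and ecldh and has_lactate_etf:
        substrate = "lactic_acid"
    elif carb_sugars:
        substrate = f"carbohydrate:{carb_sugars[0]}"
    elif ada and adh:
        substrate = "ethanol_putative"
        caveats.append(
            "ADA/ADH are common to many taxa and reversible; ethanol use is putative"
        )
    else:
        substrate = "unresolved"
    return SubstrateInference(genome_id, True, substrate, evidence, tuple(caveats))


def assign_roles(
    genome_id: str,
    pathway_calls: Mapping[str, PathwayCall],
    step_calls: Mapping[str, StepCall],
    substrate: SubstrateInference,
    allow_near_complete: bool = True,
) -> CommunityRole:
    """Community role set of one genome from its pathway and substrate calls."""
    ok = _OK_FOR_ROLE if allow_near_complete else ("complete",)
    roles: set[str] = set()
    notes: list[str] = []

    leloir = _pw_status(pathway_calls, "leloir")
    emp = _pw_status(pathway_calls, "emp_glycolysis")
    bifid = _pw_status(pathway_calls, "bifid_shunt")
    pk = _pw_status(pathway_calls, "phosphoketolase")
    hetero_arm = bifid in ok or pk in ok

    if leloir == "complete" and hetero_arm:
        roles.add("lactose_fermenter_heterofermentative")
    if leloir == "complete" and emp == "complete" and not hetero_arm:
        roles.add("lactose_fermenter_homofermentative")
    if roles & {"lactose_fermenter_heterofermentative", "lactose_fermenter_homofermentative"}:
        if not (_present(step_calls, "LacS") or _present(step_calls, "PTSLac")):
            notes.append("transporter not identified")

    succ_complete = any(
        pathway_calls[p].status == "complete"
        for p in pathway_calls
        if p.startswith("succinate_route_")
    )
    if succ_complete:
        roles.add("succinate_producer")

    sugar_complete = bool(_complete_carb_routes(pathway_calls))
    if _present(step_calls, "ADA") and _present(step_calls, "ADH") and sugar_complete:
        roles.add("ethanol_producer")

    if substrate.is_chain_elongator:
        roles.add("chain_elongator")
        notes.extend(substrate.caveats)

    return CommunityRole(genome_id=genome_id, roles=frozenset(roles), notes=tuple(notes))


def community_report(
    roles: Mapping[str, CommunityRole],
    substrates: Mapping[str, SubstrateInference],
    abundance: pd.DataFrame,
    periods: Sequence,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Join roles, substrates and abundance-period co-occurrence.

    For each genome lists the operational periods in which its relative
    abundance reaches ``threshold`` percent (inclusive) in at least one
    sample, alongside those periods' dominant products.  ``abundance`` is a
    (sample day × genome) percent matrix; ``periods`` is an iterable of
    objects with label/start_day/end_day/top2_products.
    """
    rows = []
    for genome_id in abundance.columns:
        col = abundance[genome_id]
        active, products = [], []
        for per in periods:
            in_period = col[(col.index >= per.start_day) & (col.index <= per.end_day)]
            if (in_period >= threshold).any():
                active.append(per.label)
                products.append("+".join(per.top2_products))
        role = roles.get(genome_id)
        sub = substrates.get(genome_id)
        rows.append(
            {
                "genome_id": genome_id,
                "roles": ";".join(sorted(role.roles)) if role else "",
                "substrate": (sub.substrate or "") if sub else "",
                "abundant_in_periods": ",".join(active),
                "period_products": ";".join(products),
                "max_abundance": float(col.max()),
            }
        )
    return pd.DataFrame(rows)
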