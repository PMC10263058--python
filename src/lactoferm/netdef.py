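"""Declarative metabolic network and compound registry.

The network describes the known routes from lactose to the major extracellular
fermentation products of an acidogenic dairy-coproduct bioreactor: lactose
uptake and hydrolysis, the Leloir and tagatose-6-phosphate routes, EMP
glycolysis, the bifid shunt and phosphoketolase heterofermentation, two
anaerobic succinate routes, reverse β-oxidation (chain elongation), the
alternative butyrate-terminal steps, ethanol production/utilization, and
lactate utilization via the electron-confurcating lactate dehydrogenase
(ecLDH) / EtfAB complex.

Each enzymatic step carries the identifier sets (EC, KO, COG, product-name
patterns, homology query names) used to recognise it in genome annotations.
The default document shipped with the package (``data/network.yaml``) encodes
curated standard identifiers and is user-replaceable: curation differences
require no code changes.

The compound registry carries elemental formulas from which theoretical
oxygen demand (ThOD, g O2 per g compound) is derived, the conversion factor
used throughout COD accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ATOMIC_WEIGHTS",
    "CompoundSpec",
    "ReactionStep",
    "PathwayDefinition",
    "MetabolicNetwork",
    "NetworkDefinitionError",
    "molar_mass",
    "thod_factor",
    "load_network",
    "default_network",
]

# Standard atomic weights (IUPAC 2021, rounded to 3 decimals).
ATOMIC_WEIGHTS: dict[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
}

#: molar mass of O2 used in ThOD arithmetic
_O2_MASS = 2 * ATOMIC_WEIGHTS["O"]


class NetworkDefinitionError(ValueError):
    """Raised when a network document is malformed or internally inconsistent."""


def molar_mass(formula: Mapping[str, int | float]) -> float:
    """Molar mass (g/mol) of an elemental composition over C, H, O, N."""
    if not formula or sum(formula.values()) <= 0:
        raise ValueError("empty formula")
    unknown = set(formula) - set(ATOMIC_WEIGHTS)
    if unknown:
        raise ValueError(f"unsupported elements: {sorted(unknown)}")
    if any(v < 0 for v in formula.values()):
        raise ValueError("negative element count")
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())


def thod_factor(formula: Mapping[str, int | float]) -> float:
    """Theoretical oxygen demand of a compound, g O2 per g compound.

    Balances full combustion C_a H_b O_c N_d + x O2 -> a CO2 + water, with
    nitrogen excreted as ammonia (no nitrification — the standard convention
    for COD accounting of fermentation broths), giving

        x = a + b/4 - c/2 - 3 d/4   moles O2 per mole compound.

    Fully (or over-) oxidised species such as CO2 clamp to 0.
    """
    mm = molar_mass(formula)  # validates
    a = formula.get("C", 0)
    b = formula.get("H", 0)
    c = formula.get("O", 0)
    d = formula.get("N", 0)
    n_o2 = a + b / 4.0 - c / 2.0 - 3.0 * d / 4.0
    return max(0.0, n_o2) * _O2_MASS / mm


@dataclass(frozen=True)
class CompoundSpec:
    """A fermentation analyte with elemental formula and derived ThOD.

    ``category`` separates carbohydrates (substrates) from fermentation
    products so that product-ranking logic can exclude sugars.
    """

    name: str
    formula: Mapping[str, int]
    category: str = "fermentation_product"  # or "carbohydrate", "inorganic"

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)

    @property
    def thod(self) -> float:
        """g O2 per g compound."""
        return thod_factor(self.formula)


@dataclass(frozen=True)
class ReactionStep:
    """A named enzymatic step with the identifier sets that recognise it.

    A gene annotation supports the step if any identifier matches: EC, KO or
    COG exactly, or a product pattern as a case-insensitive substring.
    ``homology_queries`` names reference proteins whose filtered tblastn-style
    hits also evidence the step (e.g. the *Acetobacterium woodii* ecLDH).
    """

    step_id: str
    display_name: str
    ec_numbers: frozenset[str] = frozenset()
    ko_ids: frozenset[str] = frozenset()
    cog_ids: frozenset[str] = frozenset()
    product_patterns: frozenset[str] = frozenset()
    homology_queries: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (
            self.ec_numbers
            or self.ko_ids
            or self.cog_ids
            or self.product_patterns
            or self.homology_queries
        ):
            raise NetworkDefinitionError(
                f"step {self.step_id!r}: at least one identifier set must be non-empty"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    """An ordered list of steps forming one route; variants share a group label."""

    pathway_id: str
    steps: tuple[str, ...]
    variant_group: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.steps)) != len(self.steps):
            raise NetworkDefinitionError(
                f"pathway {self.pathway_id!r}: duplicate steps"
            )


@dataclass
class MetabolicNetwork:
    """Registries of steps, pathways and compounds with referential integrity."""

    steps: dict[str, ReactionStep] = field(default_factory=dict)
    pathways: dict[str, PathwayDefinition] = field(default_factory=dict)
    compounds: dict[str, CompoundSpec] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.pathways:
            raise NetworkDefinitionError("no pathways defined")
        dangling = sorted(
            {
                step_id
                for pw in self.pathways.values()
                for step_id in pw.steps
                if step_id not in self.steps
            }
        )
        if dangling:
            raise NetworkDefinitionError(
                f"pathways reference undefined steps: {', '.join(dangling)}"
            )

    def variant_pathways(self, group: str) -> list[PathwayDefinition]:
        """All pathway variants carrying a given ``variant_group`` label."""
        return [p for p in self.pathways.values() if p.variant_group == group]

    def compound(self, name: str) -> CompoundSpec:
        try:
            return self.compounds[name]
        except KeyError:
            raise KeyError(f"unknown compound: {name!r}") from None

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "step_id": s.step_id,
                    "display_name": s.display_name,
                    "ec_numbers": sorted(s.ec_numbers),
                    "ko_ids": sorted(s.ko_ids),
                    "cog_ids": sorted(s.cog_ids),
                    "product_patterns": sorted(s.product_patterns),
                    "homology_queries": sorted(s.homology_queries),
                }
                for s in self.steps.values()
            ],
            "pathways": [
                {
                    "pathway_id": p.pathway_id,
                    "steps": list(p.steps),
                    "variant_group": p.variant_group,
                    "description": p.description,
                }
                for p in self.pathways.values()
            ],
            "compounds": [
                {
                    "name": c.name,
                    "formula": dict(c.formula),
                    "category": c.category,
                }
                for c in self.compounds.values()
            ],
        }


def _parse_step(raw: Mapping) -> ReactionStep:
    return ReactionStep(
        step_id=str(raw["step_id"]),
        display_name=str(raw.get("display_name", raw["step_id"])),
        ec_numbers=frozenset(map(str, raw.get("ec_numbers") or [])),
        ko_ids=frozenset(map(str, raw.get("ko_ids") or [])),
        cog_ids=frozenset(map(str, raw.get("cog_ids") or [])),
        product_patterns=frozenset(map(str, raw.get("product_patterns") or [])),
        homology_queries=frozenset(map(str, raw.get("homology_queries") or [])),
    )


def load_network(source: str | Path) -> MetabolicNetwork:
    """Load and validate a network document (YAML text or a path to one).

    Raises :class:`NetworkDefinitionError` for malformed documents, dangling
    step references (the error names them), duplicate pathway ids, or a
    document defining no pathways.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif "\n" not in source and source.endswith((".yaml", ".yml", ".json")):
        text = Path(source).read_text()
    else:
        text = source
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NetworkDefinitionError(f"malformed network document: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise NetworkDefinitionError("no pathways defined")

    net = MetabolicNetwork()
    for raw in doc.get("steps") or []:
        step = _parse_step(raw)
        if step.step_id in net.steps:
            raise NetworkDefinitionError(f"duplicate step_id: {step.step_id!r}")
        net.steps[step.step_id] = step
    for raw in doc.get("pathways") or []:
        pw = PathwayDefinition(
            pathway_id=str(raw["pathway_id"]),
            steps=tuple(map(str, raw.get("steps") or [])),
            variant_group=raw.get("variant_group"),
            description=str(raw.get("description", "")),
        )
        if pw.pathway_id in net.pathways:
            raise NetworkDefinitionError(f"duplicate pathway_id: {pw.pathway_id!r}")
        net.pathways[pw.pathway_id] = pw
    for raw in doc.get("compounds") or []:
        spec = CompoundSpec(
            name=str(raw["name"]),
            formula={k: int(v) for k, v in (raw.get("formula") or {}).items()},
            category=str(raw.get("category", "fermentation_product")),
        )
        net.compounds[spec.name] = spec
    net.validate()
    return net


def default_network() -> MetabolicNetwork:
    """The network document shipped with the package."""
    text = resources.files("lactoferm.data").joinpath("network.yaml").read_text()
    return load_network(text)
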