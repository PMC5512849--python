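"""Metabolic network definition: species, reactions, regulation edges, conserved pools.

The network is declared in a structured YAML file (see ``data/ecoli_network.yaml``)
listing every species with its compartment and carbon count, every reaction with
its stoichiometry and rate-law form, the transcription-factor regulation edges,
and the conserved cofactor pools.  The module also ships the curated central
carbon metabolism network of *Escherichia coli* used throughout the package:
glycolysis, pentose phosphate pathway, TCA cycle, glyoxylate shunt, anaplerosis,
fermentative branches (LDH, Pfl, ALDH/ADH, Pta-Ack, Frd) and the respiratory
chain (Nuo, Ndh, Cyo, Cyd) coupled to a conserved quinone pool.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Species",
    "RateLawSpec",
    "ReactionSpec",
    "RegulationEdge",
    "ConservedPool",
    "MetabolicNetwork",
    "load_network",
    "validate_network",
    "CORE_ENZYMES",
]

#: Enzymes every shipped E. coli network must contain (central carbon +
#: fermentative + respiratory reactions of the model).
CORE_ENZYMES = (
    "PTS Glk Pfk Fba L_Emp Pyk Pps PDH Pfl LDH ALDH ADH PTACK Acs CS ICDH "
    "aKGDH SDH Frd Fum MDH Mez Pck Ppc Icl MS G6PDH PGDH Rpe Rpi TktA TktB "
    "Tal Fbp Nuo Ndh Cyo Cyd npts"
).split()

VALID_COMPARTMENTS = {"extracellular", "cytoplasm", "pool", "boundary", "sink"}


@dataclass(frozen=True)
class Species:
    id: str
    compartment: str  # extracellular | cytoplasm | pool | boundary | sink
    carbon: int = 0
    mw: float | None = None  # g/mmol * 1000, i.e. molar mass in g/mol (extracellular)


@dataclass(frozen=True)
class RateLawSpec:
    """Declarative rate law, compiled by :mod:`aeroferm.kinetics`.

    forms
    -----
    mm          irreversible multiplicative Michaelis-Menten
    rev         reversible MM with mass-action ratio numerator
    mass_action k * product of substrate concentrations
    constant    zero-order (boundary input; toy fixtures)

    ``modifiers`` entries (dicts):
      {type: activation, species, K, beta}  -> *(1 + beta*A/(K+A))
      {type: inhibition, species, K}        -> /(1 + I/K)
      {type: ratio, num, den, K}            -> *num/(num + K*den)
    A substrate entry may carry an ``h`` symbol for a Hill exponent
    (S^h/(K^h+S^h), cooperative binding); default is plain MM.
    Every K / beta / h / vmax entry is a parameter *symbol* resolved against
    the ParameterSet at compile time.
    """

    form: str
    vmax: str
    substrates: tuple = ()  # tuple of (species, K-symbol[, h-symbol])
    products: tuple = ()  # rev only: (species, K-symbol)
    keq: str | None = None  # rev only
    modifiers: tuple = ()


@dataclass(frozen=True)
class ReactionSpec:
    id: str
    stoichiometry: Mapping[str, float]
    rate_law: RateLawSpec
    reversible: bool = False
    gene: str | None = None


@dataclass(frozen=True)
class RegulationEdge:
    tf: str  # "Fnr" | "ArcA"
    gene: str  # target gene; matched against ReactionSpec.gene
    sign: str  # "activation" | "repression"
    strength: str  # parameter symbol for a (activation) or r (repression)


@dataclass(frozen=True)
class ConservedPool:
    members: tuple[str, ...]
    total: str  # parameter symbol for the conserved total


@dataclass
class MetabolicNetwork:
    species: dict[str, Species]
    reactions: dict[str, ReactionSpec]
    regulation_edges: list[RegulationEdge]
    conserved_pools: list[ConservedPool]
    #: biomass precursor demand, mmol per gDW (normalized against the biomass
    #: carbon-content parameter at compile time)
    biomass_drain: dict[str, float] = field(default_factory=dict)
    name: str = "network"

    def copy(self) -> "MetabolicNetwork":
        return copy.deepcopy(self)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    def species_in(self, compartment: str) -> list[str]:
        return [s.id for s in self.species.values() if s.compartment == compartment]

    def edges_for_gene(self, gene: str | None) -> list[RegulationEdge]:
        if gene is None:
            return []
        return [e for e in self.regulation_edges if e.gene == gene]

    def parameter_symbols(self) -> set[str]:
        """All parameter symbols the network's rate laws and tables reference."""
        syms: set[str] = set()
        for rxn in self.reactions.values():
            rl = rxn.rate_law
            syms.add(rl.vmax)
            for sub in rl.substrates:
                syms.update(s for s in sub[1:] if s)
            for _, k in rl.products:
                syms.add(k)
            if rl.keq:
                syms.add(rl.keq)
            for mod in rl.modifiers:
                for key in ("K", "beta"):
                    if key in mod:
                        syms.add(mod[key])
        for edge in self.regulation_edges:
            syms.add(edge.strength)
        for pool in self.conserved_pools:
            syms.add(pool.total)
        return syms


def _parse_rate_law(d: Mapping) -> RateLawSpec:
    return RateLawSpec(
        form=d["form"],
        vmax=d["vmax"],
        substrates=tuple(
            (s["species"], s.get("K", ""), s["h"]) if "h" in s else (s["species"], s.get("K", ""))
            for s in d.get("substrates", [])
        ),
        products=tuple((s["species"], s.get("K", "")) for s in d.get("products", [])),
        keq=d.get("keq"),
        modifiers=tuple(dict(m) for m in d.get("modifiers", [])),
    )


def network_from_dict(doc: Mapping) -> MetabolicNetwork:
    species = {
        s["id"]: Species(
            id=s["id"],
            compartment=s["compartment"],
            carbon=int(s.get("carbon", 0)),
            mw=s.get("mw"),
        )
        for s in doc["species"]
    }
    reactions = {}
    for r in doc["reactions"]:
        reactions[r["id"]] = ReactionSpec(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            rate_law=_parse_rate_law(r["rate_law"]),
            reversible=bool(r.get("reversible", False)),
            gene=r.get("gene"),
        )
    edges = [
        RegulationEdge(tf=e["tf"], gene=e["gene"], sign=e["sign"], strength=e["strength"])
        for e in doc.get("regulation_edges", [])
    ]
    pools = [
        ConservedPool(members=tuple(p["members"]), total=p["total"])
        for p in doc.get("conserved_pools", [])
    ]
    return MetabolicNetwork(
        species=species,
        reactions=reactions,
        regulation_edges=edges,
        conserved_pools=pools,
        biomass_drain={k: float(v) for k, v in doc.get("biomass_drain", {}).items()},
        name=doc.get("name", "network"),
    )


def load_network(source=None) -> MetabolicNetwork:
    """Load a network from a YAML path/stream; default is the packaged E. coli network."""
    if source is None:
        ref = resources.files("aeroferm.data").joinpath("ecoli_network.yaml")
        with ref.open("r") as fh:
            doc = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return network_from_dict(doc)


def validate_network(
    network: MetabolicNetwork, required_enzymes: Iterable[str] | None = CORE_ENZYMES
) -> list[str]:
    """Check the network's structural invariants.

    Returns a machine-readable list of violation strings (empty == valid):
    undeclared species in stoichiometries, conserved pools whose members are
    created/destroyed by some reaction (nonzero pool row-sum), and missing
    core enzymes.  ``required_enzymes=None`` skips the enzyme-completeness
    check (used for toy networks).
    """
    violations: list[str] = []
    for rxn in network.reactions.values():
        for sp in rxn.stoichiometry:
            if sp not in network.species:
                violations.append(f"reaction {rxn.id}: undeclared species {sp}")
    for pool in network.conserved_pools:
        missing = [m for m in pool.members if m not in network.species]
        for m in missing:
            violations.append(f"pool {pool.total}: undeclared member {m}")
        for rxn in network.reactions.values():
            row_sum = sum(rxn.stoichiometry.get(m, 0.0) for m in pool.members)
            if abs(row_sum) > 1e-12:
                violations.append(
                    f"pool {'+'.join(pool.members)}: reaction {rxn.id} changes the "
                    f"pool total (row-sum {row_sum:g})"
                )
    if required_enzymes is not None:
        for enz in required_enzymes:
            if enz not in network.reactions:
                violations.append(f"missing core enzyme {enz}")
    # carbon consistency: each reaction conserves declared carbon counts
    for rxn in network.reactions.values():
        cbal = sum(
            coef * network.species[sp].carbon
            for sp, coef in rxn.stoichiometry.items()
            if sp in network.species
        )
        if abs(cbal) > 1e-9:
            violations.append(f"reaction {rxn.id}: carbon imbalance {cbal:g}")
    return violations
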