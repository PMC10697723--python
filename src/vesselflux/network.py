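"""Reduced core metabolic network and its JSON/SBML serialization.

The packaged network is an original ~50-reaction reconstruction covering the
pathway roles needed for condition comparisons in a tumor-cell energy model:
glycolysis (split into upper and lower halves), lactate exchange, pyruvate
entry into the TCA cycle, glutaminolysis (glutamine -> glutamate ->
alpha-ketoglutarate), oxidative phosphorylation with O2 exchange, an ATP
demand reaction, hyaluronic-acid (HA) synthesis from UDP-glucuronate plus
UDP-N-acetylglucosamine, a biomass/growth reaction, and exchange reactions for
glucose, lactate, O2, CO2, ammonium, HA and all 20 canonical amino acids.

Lumping conventions (documented, not atom-balanced): FADH2 is treated as NADH;
the serine->glycine one-carbon unit is routed to CO2; GTP is treated as ATP.
ATP/ADP and NAD+/NADH are conserved moiety pairs in every reaction, so energy
and redox bookkeeping is closed.

Sign convention for exchange fluxes: positive = secretion, negative = uptake.
"""
from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .exceptions import NetworkError

__all__ = [
    "Reaction",
    "MetabolicNetwork",
    "toy_core_network",
    "load_network",
    "save_network_json",
    "write_sbml",
    "read_sbml",
    "AMINO_ACIDS",
]

#: The 20 canonical (proteinogenic) amino acids, medium-side names.
AMINO_ACIDS: Tuple[str, ...] = (
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamine", "glutamate", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
)

REQUIRED_TAGS = ("HA_synthesis", "ATP_demand", "growth", "O2_exchange")

_BIG = 1000.0


@dataclass(frozen=True)
class Reaction:
    id: str
    stoich: Mapping[str, float]
    lb: float
    ub: float
    tags: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.lb > self.ub:
            raise NetworkError(f"reaction {self.id}: lb {self.lb} > ub {self.ub}")
        if not self.stoich:
            raise NetworkError(f"reaction {self.id}: empty stoichiometry")


@dataclass
class MetabolicNetwork:
    """Stoichiometric model with bounds, tags and an objective."""

    metabolites: List[str]
    reactions: List[Reaction]
    objective: Dict[str, float]

    def __post_init__(self):
        self._met_index = {m: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise NetworkError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise NetworkError("duplicate reaction ids")

    # -- indexing ---------------------------------------------------------
    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def stoichiometry_matrix(self) -> np.ndarray:
        """Dense metabolite x reaction matrix S."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoich.items():
                S[self._met_index[met], j] = coef
        return S

    def bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lb for r in self.reactions])
        ub = np.array([r.ub for r in self.reactions])
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        for rxn_id, coef in self.objective.items():
            c[self._rxn_index[rxn_id]] = coef
        return c

    # -- semantic lookups -------------------------------------------------
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if "exchange" in r.tags]

    @property
    def exchange_map(self) -> Dict[str, str]:
        """Medium metabolite name -> exchange reaction id."""
        out = {}
        for rxn in self.exchange_reactions():
            met = next(iter(rxn.stoich))
            out[met[:-2] if met.endswith("_c") else met] = rxn.id
        return out

    def tagged(self, tag: str) -> List[str]:
        return [r.id for r in self.reactions if tag in r.tags]

    # -- validation -------------------------------------------------------
    def validate(self) -> Dict[str, str]:
        """Structural invariants; returns the tag -> reaction report.

        Raises :class:`NetworkError` naming the first violated invariant.
        """
        report = {}
        for tag in REQUIRED_TAGS:
            hits = self.tagged(tag)
            if not hits:
                raise NetworkError(f"required tagged reaction missing: {tag}")
            report[tag] = ",".join(hits)
        for rxn in self.exchange_reactions():
            nonzero = [c for c in rxn.stoich.values() if c != 0]
            if len(nonzero) != 1:
                raise NetworkError(
                    f"exchange reaction {rxn.id} must have exactly one nonzero entry"
                )
        counts = {m: 0 for m in self.metabolites}
        for rxn in self.reactions:
            for met, coef in rxn.stoich.items():
                if met not in counts:
                    raise NetworkError(f"reaction {rxn.id} uses unknown metabolite {met}")
                if coef != 0:
                    counts[met] += 1
        unbalanced = [m for m, k in counts.items() if k < 2]
        if unbalanced:
            raise NetworkError(
                f"metabolites not balanced by >= 2 reactions: {unbalanced}"
            )
        missing_aa = [aa for aa in AMINO_ACIDS if aa not in self.exchange_map]
        if missing_aa:
            raise NetworkError(f"amino acids lacking exchange reactions: {missing_aa}")
        return report


# ---------------------------------------------------------------------------
# packaged reduced network
# ---------------------------------------------------------------------------

def _exchange(met: str, lb: float, ub: float, extra_tags: Sequence[str] = ()) -> Reaction:
    return Reaction(f"EX_{met}", {f"{met}_c": -1.0}, lb, ub,
                    tuple(["exchange", *extra_tags]))


def toy_core_network() -> MetabolicNetwork:
    """Build the packaged reduced tumor-core network.

    Flux units are nominal mmol/gDW/h; the growth reaction flux is in 1/h
    (biomass precursor coefficients are per unit growth rate).
    """
    rxns: List[Reaction] = []

    # exchanges -----------------------------------------------------------
    rxns.append(_exchange("glucose", -10.0, 0.0))
    rxns.append(_exchange("lactate", -10.0, 10.0))
    rxns.append(_exchange("o2", -10.0, 0.0, ["O2_exchange"]))
    rxns.append(_exchange("co2", 0.0, _BIG))
    rxns.append(_exchange("nh4", -10.0, _BIG))
    rxns.append(_exchange("ha", 0.0, _BIG))
    for aa in AMINO_ACIDS:
        rxns.append(_exchange(aa, -10.0, 10.0))

    # glycolysis ----------------------------------------------------------
    rxns.append(Reaction("HEX1", {"glucose_c": -1, "atp": -1, "g6p": 1, "adp": 1},
                         0, _BIG, ("upper_glycolysis",)))
    rxns.append(Reaction("PGI", {"g6p": -1, "f6p": 1}, -_BIG, _BIG))
    rxns.append(Reaction("PFK_ALD", {"f6p": -1, "atp": -1, "g3p": 2, "adp": 1},
                         0, _BIG, ("upper_glycolysis",)))
    rxns.append(Reaction(
        "GLYC_LOWER",
        {"g3p": -1, "adp": -2, "nad": -1, "pyr": 1, "atp": 2, "nadh": 1},
        0, _BIG, ("lower_glycolysis",)))
    rxns.append(Reaction("LDH", {"pyr": -1, "nadh": -1, "lactate_c": 1, "nad": 1},
                         -_BIG, _BIG, ("pyruvate_to_lactate",)))

    # TCA cycle and oxidative phosphorylation -----------------------------
    rxns.append(Reaction("PDH", {"pyr": -1, "nad": -1, "accoa": 1, "co2_c": 1, "nadh": 1},
                         0, _BIG))
    rxns.append(Reaction(
        "CS_IDH", {"accoa": -1, "oaa": -1, "nad": -1, "akg": 1, "co2_c": 1, "nadh": 1},
        0, _BIG))
    rxns.append(Reaction(
        "AKGDH", {"akg": -1, "nad": -1, "succoa": 1, "co2_c": 1, "nadh": 1},
        0, _BIG, ("akg_to_succinylcoa",)))
    rxns.append(Reaction(
        "SCS_MDH",
        {"succoa": -1, "adp": -1, "nad": -2, "oaa": 1, "atp": 1, "nadh": 2},
        0, _BIG))
    rxns.append(Reaction("PC", {"pyr": -1, "atp": -1, "co2_c": -1, "oaa": 1, "adp": 1},
                         0, _BIG))
    # lumped MDH-reverse + malic enzyme: cataplerotic exit for TCA carbon,
    # enables net glutaminolysis to lactate
    rxns.append(Reaction("ME_LUMP", {"oaa": -1, "pyr": 1, "co2_c": 1}, 0, _BIG))
    rxns.append(Reaction(
        "OXPHOS", {"nadh": -1, "o2_c": -0.5, "adp": -2.5, "nad": 1, "atp": 2.5},
        0, _BIG))
    rxns.append(Reaction("ATPM", {"atp": -1, "adp": 1}, 0, _BIG, ("ATP_demand",)))

    # nitrogen metabolism -------------------------------------------------
    rxns.append(Reaction(
        "GDH", {"glutamate_c": -1, "nad": -1, "akg": 1, "nh4_c": 1, "nadh": 1},
        -_BIG, _BIG, ("glutamate_to_akg",)))
    rxns.append(Reaction("GLS", {"glutamine_c": -1, "glutamate_c": 1, "nh4_c": 1},
                         0, _BIG))
    rxns.append(Reaction(
        "GS", {"glutamate_c": -1, "nh4_c": -1, "atp": -1, "glutamine_c": 1, "adp": 1},
        0, _BIG))
    rxns.append(Reaction(
        "ALT", {"pyr": -1, "glutamate_c": -1, "alanine_c": 1, "akg": 1},
        -_BIG, _BIG))
    rxns.append(Reaction(
        "AST", {"oaa": -1, "glutamate_c": -1, "aspartate_c": 1, "akg": 1},
        -_BIG, _BIG))
    rxns.append(Reaction(
        "ASNS",
        {"aspartate_c": -1, "glutamine_c": -1, "atp": -1,
         "asparagine_c": 1, "glutamate_c": 1, "adp": 1},
        0, _BIG))
    rxns.append(Reaction("ASNASE", {"asparagine_c": -1, "aspartate_c": 1, "nh4_c": 1},
                         0, _BIG))
    rxns.append(Reaction(
        "SERSYN",
        {"g3p": -1, "glutamate_c": -1, "nad": -1, "serine_c": 1, "akg": 1, "nadh": 1},
        0, _BIG))
    rxns.append(Reaction("SHMT", {"serine_c": -1, "glycine_c": 1, "co2_c": 1}, 0, _BIG))
    rxns.append(Reaction(
        "PROSYN",
        {"glutamate_c": -1, "atp": -1, "nadh": -2, "proline_c": 1, "adp": 1, "nad": 2},
        0, _BIG))
    # lumped catabolic sinks for essential amino acids whose exchange is
    # typically measurement-constrained; keeps forced uptake absorbable
    for aa in ("arginine", "cysteine", "histidine", "isoleucine", "methionine"):
        rxns.append(Reaction(
            f"DEG_{aa}",
            {f"{aa}_c": -1, "nad": -1, "nh4_c": 1, "co2_c": 1, "nadh": 1},
            0, _BIG))

    # hyaluronic acid synthesis ------------------------------------------
    rxns.append(Reaction(
        "UDPGA_SYN",
        {"g6p": -1, "atp": -1, "nad": -2, "udp_glcua": 1, "adp": 1, "nadh": 2},
        0, _BIG))
    rxns.append(Reaction(
        "UDPGNA_SYN",
        {"f6p": -1, "glutamine_c": -1, "accoa": -1, "atp": -1,
         "udp_glcnac": 1, "glutamate_c": 1, "adp": 1},
        0, _BIG))
    rxns.append(Reaction("HAS", {"udp_glcua": -1, "udp_glcnac": -1, "ha_c": 1},
                         0, _BIG, ("HA_synthesis",)))

    # growth --------------------------------------------------------------
    growth_stoich: Dict[str, float] = {"g6p": -0.3, "atp": -10.0, "adp": 10.0}
    for aa in AMINO_ACIDS:
        growth_stoich[f"{aa}_c"] = -0.05
    rxns.append(Reaction("GROWTH", growth_stoich, 0, _BIG, ("growth",)))

    mets: List[str] = sorted({m for r in rxns for m in r.stoich})
    net = MetabolicNetwork(metabolites=mets, reactions=rxns, objective={"HAS": 1.0})
    net.validate()
    return net


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "metabolites": list(net.metabolites),
        "reactions": [
            {"id": r.id, "stoich": dict(r.stoich), "lb": r.lb, "ub": r.ub,
             "tags": list(r.tags)}
            for r in net.reactions
        ],
        "objective": dict(net.objective),
    }


def network_from_dict(data: Mapping) -> MetabolicNetwork:
    try:
        reactions = [
            Reaction(r["id"], r["stoich"], float(r["lb"]), float(r["ub"]),
                     tuple(r.get("tags", ())))
            for r in data["reactions"]
        ]
        net = MetabolicNetwork(
            metabolites=list(data["metabolites"]),
            reactions=reactions,
            objective={k: float(v) for k, v in data.get("objective", {}).items()},
        )
    except (KeyError, TypeError) as exc:
        raise NetworkError(f"malformed network description: {exc}") from exc
    return net


def save_network_json(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_dict(net), fh, indent=1, sort_keys=True)


def load_network(path=None) -> MetabolicNetwork:
    """Load and validate a network from JSON (or the packaged asset).

    ``path=None`` loads the packaged reduced core network. Validation fails
    loudly, naming the violated invariant or missing tagged reaction.
    """
    if path is None:
        ref = importlib.resources.files("vesselflux").joinpath("data/core_network.json")
        data = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            data = json.load(fh)
    net = network_from_dict(data)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# SBML (via cobrapy, the field-standard SBML layer)
# ---------------------------------------------------------------------------

def _to_cobra(net: MetabolicNetwork):
    import cobra

    model = cobra.Model("vesselflux_core")
    mets = {m: cobra.Metabolite(m, compartment="c") for m in net.metabolites}
    for rxn in net.reactions:
        r = cobra.Reaction(rxn.id, lower_bound=rxn.lb, upper_bound=rxn.ub)
        model.add_reactions([r])
        r.add_metabolites({mets[m]: c for m, c in rxn.stoich.items()})
        if rxn.tags:
            r.notes["tags"] = list(rxn.tags)
    for rxn_id, coef in net.objective.items():
        model.reactions.get_by_id(rxn_id).objective_coefficient = coef
    return model


def write_sbml(net: MetabolicNetwork, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(_to_cobra(net), str(path))


def read_sbml(path) -> MetabolicNetwork:
    import cobra.io
    import cobra.util.solver as solver_util

    model = cobra.io.read_sbml_model(str(path))
    reactions = []
    objective = {}
    coeffs = solver_util.linear_reaction_coefficients(model)
    for r in model.reactions:
        tags = tuple(r.notes.get("tags", ()))
        reactions.append(Reaction(
            r.id, {m.id: c for m, c in r.metabolites.items()},
            float(r.lower_bound), float(r.upper_bound), tags))
        if r in coeffs and coeffs[r] != 0:
            objective[r.id] = float(coeffs[r])
    net = MetabolicNetwork(
        metabolites=[m.id for m in model.metabolites],
        reactions=reactions,
        objective=objective,
    )
    return net
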