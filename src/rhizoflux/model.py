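"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a stoichiometric network: metabolites in
compartments, reactions with flux bounds (mmol/gDW/h) and GPR rules, and
one objective (a biomass or symbiotic pseudo-reaction). The sign
convention is the COBRA standard: negative stoichiometric coefficients
consume, exchange flux < 0 is uptake and > 0 is secretion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .gpr import GPRExpression, parse_gpr

__all__ = [
    "DEFAULT_BOUND",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MediaCondition",
    "apply_media",
    "REACTION_CLASSES",
]

#: Default magnitude for an unbounded flux (mmol/gDW/h).
DEFAULT_BOUND = 1000.0

REACTION_CLASSES = frozenset(
    {"enzymatic", "transport", "exchange", "demand", "sink", "biomass", "spontaneous"}
)

#: Boundary classes: reactions that create/destroy mass at the system edge.
BOUNDARY_CLASSES = frozenset({"exchange", "demand", "sink"})


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int | None = None
    compartment: str = "c"
    annotation: dict = field(default_factory=dict)


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression = field(default_factory=lambda: GPRExpression(None))
    subsystem: str = ""
    reaction_class: str = "enzymatic"
    annotation: dict = field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.reaction_class not in REACTION_CLASSES:
            raise ValueError(f"reaction {self.id}: unknown class {self.reaction_class!r}")

    @property
    def is_boundary(self) -> bool:
        return self.reaction_class in BOUNDARY_CLASSES

    def genes(self) -> frozenset[str]:
        return self.gpr.genes()


def infer_reaction_class(
    reaction_id: str,
    stoichiometry: Mapping[str, float],
    explicit: str | None = None,
    objective: bool = False,
) -> str:
    """Classify a reaction.

    Precedence: explicit annotation > id prefix (``EX_``/``DM_``/``SK_``)
    > boundary structure (single-metabolite reactions are exchanges) >
    objective flag (biomass) > enzymatic. Deposited models vary in how
    completely they annotate boundary reactions, hence the cascade.
    """
    if explicit in REACTION_CLASSES:
        return explicit
    rid = reaction_id.upper()
    if rid.startswith("EX_"):
        return "exchange"
    if rid.startswith("DM_"):
        return "demand"
    if rid.startswith("SK_") or rid.startswith("SINK_"):
        return "sink"
    if len(stoichiometry) == 1:
        return "exchange"
    if objective or "BIOMASS" in rid:
        return "biomass"
    return "enzymatic"


class MetabolicModel:
    """A stoichiometric network with gene associations and one objective."""

    def __init__(
        self,
        name: str = "",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        genes: Iterable[str] = (),
        objective_id: str | None = None,
    ):
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.genes: set[str] = set(genes)
        for met in metabolites:
            self.add_metabolite(met)
        for rxn in reactions:
            self.add_reaction(rxn)
        self.objective_id = objective_id

    # -- construction ------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        if not rxn.stoichiometry:
            raise ValueError(f"reaction {rxn.id}: empty stoichiometry")
        missing = set(rxn.stoichiometry) - set(self.metabolites)
        if missing:
            raise KeyError(f"reaction {rxn.id}: unknown metabolites {sorted(missing)}")
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.genes()

    # -- views -------------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.metabolites)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.reaction_class == "exchange"]

    def boundary(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_boundary]

    @property
    def objective(self) -> Reaction:
        if self.objective_id is None:
            raise ValueError(f"model {self.name!r} has no objective reaction")
        return self.reactions[self.objective_id]

    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """S (metabolites x reactions), with its row and column id orders."""
        met_ids = self.metabolite_ids
        rxn_ids = self.reaction_ids
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met, coef in self.reactions[rid].stoichiometry.items():
                rows.append(met_index[met])
                cols.append(j)
                data.append(float(coef))
        S = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()])
        ub = np.array([r.upper_bound for r in self.reactions.values()])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check referential integrity (stoichiometry keys, GPR leaves, objective)."""
        for rxn in self.reactions.values():
            missing = set(rxn.stoichiometry) - set(self.metabolites)
            if missing:
                raise ValueError(f"reaction {rxn.id}: unresolved metabolites {sorted(missing)}")
            orphans = rxn.genes() - self.genes
            if orphans:
                raise ValueError(f"reaction {rxn.id}: unregistered genes {sorted(orphans)}")
        if self.objective_id is not None and self.objective_id not in self.reactions:
            raise ValueError(f"objective {self.objective_id!r} is not a reaction")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicModel {self.name!r}: {len(self.genes)} genes, "
            f"{len(self.reactions)} reactions, {len(self.metabolites)} metabolites>"
        )


@dataclass
class MediaCondition:
    """Nutrient availability: exchange reaction id -> maximum uptake rate.

    Rates are stated as positive magnitudes (mmol/gDW/h) and applied as
    negative lower bounds on the exchange, following the convention that
    uptake flux is negative.
    """

    uptakes: dict[str, float] = field(default_factory=dict)
    label: str = "custom"

    def __post_init__(self):
        bad = {k: v for k, v in self.uptakes.items() if v < 0}
        if bad:
            raise ValueError(f"negative uptake rates not allowed: {bad}")


def apply_media(
    model: MetabolicModel, media: MediaCondition, close_others: bool = True
) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set from the media.

    Each listed exchange gets ``lower_bound = -rate``. With
    ``close_others`` every unlisted exchange has its lower bound raised to
    0 (uptake closed; secretion stays open). Stoichiometry is never
    touched.
    """
    exchange_ids = {r.id for r in model.exchanges()}
    unknown = set(media.uptakes) - exchange_ids
    if unknown:
        raise KeyError(
            f"media {media.label!r} references non-exchange reactions: {sorted(unknown)}"
        )
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.reaction_class != "exchange":
            continue
        if rxn.id in media.uptakes:
            rxn.lower_bound = -float(media.uptakes[rxn.id])
        elif close_others:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out
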