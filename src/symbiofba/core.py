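"""Core data model for compartmentalized stoichiometric metabolic networks.

A metabolic network is a set of metabolites partitioned into compartments and
a set of reactions, each a sparse signed stoichiometry over those metabolites
with flux bounds in mmol·gDW⁻¹·h⁻¹.  Sign conventions used throughout the
package:

* negative stoichiometric coefficient = consumed, positive = produced;
* for exchange reactions, positive flux = export to the environment,
  negative flux = uptake.

``OrganismModel`` is the unit of file I/O (one organism per file); community
models built from several organisms reuse the same container with
compartment-tagged identifiers (see :mod:`symbiofba.community`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError

#: Default flux bound (mmol·gDW⁻¹·h⁻¹) when a file does not state one.
DEFAULT_BOUND = 1000.0

#: Separator between a bare id and its organism tag in community models.
ORG_SEP = "__"


class ReactionKind(str, Enum):
    INTERNAL = "internal"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    DEMAND = "demand"
    BIOMASS = "biomass"


@dataclass(frozen=True)
class Metabolite:
    """One chemical species in one compartment.

    ``transportable`` flags species that may be linked to a shared community
    pool at assembly time; it is the default source of the linked-metabolite
    set when a community spec gives no explicit allow-list.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    transportable: bool = False


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoich`` maps metabolite id → signed coefficient (negative = consumed).
    A demand reaction with ``lb == ub > 0`` is a *fixed demand*: the organism
    is obliged to drain that flux regardless of any optimization objective.
    """

    id: str
    stoich: Mapping[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    kind: ReactionKind = ReactionKind.INTERNAL
    gene_rule: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoich", dict(self.stoich))


@dataclass
class OrganismModel:
    """A validated single-organism (or merged community) metabolic model."""

    id: str
    compartments: set[str] = field(default_factory=set)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    biomass_id: str | None = None
    objective: dict[str, float] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_parts(
        cls,
        id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        biomass_id: str | None = None,
        objective: Mapping[str, float] | None = None,
        compartments: Iterable[str] | None = None,
    ) -> "OrganismModel":
        mets = {m.id: m for m in metabolites}
        rxns = {r.id: r for r in reactions}
        comps = set(compartments) if compartments is not None else {
            m.compartment for m in mets.values()
        }
        model = cls(
            id=id,
            compartments=comps,
            metabolites=mets,
            reactions=rxns,
            biomass_id=biomass_id,
            objective=dict(objective or {}),
        )
        model.validate()
        return model

    def copy(self) -> "OrganismModel":
        return OrganismModel(
            id=self.id,
            compartments=set(self.compartments),
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            biomass_id=self.biomass_id,
            objective=dict(self.objective),
        )

    def with_reaction_bounds(self, rxn_id: str, lb: float, ub: float) -> "OrganismModel":
        """Return a copy with one reaction's bounds replaced."""
        out = self.copy()
        out.reactions[rxn_id] = replace(out.reactions[rxn_id], lb=lb, ub=ub)
        return out

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first structural defect."""
        if not self.id:
            raise ValidationError("model id must be nonempty")
        if not self.reactions:
            raise ValidationError(f"model {self.id!r} has no reactions")
        for m in self.metabolites.values():
            if not m.id:
                raise ValidationError("metabolite with empty id")
            if m.compartment not in self.compartments:
                raise ValidationError(
                    f"metabolite {m.id!r} references undeclared compartment "
                    f"{m.compartment!r}"
                )
        for r in self.reactions.values():
            if not r.stoich:
                raise ValidationError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lb > r.ub:
                raise ValidationError(
                    f"reaction {r.id!r} has lb={r.lb} > ub={r.ub}"
                )
            for met_id in r.stoich:
                if met_id not in self.metabolites:
                    raise ValidationError(
                        f"reaction {r.id!r} references undeclared metabolite "
                        f"{met_id!r}"
                    )
            if r.kind is ReactionKind.EXCHANGE and len(r.stoich) != 1:
                raise ValidationError(
                    f"exchange reaction {r.id!r} must touch exactly one "
                    f"metabolite, touches {len(r.stoich)}"
                )
        if self.biomass_id is not None and self.biomass_id not in self.reactions:
            raise ValidationError(
                f"biomass_id {self.biomass_id!r} is not a reaction of {self.id!r}"
            )
        for rid in self.objective:
            if rid not in self.reactions:
                raise ValidationError(
                    f"objective references unknown reaction {rid!r}"
                )

    # -- convenience ----------------------------------------------------------

    @property
    def transportable_metabolites(self) -> set[str]:
        return {m.id for m in self.metabolites.values() if m.transportable}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrganismModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.compartments == other.compartments
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and self.biomass_id == other.biomass_id
            and self.objective == other.objective
        )


@dataclass(frozen=True)
class Medium:
    """Growth medium: metabolite id → maximum uptake rate (≥ 0).

    A rate of 0 blocks uptake but still permits secretion through the
    corresponding exchange reaction.
    """

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for met, rate in self.entries.items():
            if rate < 0:
                raise ValidationError(
                    f"medium uptake rate for {met!r} must be >= 0, got {rate}"
                )


@dataclass(frozen=True)
class StoichiometricMatrix:
    """Sparse S matrix with its deterministic (sorted-id) index maps."""

    matrix: sp.csr_matrix
    met_ids: tuple[str, ...]
    rxn_ids: tuple[str, ...]

    @property
    def met_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.met_ids)}

    @property
    def rxn_index(self) -> dict[str, int]:
        return {r: j for j, r in enumerate(self.rxn_ids)}


def stoichiometric_matrix(model: OrganismModel) -> StoichiometricMatrix:
    """Build the metabolite × reaction stoichiometric matrix S.

    Rows/columns are ordered by sorted metabolite/reaction id so that the
    representation is deterministic across runs and platforms.
    """
    model.validate()
    met_ids = tuple(sorted(model.metabolites))
    rxn_ids = tuple(sorted(model.reactions))
    mi = {m: i for i, m in enumerate(met_ids)}
    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for met, coef in model.reactions[rid].stoich.items():
            rows.append(mi[met])
            cols.append(j)
            vals.append(float(coef))
    S = sp.coo_matrix(
        (np.asarray(vals), (np.asarray(rows, dtype=int), np.asarray(cols, dtype=int))),
        shape=(len(met_ids), len(rxn_ids)),
    ).tocsr()
    return StoichiometricMatrix(matrix=S, met_ids=met_ids, rxn_ids=rxn_ids)
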