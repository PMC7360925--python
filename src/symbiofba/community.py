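"""Assemble host + symbiont models into one biomass-ratio-coupled community.

The community model couples organisms through a shared extracellular pool
(the insect hemolymph, in the aphid–Buchnera–Hamiltonella symbiosis this
package was built around).  Coupling convention:

* Every community flux is expressed per gram dry weight of a designated
  *reference* organism (the obligate symbiont, by default).
* An organism present at biomass ``r`` grams per gram of reference
  contributes ``r ×`` (its per-gram flux) to the community.  This is
  implemented by multiplying all of that organism's flux bounds — and in
  particular its fixed demand pins — by ``r``, so the whole community stays
  a single LP and a biomass-ratio sweep is a pure rescaling.
* The host is represented by fixed nutrient demands on the pool (e.g. a
  histidine drain) rather than a growth objective; a biomass objective can
  still be supplied through the merged model's ``objective`` if wanted.

Identifiers are tagged ``<id>__<organism>`` on merge; pool species are
tagged ``__pool``.  Tag collisions are errors, never silently renamed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .core import (
    DEFAULT_BOUND,
    ORG_SEP,
    Medium,
    Metabolite,
    OrganismModel,
    Reaction,
    ReactionKind,
)
from .errors import AssemblyError, ConfigurationError, ValidationError

POOL = "pool"


@dataclass(frozen=True)
class CommunitySpec:
    """Recipe for a community: host, symbionts with biomass ratios, medium.

    ``symbionts`` is an ordered list of ``(model, r)`` where ``r`` is grams
    of that organism per gram of the reference organism.  ``linked_mets``
    defaults to the union of metabolites flagged ``transportable`` across
    all member models.
    """

    host: OrganismModel
    symbionts: Sequence[tuple[OrganismModel, float]]
    medium: Medium
    reference: str | None = None
    shared_pool: str = POOL
    linked_mets: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbionts", tuple(self.symbionts))
        if self.linked_mets is not None:
            object.__setattr__(self, "linked_mets", frozenset(self.linked_mets))

    @property
    def reference_id(self) -> str:
        if self.reference is not None:
            return self.reference
        if not self.symbionts:
            return self.host.id
        return self.symbionts[0][0].id

    def organisms(self) -> list[tuple[OrganismModel, float]]:
        """All members with their biomass scalings (host scales at 1)."""
        return [(self.host, 1.0)] + list(self.symbionts)

    def validate(self) -> None:
        ids = [self.host.id] + [m.id for m, _ in self.symbionts]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate organism ids in community spec: {ids}")
        for model, r in self.symbionts:
            if not r > 0:
                raise ValidationError(
                    f"biomass ratio for {model.id!r} must be > 0, got {r} "
                    "(omit the organism instead of setting r = 0)"
                )
        if self.reference_id not in ids:
            raise ValidationError(f"reference organism {self.reference_id!r} not in community")
        linked = self.resolved_linked_mets()
        if not linked:
            raise ValidationError("no linked metabolites: nothing couples the community")
        for met in linked:
            if not any(met in m.metabolites for m, _ in self.organisms()):
                raise ValidationError(f"linked metabolite {met!r} absent from every organism")

    def resolved_linked_mets(self) -> frozenset[str]:
        if self.linked_mets is not None:
            return self.linked_mets
        out: set[str] = set()
        for model, _ in self.organisms():
            out |= model.transportable_metabolites
        return frozenset(out)

    def without(self, organism_id: str) -> "CommunitySpec":
        """The same spec with one symbiont removed (e.g. the symbiont-free baseline)."""
        kept = tuple((m, r) for m, r in self.symbionts if m.id != organism_id)
        if len(kept) == len(self.symbionts):
            raise ConfigurationError(f"no symbiont {organism_id!r} to remove")
        ref = self.reference
        if ref == organism_id:
            ref = None
        return replace(self, symbionts=kept, reference=ref)

    def with_ratio(self, organism_id: str, r: float) -> "CommunitySpec":
        if not r > 0:
            raise ValidationError(f"biomass ratio must be > 0, got {r}")
        found = False
        updated = []
        for m, old in self.symbionts:
            if m.id == organism_id:
                updated.append((m, r))
                found = True
            else:
                updated.append((m, old))
        if not found:
            raise ConfigurationError(f"unknown organism {organism_id!r}")
        return replace(self, symbionts=tuple(updated))


@dataclass
class CommunityModel:
    """A merged, ratio-scaled, medium-constrained community LP description."""

    model: OrganismModel
    organism_of: dict[str, str]
    scaling: dict[str, float]
    reference: str
    pool_transports: dict[tuple[str, str], str]  # (organism, bare met) -> rxn id
    pool_exchanges: dict[str, str]  # bare met -> exchange rxn id
    fixed_demands: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            model=self.model.copy(),
            organism_of=dict(self.organism_of),
            scaling=dict(self.scaling),
            reference=self.reference,
            pool_transports=dict(self.pool_transports),
            pool_exchanges=dict(self.pool_exchanges),
            fixed_demands=dict(self.fixed_demands),
        )

    def organisms(self) -> list[str]:
        return sorted(self.scaling)

    def tagged(self, bare_id: str, organism: str) -> str:
        return f"{bare_id}{ORG_SEP}{organism}"

    def reaction_of(self, bare_id: str, organism: str) -> str:
        """Resolve a bare reaction id within an organism, or raise."""
        rid = self.tagged(bare_id, organism)
        if rid not in self.model.reactions:
            candidates = [
                r for r in self.model.reactions
                if bare_id.lower() in r.lower()
            ]
            raise ConfigurationError(
                f"reaction {bare_id!r} not found in organism {organism!r} "
                f"(expected id {rid!r}; near matches: {sorted(candidates)[:5]})"
            )
        return rid

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityModel):
            return NotImplemented
        return (
            self.model == other.model
            and self.organism_of == other.organism_of
            and self.scaling == other.scaling
            and self.reference == other.reference
            and self.pool_transports == other.pool_transports
            and self.pool_exchanges == other.pool_exchanges
            and self.fixed_demands == other.fixed_demands
        )


def _check_member_feasibility(spec: CommunitySpec) -> None:
    """Each member must be able to meet its own fixed demands given free
    exchange of its transportable metabolites (auxotrophs are only feasible
    with pool supply, so exchanges are opened wide rather than medium-capped)."""
    from .fba import solve_fba  # local import: fba depends on this module

    linked = spec.resolved_linked_mets()
    for model, _ in spec.organisms():
        probe = model.copy()
        probe.id = model.id
        for met in sorted(linked & set(model.metabolites)):
            rid = f"_PROBE_EX_{met}"
            if rid in probe.reactions:
                raise AssemblyError(f"id collision with probe exchange {rid!r}")
            probe.reactions[rid] = Reaction(
                id=rid, stoich={met: -1.0}, lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND,
                kind=ReactionKind.EXCHANGE,
            )
        sol = solve_fba(probe, objective={}, sense="min")
        if sol.status != "optimal":
            raise AssemblyError(
                f"organism {model.id!r} is infeasible even with free pool "
                f"exchange (status {sol.status}); fix its model before assembly"
            )


def assemble_community(spec: CommunitySpec, check_feasibility: bool = True) -> CommunityModel:
    """Merge the spec's organisms into one pool-coupled community model.

    Raises :class:`AssemblyError` on id collisions or a linked metabolite
    missing everywhere, and (when ``check_feasibility``) on any member that
    cannot satisfy its own fixed demands given free pool exchange.
    """
    spec.validate()
    if check_feasibility:
        _check_member_feasibility(spec)

    linked = spec.resolved_linked_mets()
    merged_mets: dict[str, Metabolite] = {}
    merged_rxns: dict[str, Reaction] = {}
    compartments: set[str] = {spec.shared_pool}
    organism_of: dict[str, str] = {}
    scaling: dict[str, float] = {}
    pool_transports: dict[tuple[str, str], str] = {}
    pool_exchanges: dict[str, str] = {}
    fixed_demands: dict[str, float] = {}
    objective: dict[str, float] = {}

    def add_rxn(rxn: Reaction, organism: str | None) -> None:
        if rxn.id in merged_rxns:
            raise AssemblyError(f"reaction id collision after tagging: {rxn.id!r}")
        merged_rxns[rxn.id] = rxn
        if organism is not None:
            organism_of[rxn.id] = organism

    # pool species for every linked metabolite (compartment = shared pool)
    for met in sorted(linked):
        pool_id = f"{met}{ORG_SEP}{spec.shared_pool}"
        merged_mets[pool_id] = Metabolite(id=pool_id, name=met, compartment=spec.shared_pool)

    for model, r in spec.organisms():
        org = model.id
        scaling[org] = r
        for met in sorted(model.metabolites):
            m = model.metabolites[met]
            tagged = f"{met}{ORG_SEP}{org}"
            if tagged in merged_mets:
                raise AssemblyError(f"metabolite id collision after tagging: {tagged!r}")
            comp = f"{m.compartment}{ORG_SEP}{org}"
            compartments.add(comp)
            merged_mets[tagged] = replace(m, id=tagged, compartment=comp)
        for rid in sorted(model.reactions):
            rx = model.reactions[rid]
            tagged_id = f"{rid}{ORG_SEP}{org}"
            stoich = {f"{met}{ORG_SEP}{org}": c for met, c in rx.stoich.items()}
            scaled = replace(rx, id=tagged_id, stoich=stoich, lb=rx.lb * r, ub=rx.ub * r)
            add_rxn(scaled, org)
            if rx.kind is ReactionKind.DEMAND and rx.lb == rx.ub and rx.lb != 0.0:
                fixed_demands[tagged_id] = rx.lb * r
            if rid in model.objective:
                objective[tagged_id] = model.objective[rid]
        # reversible pool transports for linked metabolites this organism holds
        for met in sorted(linked & set(model.metabolites)):
            tid = f"TP_{met}{ORG_SEP}{org}"
            pool_id = f"{met}{ORG_SEP}{spec.shared_pool}"
            add_rxn(
                Reaction(
                    id=tid,
                    stoich={f"{met}{ORG_SEP}{org}": -1.0, pool_id: +1.0},
                    lb=-DEFAULT_BOUND * r,
                    ub=DEFAULT_BOUND * r,
                    kind=ReactionKind.TRANSPORT,
                ),
                org,
            )
            pool_transports[(org, met)] = tid

    # environment exchanges on the pool; uptake closed until a medium is applied
    for met in sorted(linked):
        eid = f"EX_{met}{ORG_SEP}{spec.shared_pool}"
        pool_id = f"{met}{ORG_SEP}{spec.shared_pool}"
        add_rxn(
            Reaction(
                id=eid,
                stoich={pool_id: -1.0},
                lb=0.0,
                ub=DEFAULT_BOUND,
                kind=ReactionKind.EXCHANGE,
            ),
            None,
        )
        pool_exchanges[met] = eid

    merged = OrganismModel(
        id=ORG_SEP.join(sorted(scaling)),
        compartments=compartments,
        metabolites=merged_mets,
        reactions=merged_rxns,
        biomass_id=None,
        objective=objective,
    )
    merged.validate()
    community = CommunityModel(
        model=merged,
        organism_of=organism_of,
        scaling=scaling,
        reference=spec.reference_id,
        pool_transports=pool_transports,
        pool_exchanges=pool_exchanges,
        fixed_demands=fixed_demands,
    )
    return apply_medium(community, spec.medium)


def set_biomass_ratio(community: CommunityModel, organism: str, r: float) -> CommunityModel:
    """Re-scale one organism's biomass ratio; returns a new community.

    Rescales that organism's bounds and fixed demand pins by ``new r / old
    r``; setting the current value is the identity.
    """
    if organism not in community.scaling:
        raise ConfigurationError(
            f"unknown organism {organism!r}; community members: {community.organisms()}"
        )
    if not r > 0:
        raise ValidationError(f"biomass ratio must be > 0, got {r}")
    if organism == community.reference and r != 1.0:
        raise ConfigurationError("the reference organism is pinned at r = 1")
    old = community.scaling[organism]
    factor = r / old
    out = community.copy()
    out.scaling[organism] = r
    if factor == 1.0:
        return out
    for rid, org in community.organism_of.items():
        if org != organism:
            continue
        rx = out.model.reactions[rid]
        out.model.reactions[rid] = replace(rx, lb=rx.lb * factor, ub=rx.ub * factor)
        if rid in out.fixed_demands:
            out.fixed_demands[rid] *= factor
    return out


def apply_medium(community: CommunityModel, medium: Medium) -> CommunityModel:
    """Constrain pool exchanges to the medium's maximum uptake rates.

    Listed metabolites get ``lb = -rate``; everything else has uptake blocked
    (``lb = 0``).  Upper bounds (secretion) are untouched.
    """
    for met in medium.entries:
        if met not in community.pool_exchanges:
            raise ConfigurationError(
                f"medium metabolite {met!r} has no pool exchange reaction; "
                f"pool species: {sorted(community.pool_exchanges)}"
            )
    out = community.copy()
    for met, eid in out.pool_exchanges.items():
        rx = out.model.reactions[eid]
        rate = medium.entries.get(met, 0.0)
        out.model.reactions[eid] = replace(rx, lb=-rate)
    return out
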