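"""Model and medium file I/O.

Three input dialects are supported:

``native-json``
    The package's own schema: one JSON object with ``id``, ``compartments``,
    ``metabolites``, ``reactions``, ``biomass_id`` and ``objective`` keys.
    Lossless round-trip.

``tsv-pair``
    A directory holding ``metabolites.tsv`` (columns
    ``id, name, compartment, formula, charge, transportable``) and
    ``reactions.tsv`` (columns ``id, stoich, lb, ub, kind, gene_rule,
    objective_weight, is_biomass``), where ``stoich`` encodes the sparse
    row as ``met:coef;met:coef``.  Model-level metadata (model id,
    compartment list) rides in ``#key=json`` comment lines at the top of
    ``reactions.tsv`` so the pair stays lossless.

``sbml``
    Read-only SBML Level 3 import through libsbml.  Flux bounds are taken
    from the fbc package when present, from kinetic-law ``LOWER_BOUND`` /
    ``UPPER_BOUND`` parameters as a fallback, and otherwise default to
    ±1000 (0..1000 for reactions flagged irreversible).  Identifiers are
    preserved verbatim; annotations and groups are ignored.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal

from .core import (
    DEFAULT_BOUND,
    Medium,
    Metabolite,
    OrganismModel,
    Reaction,
    ReactionKind,
)
from .errors import FormatError, ValidationError

ModelFormat = Literal["native-json", "tsv-pair", "sbml"]

_MET_COLS = ["id", "name", "compartment", "formula", "charge", "transportable"]
_RXN_COLS = ["id", "stoich", "lb", "ub", "kind", "gene_rule", "objective_weight", "is_biomass"]


# ---------------------------------------------------------------------------
# native JSON


def _model_to_dict(model: OrganismModel) -> dict:
    return {
        "id": model.id,
        "compartments": sorted(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
                "transportable": m.transportable,
            }
            for m in (model.metabolites[k] for k in sorted(model.metabolites))
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: r.stoich[k] for k in sorted(r.stoich)},
                "lb": r.lb,
                "ub": r.ub,
                "kind": r.kind.value,
                "gene_rule": r.gene_rule,
            }
            for r in (model.reactions[k] for k in sorted(model.reactions))
        ],
        "biomass_id": model.biomass_id,
        "objective": {k: model.objective[k] for k in sorted(model.objective)},
    }


def _model_from_dict(data: dict, source: str) -> OrganismModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
                charge=m.get("charge"),
                transportable=bool(m.get("transportable", False)),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoich={k: float(v) for k, v in r["stoich"].items()},
                lb=float(r.get("lb", -DEFAULT_BOUND)),
                ub=float(r.get("ub", DEFAULT_BOUND)),
                kind=ReactionKind(r.get("kind", "internal")),
                gene_rule=r.get("gene_rule"),
            )
            for r in data["reactions"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{source}: malformed model record ({exc})") from exc
    return OrganismModel.from_parts(
        id=data.get("id", Path(source).stem),
        metabolites=mets,
        reactions=rxns,
        biomass_id=data.get("biomass_id"),
        objective=data.get("objective") or {},
        compartments=data.get("compartments"),
    )


# ---------------------------------------------------------------------------
# TSV pair


def _stoich_to_text(stoich: dict[str, float]) -> str:
    return ";".join(f"{k}:{stoich[k]!r}" for k in sorted(stoich))


def _stoich_from_text(text: str, source: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in text.split(";"):
        if not part:
            continue
        try:
            met, coef = part.rsplit(":", 1)
            out[met] = float(coef)
        except ValueError as exc:
            raise FormatError(f"{source}: bad stoichiometry entry {part!r}") from exc
    return out


def _write_tsv_pair(model: OrganismModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "metabolites.tsv", "w") as fh:
        fh.write("\t".join(_MET_COLS) + "\n")
        for mid in sorted(model.metabolites):
            m = model.metabolites[mid]
            fh.write(
                "\t".join(
                    [
                        m.id,
                        m.name,
                        m.compartment,
                        "" if m.formula is None else m.formula,
                        "" if m.charge is None else str(m.charge),
                        "1" if m.transportable else "0",
                    ]
                )
                + "\n"
            )
    with open(path / "reactions.tsv", "w") as fh:
        fh.write(f"#model_id={json.dumps(model.id)}\n")
        fh.write(f"#compartments={json.dumps(sorted(model.compartments))}\n")
        fh.write("\t".join(_RXN_COLS) + "\n")
        for rid in sorted(model.reactions):
            r = model.reactions[rid]
            fh.write(
                "\t".join(
                    [
                        r.id,
                        _stoich_to_text(dict(r.stoich)),
                        repr(r.lb),
                        repr(r.ub),
                        r.kind.value,
                        "" if r.gene_rule is None else r.gene_rule,
                        repr(model.objective.get(r.id, 0.0)),
                        "1" if model.biomass_id == r.id else "0",
                    ]
                )
                + "\n"
            )


def _read_tsv_pair(path: Path) -> OrganismModel:
    met_file = path / "metabolites.tsv"
    rxn_file = path / "reactions.tsv"
    for f in (met_file, rxn_file):
        if not f.exists():
            raise FormatError(f"tsv-pair directory {path} is missing {f.name}")

    mets = []
    with open(met_file) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != _MET_COLS[:5]:
            raise FormatError(f"{met_file}: unexpected header {header!r}")
        for line in fh:
            row = line.rstrip("\n").split("\t")
            rec = dict(zip(header, row))
            mets.append(
                Metabolite(
                    id=rec["id"],
                    name=rec.get("name", ""),
                    compartment=rec["compartment"],
                    formula=rec.get("formula") or None,
                    charge=int(rec["charge"]) if rec.get("charge") else None,
                    transportable=rec.get("transportable", "0") == "1",
                )
            )

    meta: dict[str, object] = {}
    rxns, objective = [], {}
    biomass_id = None
    with open(rxn_file) as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = json.loads(value)
            line = fh.readline()
        header = line.rstrip("\n").split("\t")
        if header[:5] != _RXN_COLS[:5]:
            raise FormatError(f"{rxn_file}: unexpected header {header!r}")
        for line in fh:
            row = line.rstrip("\n").split("\t")
            rec = dict(zip(header, row))
            rid = rec["id"]
            rxns.append(
                Reaction(
                    id=rid,
                    stoich=_stoich_from_text(rec["stoich"], str(rxn_file)),
                    lb=float(rec["lb"]),
                    ub=float(rec["ub"]),
                    kind=ReactionKind(rec["kind"]),
                    gene_rule=rec.get("gene_rule") or None,
                )
            )
            w = float(rec.get("objective_weight") or 0.0)
            if w != 0.0:
                objective[rid] = w
            if rec.get("is_biomass") == "1":
                biomass_id = rid

    return OrganismModel.from_parts(
        id=str(meta.get("model_id", path.name)),
        metabolites=mets,
        reactions=rxns,
        biomass_id=biomass_id,
        objective=objective,
        compartments=meta.get("compartments"),
    )


# ---------------------------------------------------------------------------
# SBML (read-only)


def _sbml_bounds(reaction, sbml_model) -> tuple[float, float]:
    """Resolve flux bounds: fbc attributes, kinetic-law parameters, defaults."""
    fbc = reaction.getPlugin("fbc")
    if fbc is not None:
        lb_id, ub_id = fbc.getLowerFluxBound(), fbc.getUpperFluxBound()
        if lb_id and ub_id:
            lo = sbml_model.getParameter(lb_id)
            hi = sbml_model.getParameter(ub_id)
            if lo is not None and hi is not None:
                return lo.getValue(), hi.getValue()
    kl = reaction.getKineticLaw()
    if kl is not None:
        lo = kl.getParameter("LOWER_BOUND")
        hi = kl.getParameter("UPPER_BOUND")
        if lo is not None and hi is not None:
            return lo.getValue(), hi.getValue()
    if reaction.isSetReversible() and not reaction.getReversible():
        return 0.0, DEFAULT_BOUND
    return -DEFAULT_BOUND, DEFAULT_BOUND


def _classify_sbml_reaction(rid: str, stoich: dict[str, float]) -> ReactionKind:
    low = rid.lower()
    if len(stoich) == 1:
        if low.startswith(("dm_", "sink_", "sk_")):
            return ReactionKind.DEMAND
        return ReactionKind.EXCHANGE
    if "biomass" in low:
        return ReactionKind.BIOMASS
    return ReactionKind.INTERNAL


def _read_sbml(path: Path) -> OrganismModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: SBML document contains no model element")

    clamp = lambda b: math.copysign(min(abs(b), DEFAULT_BOUND), b) if math.isfinite(b) else math.copysign(DEFAULT_BOUND, b)

    mets = []
    for i in range(sbml_model.getNumSpecies()):
        sp_ = sbml_model.getSpecies(i)
        if sp_.getBoundaryCondition():
            continue  # boundary species are the implicit environment
        fbc_sp = sp_.getPlugin("fbc")
        formula = fbc_sp.getChemicalFormula() if fbc_sp is not None and fbc_sp.isSetChemicalFormula() else None
        charge = int(fbc_sp.getCharge()) if fbc_sp is not None and fbc_sp.isSetCharge() else None
        mets.append(
            Metabolite(
                id=sp_.getId(),
                name=sp_.getName() or "",
                compartment=sp_.getCompartment() or "c",
                formula=formula,
                charge=charge,
            )
        )
    met_ids = {m.id for m in mets}

    rxns = []
    objective: dict[str, float] = {}
    biomass_id = None
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        if not stoich:
            raise FormatError(
                f"{path}: reaction {rx.getId()!r} references only boundary/unknown species"
            )
        lb, ub = _sbml_bounds(rx, sbml_model)
        kind = _classify_sbml_reaction(rx.getId(), stoich)
        if kind is ReactionKind.BIOMASS and biomass_id is None:
            biomass_id = rx.getId()
        rxns.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoich=stoich,
                lb=clamp(lb),
                ub=clamp(ub),
                kind=kind,
            )
        )

    fbc_model = sbml_model.getPlugin("fbc")
    if fbc_model is not None:
        obj = fbc_model.getActiveObjective()
        if obj is not None:
            for i in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(i)
                objective[fo.getReaction()] = fo.getCoefficient()

    return OrganismModel.from_parts(
        id=sbml_model.getId() or path.stem,
        metabolites=mets,
        reactions=rxns,
        biomass_id=biomass_id,
        objective=objective,
    )


# ---------------------------------------------------------------------------
# public API


def load_model(path: str | Path, format: ModelFormat = "native-json") -> OrganismModel:
    """Load and validate an :class:`OrganismModel` from ``path``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native-json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
        return _model_from_dict(data, str(path))
    if format == "tsv-pair":
        return _read_tsv_pair(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: OrganismModel, path: str | Path, format: ModelFormat = "native-json") -> Path:
    """Serialize a validated model; inverse of :func:`load_model`."""
    model.validate()
    path = Path(path)
    if format == "native-json":
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(_model_to_dict(model), indent=1))
    elif format == "tsv-pair":
        _write_tsv_pair(model, path)
    elif format == "sbml":
        raise ValueError("SBML export is not supported (import only)")
    else:
        raise ValueError(f"unknown model format {format!r}")
    return path


def load_medium(path: str | Path) -> Medium:
    """Read a 2-column TSV ``metabolite<TAB>max_uptake`` medium table."""
    entries: dict[str, float] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "metabolite":  # optional header
                continue
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                entries[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad rate {parts[1]!r}") from exc
    try:
        return Medium(entries)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_medium(medium: Medium, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("metabolite\tmax_uptake\n")
        for met in sorted(medium.entries):
            fh.write(f"{met}\t{medium.entries[met]!r}\n")
    return path
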