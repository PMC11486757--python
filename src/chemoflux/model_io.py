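"""Stoichiometric model containers and I/O (SBML L3+fbc subset, native JSON).

Only the FBA-relevant content of a model is represented: metabolites,
reactions with stoichiometry and flux bounds, the objective reaction and an
optional maintenance (NGAM) reaction.  Kinetic laws, gene associations and
annotations are outside this package's scope and are ignored on read.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ModelIOError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "read_sbml",
    "read_native",
    "write_native",
    "validate_model",
]

DEFAULT_BOUND = 1000.0


class ModelIOError(ValueError):
    """Raised for unreadable or schema-violating model files."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None


@dataclass
class Reaction:
    """A reaction: stoichiometry (negative = consumed) and flux bounds [mmol/gDW/h]."""

    id: str
    stoichiometry: dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str | None = None
    is_exchange: bool = False


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str | None = None
    ngam_id: str | None = None
    id: str = "model"

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.id!r}")

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[Metabolite(m.id, m.name, m.compartment, m.formula) for m in self.metabolites],
            reactions=[
                Reaction(r.id, dict(r.stoichiometry), r.lb, r.ub, r.name, r.subsystem, r.is_exchange)
                for r in self.reactions
            ],
            objective_id=self.objective_id,
            ngam_id=self.ngam_id,
            id=self.id,
        )


def _mark_exchanges(model: MetabolicModel, exchange_prefix: str = "EX_") -> None:
    for r in model.reactions:
        if len(r.stoichiometry) == 1 or r.id.startswith(exchange_prefix):
            r.is_exchange = True


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml(path, *, exchange_prefix: str = "EX_") -> MetabolicModel:
    """Read an SBML Level 3 model with fbc bounds and objective.

    The supported subset is what constraint-based analysis needs: species,
    reactions with stoichiometry, flux bounds referenced through fbc bound
    parameters (falling back to ±1000 / [0, 1000] by reversibility when
    absent), and the active fbc objective.  Kinetic laws are ignored with a
    warning.  Malformed XML or a missing objective raises ``ModelIOError``.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelIOError(
            f"SBML parse error in {path}: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelIOError(f"{path}: no <model> element")

    params = {
        p.getId(): p.getValue()
        for p in (sbml_model.getParameter(i) for i in range(sbml_model.getNumParameters()))
    }

    model = MetabolicModel(id=sbml_model.getId() or "model")
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are outside the balanced system
        formula = None
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        model.metabolites.append(
            Metabolite(sp.getId(), sp.getName() or "", sp.getCompartment() or "", formula)
        )
    balanced = set(model.metabolite_ids())

    kinetic_seen = False
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        if rxn.isSetKineticLaw():
            kinetic_seen = True
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            if ref.getSpecies() in balanced:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            if ref.getSpecies() in balanced:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rev = rxn.getReversible()
        lb, ub = (-DEFAULT_BOUND if rev else 0.0), DEFAULT_BOUND
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None:
            if fbc_rxn.isSetLowerFluxBound():
                lb = params.get(fbc_rxn.getLowerFluxBound(), lb)
            if fbc_rxn.isSetUpperFluxBound():
                ub = params.get(fbc_rxn.getUpperFluxBound(), ub)
        model.reactions.append(
            Reaction(rxn.getId(), stoich, lb, ub, rxn.getName() or "")
        )
    if kinetic_seen:
        warnings.warn("kinetic laws present in SBML file are ignored", stacklevel=2)

    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = obj.getFluxObjective(0).getReaction()
    if model.objective_id is None:
        raise ModelIOError(f"{path}: no fbc objective defined")

    _mark_exchanges(model, exchange_prefix)
    return model


# ---------------------------------------------------------------------------
# native JSON dialect
# ---------------------------------------------------------------------------

def write_native(model: MetabolicModel, path) -> None:
    """Write the lossless JSON dialect with stable key ordering (diffable)."""
    doc = {
        "id": model.id,
        "objective": model.objective_id,
        "ngam": model.ngam_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment, "formula": m.formula}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lb,
                "ub": r.ub,
                "subsystem": r.subsystem,
                "is_exchange": r.is_exchange,
            }
            for r in model.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _require(cond: bool, jsonpath: str, msg: str) -> None:
    if not cond:
        raise ModelIOError(f"{jsonpath}: {msg}")


def read_native(path) -> MetabolicModel:
    """Read the native JSON dialect, validating the schema with JSON paths."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelIOError(f"{path}: not valid JSON ({e})") from e
    _require(isinstance(doc, dict), "$", "document must be an object")
    _require("metabolites" in doc, "$", "missing 'metabolites'")
    _require("reactions" in doc, "$", "missing 'reactions'")
    model = MetabolicModel(
        id=doc.get("id", "model"),
        objective_id=doc.get("objective"),
        ngam_id=doc.get("ngam"),
    )
    for i, m in enumerate(doc["metabolites"]):
        _require("id" in m, f"$.metabolites[{i}]", "missing 'id'")
        model.metabolites.append(
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""), m.get("formula"))
        )
    for i, r in enumerate(doc["reactions"]):
        where = f"$.reactions[{i}]"
        _require("id" in r, where, "missing 'id'")
        _require(isinstance(r.get("stoichiometry"), dict) and r["stoichiometry"], where, "stoichiometry must be a non-empty object")
        lb = float(r.get("lb", -DEFAULT_BOUND))
        ub = float(r.get("ub", DEFAULT_BOUND))
        _require(lb <= ub, where, f"lb > ub ({lb} > {ub})")
        model.reactions.append(
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoichiometry"].items()},
                lb,
                ub,
                r.get("name", ""),
                r.get("subsystem"),
                bool(r.get("is_exchange", False)),
            )
        )
    return model


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: MetabolicModel) -> list[dict]:
    """Structural checks; returns a machine-readable issue list, never raises.

    Issue kinds: duplicate-id, bad-bounds, nonfinite-bound, empty-stoichiometry,
    unknown-metabolite, orphan-metabolite, missing-objective, bad-exchange.
    """
    issues: list[dict] = []

    seen: set[str] = set()
    for m in model.metabolites:
        if m.id in seen:
            issues.append({"kind": "duplicate-id", "where": m.id, "detail": "metabolite id repeated"})
        seen.add(m.id)
    met_ids = set(model.metabolite_ids())

    rseen: set[str] = set()
    used_mets: set[str] = set()
    for r in model.reactions:
        if r.id in rseen:
            issues.append({"kind": "duplicate-id", "where": r.id, "detail": "reaction id repeated"})
        rseen.add(r.id)
        if not r.stoichiometry:
            issues.append({"kind": "empty-stoichiometry", "where": r.id, "detail": "no participants"})
        if r.lb > r.ub:
            issues.append({"kind": "bad-bounds", "where": r.id, "detail": f"lb {r.lb} > ub {r.ub}"})
        if not (math.isfinite(r.lb) and math.isfinite(r.ub)):
            issues.append({"kind": "nonfinite-bound", "where": r.id, "detail": f"[{r.lb}, {r.ub}]"})
        for met in r.stoichiometry:
            if met not in met_ids:
                issues.append({"kind": "unknown-metabolite", "where": r.id, "detail": met})
            used_mets.add(met)
        if r.is_exchange and len(r.stoichiometry) != 1:
            issues.append(
                {"kind": "bad-exchange", "where": r.id, "detail": f"{len(r.stoichiometry)} metabolites"}
            )
    for mid in met_ids - used_mets:
        issues.append({"kind": "orphan-metabolite", "where": mid, "detail": "not used by any reaction"})

    if model.objective_id is None or model.objective_id not in rseen:
        issues.append(
            {"kind": "missing-objective", "where": str(model.objective_id), "detail": "objective reaction not found"}
        )
    if model.ngam_id is not None and model.ngam_id not in rseen:
        issues.append({"kind": "missing-objective", "where": model.ngam_id, "detail": "ngam reaction not found"})
    return issues
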