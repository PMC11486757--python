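"""Pathway-grouped flux normalization and flux-map overlay export.

Flux vectors from different conditions are hard to compare in absolute
units, so each pathway block is reported relative to a condition-specific
reference scalar: glucose catabolism relative to the glucose uptake flux,
the TCA cycle relative to its own maximal flux, glutamate entry relative to
the total glutamate-to-alpha-ketoglutarate conversion, and the
trehalose/glycogen block relative to glycerate-3-phosphate formation.
Normalized values are magnitudes; direction is kept in a separate column,
and reactions whose direction differs across compared conditions are
flagged rather than given a single normalized value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .fba_core import FluxSolution

__all__ = [
    "NormalizationError",
    "NormalizationScheme",
    "normalize_fluxes",
    "flag_direction_changes",
    "export_flux_map",
    "schemes_from_yaml",
]

_REFERENCE_KINDS = ("reaction", "max_abs_member", "sum_abs")


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationScheme:
    """A pathway block and the rule producing its reference scalar.

    ``reference_kind``:
      - ``"reaction"``: |flux| of ``reference_reactions[0]`` (e.g. glucose uptake,
        G3P formation);
      - ``"max_abs_member"``: max |flux| over the member reactions (TCA-style);
      - ``"sum_abs"``: sum of |flux| over ``reference_reactions`` (e.g. the
        deamination + transamination routes incorporating glutamate).
    """

    name: str
    member_reactions: tuple[str, ...]
    reference_kind: str = "reaction"
    reference_reactions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.member_reactions:
            raise NormalizationError(f"scheme {self.name!r}: member list is empty")
        if self.reference_kind not in _REFERENCE_KINDS:
            raise NormalizationError(
                f"scheme {self.name!r}: unknown reference kind {self.reference_kind!r}"
            )
        if self.reference_kind != "max_abs_member" and not self.reference_reactions:
            raise NormalizationError(
                f"scheme {self.name!r}: reference kind {self.reference_kind!r} "
                "requires reference_reactions"
            )

    def reference_value(self, fluxes: dict[str, float]) -> float:
        if self.reference_kind == "max_abs_member":
            return max(abs(fluxes.get(r, 0.0)) for r in self.member_reactions)
        if self.reference_kind == "reaction":
            return abs(fluxes.get(self.reference_reactions[0], 0.0))
        return sum(abs(fluxes.get(r, 0.0)) for r in self.reference_reactions)


def normalize_fluxes(
    solution: FluxSolution | dict[str, float],
    scheme: NormalizationScheme,
    *,
    other_solutions: Sequence[FluxSolution | dict[str, float]] = (),
) -> pd.DataFrame:
    """Normalize the scheme's member fluxes by the scheme's reference scalar.

    Returns a frame with columns ``reaction``, ``raw_flux``, ``direction``
    (+1/-1/0), ``normalized`` (= |raw|/reference) and
    ``direction_consistent`` (False where the sign differs in any of
    ``other_solutions``, the cross-condition comparison).
    """
    fluxes = solution.fluxes if isinstance(solution, FluxSolution) else dict(solution)
    ref = scheme.reference_value(fluxes)
    if ref <= 0:
        raise NormalizationError(
            f"scheme {scheme.name!r}: reference scalar is {ref:g}; normalization undefined"
        )
    inconsistent = flag_direction_changes([fluxes, *[
        s.fluxes if isinstance(s, FluxSolution) else dict(s) for s in other_solutions
    ]]) if other_solutions else set()
    rows = []
    for rid in scheme.member_reactions:
        raw = fluxes.get(rid, 0.0)
        rows.append(
            {
                "reaction": rid,
                "raw_flux": raw,
                "direction": int(np.sign(raw)),
                "normalized": abs(raw) / ref,
                "direction_consistent": rid not in inconsistent,
            }
        )
    return pd.DataFrame(rows)


def flag_direction_changes(
    solutions: Sequence[dict[str, float]], *, tol: float = 1e-9
) -> set[str]:
    """Reaction ids whose flux direction differs across the given solutions."""
    flagged: set[str] = set()
    all_ids = {rid for sol in solutions for rid in sol}
    for rid in all_ids:
        signs = {int(np.sign(s.get(rid, 0.0))) for s in solutions if abs(s.get(rid, 0.0)) > tol}
        if len(signs) > 1:
            flagged.add(rid)
    return flagged


def export_flux_map(
    solution: FluxSolution | dict[str, float],
    out_path,
    *,
    layout_path=None,
) -> list[str]:
    """Write a reaction-id -> flux overlay JSON for pathway-map viewers.

    The overlay is the plain mapping format Escher-style viewers load as
    reaction data.  If a map layout JSON is given, reaction ids absent from
    the layout are returned as warnings (the overlay is still written).
    """
    fluxes = solution.fluxes if isinstance(solution, FluxSolution) else dict(solution)
    overlay = {rid: float(v) for rid, v in sorted(fluxes.items())}
    with open(out_path, "w") as fh:
        json.dump(overlay, fh, indent=2, sort_keys=True)
        fh.write("\n")
    warnings: list[str] = []
    if layout_path is not None:
        with open(layout_path) as fh:
            layout = json.load(fh)
        layout_ids = _layout_reaction_ids(layout)
        warnings = sorted(rid for rid in overlay if rid not in layout_ids)
    return warnings


def _layout_reaction_ids(layout) -> set[str]:
    # Escher map layout: [header, {"reactions": {idx: {"bigg_id": ...}}}];
    # also accept a flat {"reactions": [ids or objects]} layout
    ids: set[str] = set()
    docs = layout if isinstance(layout, list) else [layout]
    for doc in docs:
        if not isinstance(doc, dict):
            continue
        rxns = doc.get("reactions")
        if isinstance(rxns, dict):
            for entry in rxns.values():
                if isinstance(entry, dict) and "bigg_id" in entry:
                    ids.add(entry["bigg_id"])
        elif isinstance(rxns, list):
            for entry in rxns:
                if isinstance(entry, str):
                    ids.add(entry)
                elif isinstance(entry, dict) and "id" in entry:
                    ids.add(entry["id"])
    return ids


def schemes_from_yaml(path) -> dict[str, NormalizationScheme]:
    """Load normalization schemes from a YAML config (name -> members/reference)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    schemes = {}
    for name, spec in raw.items():
        schemes[name] = NormalizationScheme(
            name=name,
            member_reactions=tuple(spec["members"]),
            reference_kind=spec.get("reference_kind", "reaction"),
            reference_reactions=tuple(spec.get("reference_reactions", ())),
        )
    return schemes
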