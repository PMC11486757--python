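"""Flux balance analysis and parsimonious FBA as linear programs.

FBA maximizes the objective flux (typically biomass production) subject to
the steady-state constraint S·v = 0 and the flux bounds.  pFBA then fixes
the objective at (a fraction of) that optimum and minimizes the total
absolute flux Σ|v| — the standard proxy for minimal enzyme usage — by
splitting each flux into forward and reverse non-negative parts.

Both stages are solved with scipy's HiGHS interface.  Variable order equals
reaction declaration order, so repeated runs on the same model are
bit-stable for a given solver build.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel
from .species import SpeciesCard

__all__ = [
    "FbaError",
    "InfeasibleError",
    "FluxSolution",
    "MeasuredExchange",
    "build_stoichiometric_matrix",
    "apply_measured_exchanges",
    "fba",
    "pfba",
    "exchange_from_specific_rate",
]

#: non-growth-associated maintenance ATP demand [mmol/(gDW h)]
DEFAULT_NGAM = 1.9

_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class FbaError(RuntimeError):
    pass


class InfeasibleError(FbaError):
    pass


@dataclass
class FluxSolution:
    """Solver status, objective value and the per-reaction flux vector."""

    status: str
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)
    total_abs_flux: float = float("nan")

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class MeasuredExchange:
    """A measured exchange rate with its standard deviation [mmol/gDW/h].

    ``rate`` is in the exchange-flux sign convention: negative = uptake,
    positive = secretion.  ``fixed_zero`` marks species shown analytically
    not to be exchanged (their flux is clamped to exactly zero).
    """

    reaction_id: str
    rate: float = 0.0
    sd: float = 0.0
    fixed_zero: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.reaction_id}: sd must be >= 0")
        if self.fixed_zero and self.rate != 0.0:
            raise ValueError(f"{self.reaction_id}: fixed_zero requires rate == 0")


def exchange_from_specific_rate(
    reaction_id: str,
    q_g_per_g_h: float,
    sd_g_per_g_h: float,
    card: SpeciesCard,
    *,
    uptake: bool = True,
) -> MeasuredExchange:
    """Adapter from physiology's g/g/h rates to mmol/gDW/h exchange fluxes.

    Physiology reports uptake-positive substrate rates and production-positive
    product rates; exchange fluxes are negative for uptake.
    """
    scale = 1000.0 / card.molar_mass  # g/g/h -> mmol/gDW/h
    sign = -1.0 if uptake else 1.0
    return MeasuredExchange(reaction_id, sign * q_g_per_g_h * scale, sd_g_per_g_h * scale)


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """S[i, j] = coefficient of metabolite i in reaction j (declaration order)."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.stoichiometry.items():
            try:
                S[met_index[met], j] = coef
            except KeyError:
                raise FbaError(f"reaction {rxn.id!r} references unknown metabolite {met!r}") from None
    return S


def apply_measured_exchanges(
    model: MetabolicModel,
    constraints: list[MeasuredExchange],
    *,
    sign_convention: str = "negative_uptake",
    ngam: float | None = DEFAULT_NGAM,
) -> MetabolicModel:
    """Return a copy of the model with measured exchanges fixed (lb = ub).

    ``fixed_zero`` exchanges are clamped at 0; other measured exchanges are
    fixed at their signed rate.  If the model declares a maintenance reaction
    (``ngam_id``), its lower bound is set to ``ngam`` so the network must
    regenerate at least that much ATP regardless of growth.
    """
    if sign_convention not in ("negative_uptake", "positive_uptake"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    flip = -1.0 if sign_convention == "positive_uptake" else 1.0
    out = model.copy()
    ids = out.reaction_ids()
    for c in constraints:
        if c.reaction_id not in ids:
            candidates = difflib.get_close_matches(c.reaction_id, ids, n=3)
            raise FbaError(
                f"no reaction {c.reaction_id!r} in model; close matches: {candidates or 'none'}"
            )
        rxn = out.get_reaction(c.reaction_id)
        value = 0.0 if c.fixed_zero else flip * c.rate
        rxn.lb = rxn.ub = value
    if out.ngam_id is not None and ngam is not None:
        maint = out.get_reaction(out.ngam_id)
        maint.lb = ngam
        if maint.ub < ngam:
            maint.ub = ngam
    return out


def _objective_vector(model: MetabolicModel) -> np.ndarray:
    if model.objective_id is None:
        raise FbaError("model has no objective reaction")
    c = np.zeros(len(model.reactions))
    ids = model.reaction_ids()
    try:
        c[ids.index(model.objective_id)] = 1.0
    except ValueError:
        raise FbaError(f"objective reaction {model.objective_id!r} not in model") from None
    return c


def fba(model: MetabolicModel) -> FluxSolution:
    """Maximize the objective flux subject to S·v = 0 and the bounds."""
    S = build_stoichiometric_matrix(model)
    c = _objective_vector(model)
    bounds = [(r.lb, r.ub) for r in model.reactions]
    res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    v = res.x
    return FluxSolution(
        status="optimal",
        objective_value=float(c @ v),
        fluxes={rid: float(val) for rid, val in zip(model.reaction_ids(), v)},
        total_abs_flux=float(np.abs(v).sum()),
    )


def pfba(
    model: MetabolicModel,
    optimum_fraction: float = 1.0,
    *,
    rel_eps: float = 1e-6,
) -> FluxSolution:
    """Parsimonious FBA: minimal total |v| at (a fraction of) the FBA optimum.

    Stage 1 computes the FBA optimum ``opt``; stage 2 splits v = v⁺ − v⁻
    (v± ≥ 0), pins the objective flux at optimum_fraction·opt (an equality
    row, so the minimization cannot trade objective for total flux within
    the ε slack), and minimizes Σ(v⁺ + v⁻).  ``rel_eps`` is the tolerance
    used when verifying the returned objective against stage 1.
    """
    stage1 = fba(model)
    if not stage1.optimal:
        return stage1
    opt = stage1.objective_value

    n = len(model.reactions)
    S = build_stoichiometric_matrix(model)
    c_obj = _objective_vector(model)
    lb = np.array([r.lb for r in model.reactions])
    ub = np.array([r.ub for r in model.reactions])

    # variables: [v+ (n), v- (n)], v = v+ - v-
    A_eq = np.vstack([np.hstack([S, -S]), np.hstack([c_obj, -c_obj])[None, :]])
    b_eq = np.concatenate([np.zeros(S.shape[0]), [optimum_fraction * opt]])
    # bounds on v as inequalities: v <= ub, -v <= -lb
    eye = np.eye(n)
    A_ub = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, eye])])
    b_ub = np.concatenate([ub, -lb])
    var_bounds = [(0.0, max(ub[j], 0.0) if np.isfinite(ub[j]) else None) for j in range(n)] + [
        (0.0, max(-lb[j], 0.0) if np.isfinite(lb[j]) else None) for j in range(n)
    ]
    cost = np.ones(2 * n)
    res = linprog(
        cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds, method="highs"
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=float("nan"))
    v = res.x[:n] - res.x[n:]
    return FluxSolution(
        status="optimal",
        objective_value=float(c_obj @ v),
        fluxes={rid: float(val) for rid, val in zip(model.reaction_ids(), v)},
        total_abs_flux=float(np.abs(v).sum()),
    )
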