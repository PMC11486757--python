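"""Chemostat mass-balance physiology: specific rates, Cmol yields, C-balance.

A chemostat is a continuously fed stirred-tank reactor from which broth is
removed through a bleed tube at fixed height, so the working volume stays
constant.  Between two sampling points t_{n-1} and t_n every extensive
quantity (biomass, each dissolved species) obeys a mass balance over the
window: change in the reactor + what left through the outflow − what came in
with the feed = what the cells produced (or, with the opposite sign,
consumed).  Dividing by the mean biomass inventory x̄·V and the window length
Δt turns those balances into biomass-specific rates:

    μ   = [(x_end − x_start)·V + x̄·ΔV_bleed] / (x̄·V·Δt)              [1/h]
    q_S = [s_in·V_in − s̄·V_out − (s_end − s_start)·V] / (x̄·V·Δt)     [g/g/h]
    q_P = [(p_end − p_start)·V + p̄·V_out − p_in·V_in] / (x̄·V·Δt)     [g/g/h]

with x̄, s̄, p̄ the arithmetic means of the window endpoints.  Uptake rates are
reported positive for consumption, production rates positive for formation.
At steady state with the bleed as the only outflow, μ equals the dilution
rate D = V_out/(V·Δt) exactly.

Carbon accounting converts each rate to Cmol via the species registry;
yields are Cmol-per-Cmol-of-substrate and the carbon balance is the sum of
the biomass, CO2, trehalose and amino-acid yields.  A value of 1 means all
consumed carbon is accounted for by the measured sinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .species import SpeciesCard, SpeciesRegistry, DEFAULT_BIOMASS_CMOL_MASS, default_registry

__all__ = [
    "PhysiologyError",
    "WindowError",
    "UndefinedRateError",
    "SamplePoint",
    "ConditionWindow",
    "RatePanel",
    "YieldPanel",
    "specific_growth_rate",
    "specific_uptake_rate",
    "specific_production_rate",
    "accumulation_rate",
    "volumetric_uptake_rate",
    "co2_evolution_rate",
    "to_cmol",
    "yields_and_cbalance",
    "compute_rate_panel",
    "summarize_condition",
    "samples_from_frame",
    "window_between",
]


class PhysiologyError(ValueError):
    """Base class for physiology-stage errors."""


class WindowError(PhysiologyError):
    """Raised for degenerate sampling windows (Δt <= 0, negative volumes)."""


class UndefinedRateError(PhysiologyError):
    """Raised when a rate or yield is undefined (zero biomass, zero uptake)."""


@dataclass(frozen=True)
class SamplePoint:
    """One timestamped reactor-state measurement.

    Parameters
    ----------
    t : float
        Sampling time [h].
    x : float
        Volumetric dry cell weight [g/L].
    conc : mapping
        Species -> concentration in broth [g/L].
    v_reactor : float
        Working volume [L].
    co2_offgas : float, optional
        CO2 mole fraction in the exhaust gas [-].
    gas_flow : float, optional
        Aeration rate [L/h].
    """

    t: float
    x: float
    conc: Mapping[str, float] = field(default_factory=dict)
    v_reactor: float = 2.0
    co2_offgas: float | None = None
    gas_flow: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise PhysiologyError("sample time must be finite")
        if self.x < 0:
            raise PhysiologyError(f"DCW must be >= 0, got {self.x}")
        if self.v_reactor <= 0:
            raise PhysiologyError(f"working volume must be > 0, got {self.v_reactor}")
        for sp, c in self.conc.items():
            if c < 0:
                raise PhysiologyError(f"concentration of {sp!r} must be >= 0, got {c}")


@dataclass(frozen=True)
class ConditionWindow:
    """Paired-sample window over which the mass balances are evaluated.

    ``v_in``/``v_out``/``v_bleed`` are the volumes supplied to, discharged
    from and removed via the bleed during the window [L]; ``feed_conc`` maps
    species to their concentration in the (combined) feed [g/L].
    """

    start: SamplePoint
    end: SamplePoint
    v_in: float = 0.0
    v_out: float = 0.0
    v_bleed: float = 0.0
    feed_conc: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end.t <= self.start.t:
            raise WindowError(
                f"window must advance in time: start t={self.start.t}, end t={self.end.t}"
            )
        for name in ("v_in", "v_out", "v_bleed"):
            if getattr(self, name) < 0:
                raise WindowError(f"{name} must be >= 0")

    @property
    def dt(self) -> float:
        return self.end.t - self.start.t

    @property
    def x_mean(self) -> float:
        return 0.5 * (self.start.x + self.end.x)

    @property
    def v_reactor(self) -> float:
        return self.end.v_reactor

    def conc_mean(self, species: str) -> float:
        return 0.5 * (self.start.conc.get(species, 0.0) + self.end.conc.get(species, 0.0))


@dataclass
class RatePanel:
    """Per-window specific rates.

    Sign convention: ``q[s]`` is uptake-positive for substrates and
    production-positive for products (the roles are recorded in
    ``substrates``/``products``).  ``q_co2`` is the specific CO2 evolution
    rate in Cmol/g/h, ``None`` when no off-gas data were available.
    """

    mu: float
    q: dict[str, float] = field(default_factory=dict)
    r: dict[str, float] = field(default_factory=dict)
    accumulation: dict[str, float] = field(default_factory=dict)
    q_co2: float | None = None
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        out = {"mu_per_h": self.mu}
        for sp, v in self.q.items():
            out[f"q_{sp}_g_per_g_h"] = v
        for sp, v in self.r.items():
            out[f"r_{sp}_g_per_h"] = v
        for sp, v in self.accumulation.items():
            out[f"acc_{sp}_g_per_L_h"] = v
        if self.q_co2 is not None:
            out["q_co2_cmol_per_g_h"] = self.q_co2
        return out


@dataclass
class YieldPanel:
    """Cmol-based yields and their sum, the carbon balance.

    ``partial`` is set when the CO2 term was unavailable, in which case
    ``c_balance`` covers only the measured sinks.
    """

    y_xs: float
    y_co2s: float
    y_tres: float
    y_aas: float
    c_balance: float
    partial: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "y_xs_cmol_per_cmol": self.y_xs,
            "y_co2s_cmol_per_cmol": self.y_co2s,
            "y_tres_cmol_per_cmol": self.y_tres,
            "y_aas_cmol_per_cmol": self.y_aas,
            "c_balance": self.c_balance,
        }


# ---------------------------------------------------------------------------
# elementary rate operations
# ---------------------------------------------------------------------------

def specific_growth_rate(w: ConditionWindow) -> float:
    """Specific growth rate μ [1/h] from the biomass balance over a window.

    Accounts for the biomass lost through the bleed; at steady state
    (constant x, bleed at dilution rate D) this returns exactly D.
    """
    x_bar = w.x_mean
    if x_bar <= 0:
        raise UndefinedRateError("mean DCW over the window is zero; growth rate undefined")
    num = (w.end.x - w.start.x) * w.v_reactor + x_bar * w.v_bleed
    return num / (x_bar * w.v_reactor * w.dt)


def _uptake_numerator(w: ConditionWindow, species: str, verbatim_eq2: bool) -> float:
    s_start = w.start.conc.get(species, 0.0)
    s_end = w.end.conc.get(species, 0.0)
    s_in = w.feed_conc.get(species, 0.0)
    s_bar = 0.5 * (s_start + s_end)
    supplied = s_in * w.v_in
    discharged = s_bar * w.v_out
    accumulated = (s_end - s_start) * w.v_reactor
    if verbatim_eq2:
        # literal published numerator: accumulation enters with a + sign
        return accumulated + supplied - discharged
    return supplied - discharged - accumulated


def specific_uptake_rate(
    w: ConditionWindow,
    species: str,
    x_mean: float | None = None,
    *,
    verbatim_eq2: bool = False,
) -> float:
    """Specific substrate uptake rate q_S [g/g/h], positive = consumed.

    Default is the mass-balance-consistent form
    (supplied − discharged − accumulated); ``verbatim_eq2`` switches to the
    published numerator in which the accumulation term is added, for audit.
    """
    x_bar = w.x_mean if x_mean is None else x_mean
    if x_bar <= 0:
        raise UndefinedRateError("mean DCW is zero; uptake rate undefined")
    return _uptake_numerator(w, species, verbatim_eq2) / (x_bar * w.v_reactor * w.dt)


def specific_production_rate(
    w: ConditionWindow, species: str, x_mean: float | None = None
) -> float:
    """Specific production rate q_P [g/g/h], positive = produced.

    Product formed = accumulation in the reactor + product discharged −
    product supplied with the feed; feed and discharge terms are volumed
    (p_in·V_in, p̄·V_out) for dimensional consistency.
    """
    x_bar = w.x_mean if x_mean is None else x_mean
    if x_bar <= 0:
        raise UndefinedRateError("mean DCW is zero; production rate undefined")
    p_start = w.start.conc.get(species, 0.0)
    p_end = w.end.conc.get(species, 0.0)
    p_bar = 0.5 * (p_start + p_end)
    p_in = w.feed_conc.get(species, 0.0)
    num = (p_end - p_start) * w.v_reactor + p_bar * w.v_out - p_in * w.v_in
    return num / (x_bar * w.v_reactor * w.dt)


def accumulation_rate(w: ConditionWindow, species: str) -> float:
    """Concentration change rate (s_end − s_start)/Δt [g/L/h]."""
    return (w.end.conc.get(species, 0.0) - w.start.conc.get(species, 0.0)) / w.dt


def volumetric_uptake_rate(
    w: ConditionWindow, species: str, *, verbatim_eq2: bool = False
) -> float:
    """Reactor-scale substrate uptake rate r [g/h] (uptake numerator / Δt)."""
    return _uptake_numerator(w, species, verbatim_eq2) / w.dt


def co2_evolution_rate(
    points: Sequence[SamplePoint],
    w: ConditionWindow,
    *,
    molar_volume: float = 24.0,
    inlet_co2_frac: float = 0.0004,
) -> float | None:
    """Specific CO2 evolution rate [Cmol/g/h] from the off-gas trace.

    Integrates gas_flow·(co2_offgas − inlet baseline)/molar_volume over the
    window (trapezoid over the available samples) and divides by x̄·V·Δt.
    Returns ``None`` when no sample in the window carries off-gas data, so
    the carbon balance can be flagged as partial rather than silently wrong.
    """
    inside = [
        p
        for p in points
        if w.start.t <= p.t <= w.end.t and p.co2_offgas is not None and p.gas_flow is not None
    ]
    if not inside:
        return None
    t = np.array([p.t for p in inside])
    # molar CO2 evolution rate [mol/h] at each sample
    rate = np.array(
        [p.gas_flow * (p.co2_offgas - inlet_co2_frac) / molar_volume for p in inside]
    )
    if len(inside) == 1:
        total = float(rate[0]) * w.dt
    else:
        total = float(np.trapezoid(rate, t)) * w.dt / (t[-1] - t[0])
    x_bar = w.x_mean
    if x_bar <= 0:
        raise UndefinedRateError("mean DCW is zero; CO2 evolution rate undefined")
    return total / (x_bar * w.v_reactor * w.dt)


def to_cmol(mass_rate: float, card: SpeciesCard) -> float:
    """Convert a mass-based rate [g/(·)/h] to carbon moles [Cmol/(·)/h]."""
    return mass_rate / card.molar_mass * card.carbon_atoms


# ---------------------------------------------------------------------------
# yields and carbon balance
# ---------------------------------------------------------------------------

def yields_and_cbalance(
    rates: RatePanel,
    registry: SpeciesRegistry | None = None,
    *,
    substrates: Sequence[str] | None = None,
    trehalose: str = "trehalose",
    amino_acids: Sequence[str] | None = None,
    biomass_cmol_mass: float = DEFAULT_BIOMASS_CMOL_MASS,
) -> YieldPanel:
    """Cmol yields Y_x/s, Y_CO2/s, Y_Tre/s, Y_AA/s and their sum.

    Y_x/s is the quotient of μ (converted to Cmol of biomass per g of
    biomass) and the total substrate uptake in Cmol; the product yields are
    the corresponding quotients of the production rates.  The carbon balance
    is defined as the sum of the four yields.
    """
    registry = registry or default_registry(biomass_cmol_mass)
    subs = list(substrates if substrates is not None else rates.substrates)
    if not subs:
        raise UndefinedRateError("no substrates declared; carbon balance undefined")
    q_s_cmol = sum(to_cmol(rates.q[s], registry[s]) for s in subs)
    if q_s_cmol <= 0:
        raise UndefinedRateError(f"total substrate uptake is {q_s_cmol:g} Cmol/g/h; yields undefined")

    mu_cmol = rates.mu / biomass_cmol_mass  # Cmol_x / g_x / h
    y_xs = mu_cmol / q_s_cmol

    partial = rates.q_co2 is None
    y_co2s = 0.0 if partial else rates.q_co2 / q_s_cmol

    y_tres = 0.0
    if trehalose in rates.q:
        y_tres = to_cmol(rates.q[trehalose], registry[trehalose]) / q_s_cmol

    aas = list(
        amino_acids
        if amino_acids is not None
        else [p for p in rates.products if p != trehalose]
    )
    y_aas = sum(to_cmol(rates.q[a], registry[a]) for a in aas if a in rates.q) / q_s_cmol

    c_balance = y_xs + y_co2s + y_tres + y_aas
    return YieldPanel(y_xs, y_co2s, y_tres, y_aas, c_balance, partial=partial)


def compute_rate_panel(
    w: ConditionWindow,
    substrates: Sequence[str],
    products: Sequence[str] = (),
    *,
    points: Sequence[SamplePoint] | None = None,
    verbatim_eq2: bool = False,
    molar_volume: float = 24.0,
    inlet_co2_frac: float = 0.0004,
) -> RatePanel:
    """Evaluate all window rates in one pass: μ, q per species, r, accumulation, q_CO2."""
    mu = specific_growth_rate(w)
    q: dict[str, float] = {}
    r: dict[str, float] = {}
    acc: dict[str, float] = {}
    for s in substrates:
        q[s] = specific_uptake_rate(w, s, verbatim_eq2=verbatim_eq2)
        r[s] = volumetric_uptake_rate(w, s, verbatim_eq2=verbatim_eq2)
        acc[s] = accumulation_rate(w, s)
    for p in products:
        q[p] = specific_production_rate(w, p)
        acc[p] = accumulation_rate(w, p)
    trace = points if points is not None else (w.start, w.end)
    q_co2 = co2_evolution_rate(
        trace, w, molar_volume=molar_volume, inlet_co2_frac=inlet_co2_frac
    )
    return RatePanel(
        mu=mu,
        q=q,
        r=r,
        accumulation=acc,
        q_co2=q_co2,
        substrates=tuple(substrates),
        products=tuple(products),
    )


def summarize_condition(
    panels: Iterable[RatePanel | YieldPanel | Mapping[str, float]],
) -> pd.DataFrame:
    """Mean ± sample SD over replicate windows.

    Returns a tidy frame indexed by quantity with columns ``mean``, ``sd``
    and ``n``; a single replicate yields SD 0 with n = 1 so downstream code
    can see the SD is not estimable.
    """
    rows = []
    for p in panels:
        if isinstance(p, (RatePanel, YieldPanel)):
            rows.append(p.as_dict())
        else:
            rows.append(dict(p))
    if not rows:
        raise PhysiologyError("summarize_condition requires at least one replicate")
    df = pd.DataFrame(rows)
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1).fillna(0.0),
            "n": df.count(),
        }
    )
    out.index.name = "quantity"
    return out


# ---------------------------------------------------------------------------
# tabular I/O helpers
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = [
    "condition",
    "replicate",
    "t_h",
    "dcw_g_per_L",
    "volume_L",
    "species",
    "conc_g_per_L",
    "v_in_L",
    "v_out_L",
    "v_bleed_L",
    "co2_frac",
    "gas_flow_L_per_h",
]


def samples_from_frame(
    df: pd.DataFrame,
) -> dict[tuple, tuple[list[SamplePoint], dict[float, dict[str, float]]]]:
    """Long-format sample table -> per (condition, replicate) sample series.

    One row per (time, species); per-time metadata (DCW, volume, off-gas)
    must agree across the species rows of one time point.  Returns, for each
    group, the SamplePoint list and a per-time record of the cumulative
    v_in_L / v_out_L / v_bleed_L columns, which :func:`window_between` turns
    into window volumes by differencing.
    """
    missing = [c for c in ("condition", "replicate", "t_h", "dcw_g_per_L", "volume_L", "species", "conc_g_per_L") if c not in df.columns]
    if missing:
        raise PhysiologyError(f"sample table missing columns: {missing}")
    series: dict[tuple, tuple[list[SamplePoint], dict[float, dict[str, float]]]] = {}
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        pts = []
        cum: dict[float, dict[str, float]] = {}
        for t, tgrp in grp.groupby("t_h", sort=True):
            row0 = tgrp.iloc[0]
            conc = dict(zip(tgrp["species"], tgrp["conc_g_per_L"]))
            co2 = row0.get("co2_frac")
            gas = row0.get("gas_flow_L_per_h")
            pts.append(
                SamplePoint(
                    t=float(t),
                    x=float(row0["dcw_g_per_L"]),
                    conc=conc,
                    v_reactor=float(row0["volume_L"]),
                    co2_offgas=None if pd.isna(co2) else float(co2),
                    gas_flow=None if pd.isna(gas) else float(gas),
                )
            )
            cum[float(t)] = {
                "v_in": float(row0.get("v_in_L", 0.0) or 0.0),
                "v_out": float(row0.get("v_out_L", 0.0) or 0.0),
                "v_bleed": float(row0.get("v_bleed_L", 0.0) or 0.0),
            }
        series[(cond, rep)] = (pts, cum)
    return series


def window_between(
    start: SamplePoint,
    end: SamplePoint,
    feed_conc: Mapping[str, float],
    *,
    v_in: float | None = None,
    v_out: float | None = None,
    v_bleed: float | None = None,
    cumulative: Mapping[float, Mapping[str, float]] | None = None,
) -> ConditionWindow:
    """Build a ConditionWindow from two sample points.

    Window volumes are given directly or derived as differences of the
    cumulative per-point volume records produced by ``samples_from_frame``.
    """
    if cumulative is not None:
        a, b = cumulative[start.t], cumulative[end.t]
        v_in = b["v_in"] - a["v_in"] if v_in is None else v_in
        v_out = b["v_out"] - a["v_out"] if v_out is None else v_out
        v_bleed = b["v_bleed"] - a["v_bleed"] if v_bleed is None else v_bleed
    return ConditionWindow(
        start=start,
        end=end,
        v_in=v_in or 0.0,
        v_out=v_out or 0.0,
        v_bleed=v_bleed or 0.0,
        feed_conc=feed_conc,
    )
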