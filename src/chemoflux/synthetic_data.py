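"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators live here:

* :func:`simulate_chemostat` — forward-integrates the chemostat mass
  balances (constant working volume, bleed at fixed height, optional
  evaporation) for a scenario with *known* specific rates, emits noisy
  sample-point series in the physiology schema plus a carbon-truth ledger.
  Because the true rates are inputs, the physiology stage can be checked
  for exact recovery.

* :func:`make_toy_model` — small stoichiometric networks (linear chain, a
  chain with a redundant detour, a dual-substrate network shaped like the
  glucose + glutamate study system, and a branched TCA-like cycle) whose
  FBA/pFBA optima are derived by hand and returned alongside the model.

* :func:`simulate_de_table` — per-gene statistics tables with planted true
  positives for the DEG screen.

The carbon ledger of a scenario allocates every Cmol consumed to biomass,
measured products, CO2 and an optional *unmeasured sink*; the sink emulates
carbon leaving through channels the measurement set does not cover (e.g.
storage compounds), which makes the measured carbon balance close at
1 − sink_fraction instead of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fba_core import FluxSolution
from .model_io import MetabolicModel, Metabolite, Reaction
from .physiology import ConditionWindow, SamplePoint
from .species import DEFAULT_BIOMASS_CMOL_MASS, SpeciesRegistry, default_registry

__all__ = [
    "ChemostatScenario",
    "ChemostatSimulation",
    "simulate_chemostat",
    "windows_from_simulation",
    "samples_frame",
    "ToyModelSpec",
    "make_toy_model",
    "simulate_de_table",
    "load_preset",
    "preset_names",
    "scenario_from_yaml",
]

_RK4_DT = 0.01  # h; windows span hours, so discretization error is negligible


@dataclass(frozen=True)
class ChemostatScenario:
    """A chemostat run with known true rates.

    Flows are in g/h (``tfr`` total = ``sfr`` substrate feed + ``wfr`` water
    feed) and converted to L/h with ``density``; ``feed_conc`` is the
    *effective* concentration of each species in the combined feed stream.
    ``true_q`` is signed: positive = consumed, negative = produced [g/g/h].
    ``evaporation`` [L/h] leaves the reactor without carrying solutes, so
    the bleed flow is feed flow minus evaporation; at steady state the
    specific growth rate equals the bleed dilution rate.
    """

    name: str = "custom"
    v_reactor: float = 2.0
    feed_conc: Mapping[str, float] = field(default_factory=dict)
    tfr: float = 90.0
    sfr: float = 22.5
    wfr: float = 67.5
    density: float = 1000.0  # g/L; feed density taken as water
    evaporation: float = 0.0
    true_mu: float = 0.045
    true_q: Mapping[str, float] = field(default_factory=dict)
    unmeasured_sink_fraction: float = 0.0
    x0: float = 5.0
    c0: Mapping[str, float] | None = None
    gas_flow: float = 30.0  # 0.25 vvm on a 2 L working volume
    molar_volume: float = 24.0
    inlet_co2_frac: float = 0.0004
    biomass_cmol_mass: float = DEFAULT_BIOMASS_CMOL_MASS
    noise_cv: Mapping[str, float] = field(default_factory=dict)  # keys: dcw, conc, offgas
    grid: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.unmeasured_sink_fraction < 1.0:
            raise ValueError("unmeasured_sink_fraction must be in [0, 1)")
        if any(f < 0 for f in (self.tfr, self.sfr, self.wfr)):
            raise ValueError("flow rates must be >= 0")
        if len(self.grid) < 2 or any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("sampling grid must be strictly increasing with >= 2 points")
        if self.flow_out < 0:
            raise ValueError("evaporation exceeds the feed flow")

    @property
    def flow_in(self) -> float:
        """Volumetric feed flow [L/h]."""
        return self.tfr / self.density

    @property
    def flow_out(self) -> float:
        """Bleed flow [L/h] (feed minus evaporation; volume is constant)."""
        return self.flow_in - self.evaporation

    @property
    def dilution_out(self) -> float:
        return self.flow_out / self.v_reactor

    @classmethod
    def from_stock(
        cls, stock_conc: Mapping[str, float], **kwargs
    ) -> "ChemostatScenario":
        """Build a scenario from stock feed concentrations diluted by the water feed."""
        tfr = kwargs.get("tfr", 90.0)
        sfr = kwargs.get("sfr", 22.5)
        feed = {sp: c * sfr / tfr for sp, c in stock_conc.items()}
        return cls(feed_conc=feed, **kwargs)

    def steady_concentrations(self) -> dict[str, float]:
        """Broth concentrations at which every species balance is stationary."""
        d_in = self.flow_in / self.v_reactor
        d_out = self.dilution_out
        out = {}
        for sp in set(self.feed_conc) | set(self.true_q):
            q = self.true_q.get(sp, 0.0)
            inflow = d_in * self.feed_conc.get(sp, 0.0)
            if d_out <= 0:
                raise ValueError("steady concentrations require a positive bleed flow")
            out[sp] = max((inflow - q * self.x0) / d_out, 0.0)
        return out

    def carbon_ledger(self, registry: SpeciesRegistry | None = None) -> dict[str, float]:
        """Per-gram carbon allocation [Cmol/g/h]; exact by construction.

        consumed = biomass + products + co2 + sink; the measured carbon
        balance (biomass + products + co2 over consumed) is 1 − sink_fraction.
        """
        registry = registry or default_registry(self.biomass_cmol_mass)
        consumed = sum(
            q * registry[sp].cmol_per_gram for sp, q in self.true_q.items() if q > 0
        )
        produced = sum(
            -q * registry[sp].cmol_per_gram for sp, q in self.true_q.items() if q < 0
        )
        biomass = self.true_mu / self.biomass_cmol_mass
        sink = self.unmeasured_sink_fraction * consumed
        co2 = consumed - biomass - produced - sink
        if co2 < 0:
            raise ValueError(
                f"scenario {self.name!r}: carbon ledger requires negative CO2 "
                f"({co2:.3g} Cmol/g/h); reduce mu, products or sink fraction"
            )
        return {
            "consumed": consumed,
            "biomass": biomass,
            "products": produced,
            "co2": co2,
            "sink": sink,
            "sink_fraction": self.unmeasured_sink_fraction,
            "expected_c_balance": 1.0 - self.unmeasured_sink_fraction,
        }


@dataclass
class ChemostatSimulation:
    """Simulator output: noisy and clean sample series plus the truth ledger."""

    scenario: ChemostatScenario
    points: list[SamplePoint]
    clean_points: list[SamplePoint]
    truth: dict


def _rhs(scenario: ChemostatScenario, x: float, conc: np.ndarray, species: list[str]) -> tuple[float, np.ndarray]:
    d_in = scenario.flow_in / scenario.v_reactor
    d_out = scenario.dilution_out
    dx = (scenario.true_mu - d_out) * x
    dc = np.empty_like(conc)
    for i, sp in enumerate(species):
        q = scenario.true_q.get(sp, 0.0)
        dc[i] = d_in * scenario.feed_conc.get(sp, 0.0) - d_out * conc[i] - q * x
    return dx, dc


def simulate_chemostat(scenario: ChemostatScenario) -> ChemostatSimulation:
    """Integrate the reactor balances and emit (noisy) sample points.

    Biomass: dx/dt = (μ − D_out)·x; species i:
    dc/dt = D_in·c_feed − D_out·c − q·x.  RK4 with a 0.01 h step; a scenario
    initialized exactly at steady state stays there to machine precision.
    Multiplicative Gaussian noise (per-channel CV) is applied to DCW,
    concentrations and the off-gas fraction of the emitted points.
    """
    species = sorted(set(scenario.feed_conc) | set(scenario.true_q))
    ledger = scenario.carbon_ledger()
    x = float(scenario.x0)
    c0 = scenario.c0 if scenario.c0 is not None else scenario.steady_concentrations()
    conc = np.array([max(c0.get(sp, 0.0), 0.0) for sp in species], dtype=float)

    rng = np.random.default_rng(scenario.seed)
    cv_dcw = scenario.noise_cv.get("dcw", 0.0)
    cv_conc = scenario.noise_cv.get("conc", 0.0)
    cv_gas = scenario.noise_cv.get("offgas", 0.0)

    clean: list[SamplePoint] = []
    noisy: list[SamplePoint] = []

    def emit(t: float) -> None:
        co2_rate = ledger["co2"] * x * scenario.v_reactor  # mol/h
        frac = co2_rate * scenario.molar_volume / scenario.gas_flow + scenario.inlet_co2_frac
        clean.append(
            SamplePoint(
                t=t,
                x=x,
                conc={sp: float(v) for sp, v in zip(species, conc)},
                v_reactor=scenario.v_reactor,
                co2_offgas=frac,
                gas_flow=scenario.gas_flow,
            )
        )
        noisy.append(
            SamplePoint(
                t=t,
                x=max(x * (1.0 + cv_dcw * rng.standard_normal()), 0.0),
                conc={
                    sp: max(float(v) * (1.0 + cv_conc * rng.standard_normal()), 0.0)
                    for sp, v in zip(species, conc)
                },
                v_reactor=scenario.v_reactor,
                co2_offgas=max(frac * (1.0 + cv_gas * rng.standard_normal()), 0.0),
                gas_flow=scenario.gas_flow,
            )
        )

    emit(scenario.grid[0])
    for t0, t1 in zip(scenario.grid, scenario.grid[1:]):
        span = t1 - t0
        n = max(int(math.ceil(span / _RK4_DT)), 1)
        h = span / n
        for _ in range(n):
            k1x, k1c = _rhs(scenario, x, conc, species)
            k2x, k2c = _rhs(scenario, x + 0.5 * h * k1x, conc + 0.5 * h * k1c, species)
            k3x, k3c = _rhs(scenario, x + 0.5 * h * k2x, conc + 0.5 * h * k2c, species)
            k4x, k4c = _rhs(scenario, x + h * k3x, conc + h * k3c, species)
            x = x + h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
            conc = conc + h / 6.0 * (k1c + 2 * k2c + 2 * k3c + k4c)
            conc = np.maximum(conc, 0.0)
        emit(t1)

    truth = {
        "mu": scenario.true_mu,
        "q": dict(scenario.true_q),
        "dilution_out": scenario.dilution_out,
        "carbon": ledger,
        "species": species,
    }
    return ChemostatSimulation(scenario=scenario, points=noisy, clean_points=clean, truth=truth)


def windows_from_simulation(
    sim: ChemostatSimulation, *, use_clean: bool = False
) -> list[ConditionWindow]:
    """Consecutive-sample windows with the scenario's flow bookkeeping attached."""
    sc = sim.scenario
    pts = sim.clean_points if use_clean else sim.points
    windows = []
    for a, b in zip(pts, pts[1:]):
        dt = b.t - a.t
        windows.append(
            ConditionWindow(
                start=a,
                end=b,
                v_in=sc.flow_in * dt,
                v_out=sc.flow_out * dt,
                v_bleed=sc.flow_out * dt,
                feed_conc=dict(sc.feed_conc),
            )
        )
    return windows


def samples_frame(sim: ChemostatSimulation, condition: str = "", replicate: int = 1) -> pd.DataFrame:
    """Long-format sample table in the physiology CSV schema (cumulative volumes)."""
    sc = sim.scenario
    cond = condition or sc.name
    rows = []
    t0 = sim.points[0].t
    for p in sim.points:
        elapsed = p.t - t0
        for sp, conc in sorted(p.conc.items()):
            rows.append(
                {
                    "condition": cond,
                    "replicate": replicate,
                    "t_h": p.t,
                    "dcw_g_per_L": p.x,
                    "volume_L": p.v_reactor,
                    "species": sp,
                    "conc_g_per_L": conc,
                    "v_in_L": sc.flow_in * elapsed,
                    "v_out_L": sc.flow_out * elapsed,
                    "v_bleed_L": sc.flow_out * elapsed,
                    "co2_frac": p.co2_offgas,
                    "gas_flow_L_per_h": p.gas_flow,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy stoichiometric networks with hand-derived optima
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSpec:
    """Recipe for a small network whose optimum is known in closed form.

    Topologies: ``chain`` (uptake -> biomass), ``chain_detour`` (adds a
    redundant two-step route, distinguishing pFBA from FBA), ``dual_substrate``
    (glucose + glutamate analogue with an overflow valve, a zero-fixable
    secretion exchange and an ATP maintenance reaction), ``branched_tca``
    (uptake feeding a cycle with a cataplerotic branch balancing ATP).
    """

    topology: str = "chain"
    uptake_bound: float = 10.0
    biomass_yield: float = 0.5
    include_ngam: bool = False
    ngam: float = 1.9


def make_toy_model(spec: ToyModelSpec) -> tuple[MetabolicModel, FluxSolution]:
    """Build the network and its hand-derived optimal FBA/pFBA solution."""
    builders = {
        "chain": _toy_chain,
        "chain_detour": _toy_chain_detour,
        "dual_substrate": _toy_dual_substrate,
        "branched_tca": _toy_branched_tca,
    }
    try:
        return builders[spec.topology](spec)
    except KeyError:
        raise ValueError(
            f"unknown topology {spec.topology!r}; choose from {sorted(builders)}"
        ) from None


def _solution(fluxes: dict[str, float], objective_id: str) -> FluxSolution:
    return FluxSolution(
        status="optimal",
        objective_value=fluxes[objective_id],
        fluxes=fluxes,
        total_abs_flux=sum(abs(v) for v in fluxes.values()),
    )


def _toy_chain(spec: ToyModelSpec) -> tuple[MetabolicModel, FluxSolution]:
    u, y = spec.uptake_bound, spec.biomass_yield
    model = MetabolicModel(
        id="toy_chain",
        metabolites=[Metabolite("A", compartment="c")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, lb=-u, ub=0.0, is_exchange=True),
            Reaction("BIOMASS", {"A": -1.0 / y}, lb=0.0, ub=1000.0),
        ],
        objective_id="BIOMASS",
    )
    known = _solution({"EX_A": -u, "BIOMASS": y * u}, "BIOMASS")
    return model, known


def _toy_chain_detour(spec: ToyModelSpec) -> tuple[MetabolicModel, FluxSolution]:
    u, y = spec.uptake_bound, spec.biomass_yield
    model = MetabolicModel(
        id="toy_chain_detour",
        metabolites=[Metabolite(m, compartment="c") for m in ("A", "B", "C")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, lb=-u, ub=0.0, is_exchange=True),
            Reaction("R_DIRECT", {"A": -1.0, "B": 1.0}, lb=0.0, ub=1000.0),
            Reaction("R_DETOUR1", {"A": -1.0, "C": 1.0}, lb=0.0, ub=1000.0),
            Reaction("R_DETOUR2", {"C": -1.0, "B": 1.0}, lb=0.0, ub=1000.0),
            Reaction("BIOMASS", {"B": -1.0 / y}, lb=0.0, ub=1000.0),
        ],
        objective_id="BIOMASS",
    )
    # same yield on both routes; parsimony puts all flux on the direct one
    known = _solution(
        {"EX_A": -u, "R_DIRECT": u, "R_DETOUR1": 0.0, "R_DETOUR2": 0.0, "BIOMASS": y * u},
        "BIOMASS",
    )
    return model, known


def _toy_dual_substrate(spec: ToyModelSpec) -> tuple[MetabolicModel, FluxSolution]:
    """Two carbon sources with different ATP yields, an overflow valve and NGAM.

    Glucose catabolism yields 1 ATP per precursor, the glutamate route
    (TCA-like) 2; biomass consumes one precursor and one ATP.  With both
    uptakes at bound u the precursor supply (2u) limits growth as long as
    the ATP balance (3u − growth − maintenance) stays non-negative, so the
    optimum is growth = 2u with maintenance flux absorbing the surplus.
    """
    u = spec.uptake_bound
    ngam_lb = spec.ngam if spec.include_ngam else 0.0
    model = MetabolicModel(
        id="toy_dual_substrate",
        metabolites=[Metabolite(m, compartment="c") for m in ("GLC", "GLU", "PREC", "ATP", "ACE")],
        reactions=[
            Reaction("EX_glc", {"GLC": -1.0}, lb=-u, ub=0.0, is_exchange=True),
            Reaction("EX_glu", {"GLU": -1.0}, lb=-u, ub=0.0, is_exchange=True),
            Reaction("CAT_GLC", {"GLC": -1.0, "PREC": 1.0, "ATP": 1.0}, lb=0.0, ub=1000.0),
            Reaction("CAT_GLU", {"GLU": -1.0, "PREC": 1.0, "ATP": 2.0}, lb=0.0, ub=1000.0),
            Reaction("OVERFLOW", {"PREC": -1.0, "ACE": 1.0}, lb=0.0, ub=1000.0),
            Reaction("EX_ace", {"ACE": -1.0}, lb=0.0, ub=1000.0, is_exchange=True),
            Reaction("ATPM", {"ATP": -1.0}, lb=ngam_lb, ub=1000.0),
            Reaction("BIOMASS", {"PREC": -1.0, "ATP": -1.0}, lb=0.0, ub=1000.0),
        ],
        objective_id="BIOMASS",
        ngam_id="ATPM",
    )
    growth = 2.0 * u  # precursor-limited; ATP surplus u >= ngam for u >= 1.9
    if u < ngam_lb:
        raise ValueError("uptake bound too small to satisfy maintenance in known solution")
    known = _solution(
        {
            "EX_glc": -u,
            "EX_glu": -u,
            "CAT_GLC": u,
            "CAT_GLU": u,
            "OVERFLOW": 0.0,
            "EX_ace": 0.0,
            "ATPM": u,  # 3u ATP made, 2u consumed by biomass
            "BIOMASS": growth,
        },
        "BIOMASS",
    )
    return model, known


def _toy_branched_tca(spec: ToyModelSpec) -> tuple[MetabolicModel, FluxSolution]:
    """Glutamate-fed cycle with a cataplerotic branch.

    Uptake u is deaminated to AKG and oxidized to OAA (+2 ATP); OAA either
    enters biomass (costing 3 ATP) or is drained cataplerotically (+1 ATP).
    With growth g and cataplerotic flux c: g + c = u (OAA balance) and the
    ATP balance 2u + c − 3g = maintenance >= m gives, at the optimum,
    c = (u + m)/4 and g = (3u − m)/4.
    """
    u = spec.uptake_bound
    m = spec.ngam if spec.include_ngam else 0.0
    model = MetabolicModel(
        id="toy_branched_tca",
        metabolites=[Metabolite(x, compartment="c") for x in ("GLU", "AKG", "OAA", "ATP")],
        reactions=[
            Reaction("EX_glu", {"GLU": -1.0}, lb=-u, ub=0.0, is_exchange=True),
            Reaction("GDH", {"GLU": -1.0, "AKG": 1.0}, lb=0.0, ub=1000.0),
            Reaction("TCA", {"AKG": -1.0, "OAA": 1.0, "ATP": 2.0}, lb=0.0, ub=1000.0),
            Reaction("CATA", {"OAA": -1.0, "ATP": 1.0}, lb=0.0, ub=1000.0),
            Reaction("ATPM", {"ATP": -1.0}, lb=m, ub=1000.0),
            Reaction("BIOMASS", {"OAA": -1.0, "ATP": -3.0}, lb=0.0, ub=1000.0),
        ],
        objective_id="BIOMASS",
        ngam_id="ATPM",
    )
    cata = (u + m) / 4.0
    growth = (3.0 * u - m) / 4.0
    if growth < 0:
        raise ValueError("maintenance exceeds the network's capacity")
    atpm = 2.0 * u + cata - 3.0 * growth  # equals m by construction
    known = _solution(
        {
            "EX_glu": -u,
            "GDH": u,
            "TCA": u,
            "CATA": cata,
            "ATPM": atpm,
            "BIOMASS": growth,
        },
        "BIOMASS",
    )
    return model, known


# ---------------------------------------------------------------------------
# planted-truth gene tables
# ---------------------------------------------------------------------------

_ARCOG_CLASSES = list("CEGIJKLMOPRST")


def simulate_de_table(
    n_genes: int = 2000,
    n_true: int = 50,
    effect: float = 2.0,
    *,
    null_lfc_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene statistics with planted differential expression.

    Null genes draw p ~ Uniform(0, 1) and log2FC ~ Normal(0, null_lfc_sd);
    planted positives draw p ~ 10^-Uniform(6, 12) with |log2FC| >= effect and
    a random sign.  The ``is_true_de`` column carries the planted truth.
    """
    if n_true > n_genes:
        raise ValueError("n_true cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.0, 1.0, size=n_genes)
    lfc = rng.normal(0.0, null_lfc_sd, size=n_genes)
    truth = np.zeros(n_genes, dtype=bool)
    idx = rng.choice(n_genes, size=n_true, replace=False)
    truth[idx] = True
    p[idx] = 10.0 ** (-rng.uniform(6.0, 12.0, size=n_true))
    signs = rng.choice([-1.0, 1.0], size=n_true)
    lfc[idx] = signs * (effect + np.abs(rng.normal(0.0, 0.5, size=n_true)))
    return pd.DataFrame(
        {
            "gene_id": [f"saci_{i:04d}" for i in range(n_genes)],
            "log2fc": lfc,
            "pvalue": p,
            "arcog": rng.choice(_ARCOG_CLASSES, size=n_genes),
            "is_true_de": truth,
        }
    )


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------

def preset_names() -> list[str]:
    root = resources.files("chemoflux").joinpath("presets")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def scenario_from_yaml(path) -> ChemostatScenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _scenario_from_dict(raw)


def _scenario_from_dict(raw: dict) -> ChemostatScenario:
    raw = dict(raw)
    for key in ("grid",):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ChemostatScenario(**raw)


def load_preset(name: str, *, seed: int | None = None) -> ChemostatScenario:
    """Load one of the shipped scenario presets (``low``, ``high``, ``overfeed``)."""
    ref = resources.files("chemoflux").joinpath(f"presets/{name}.yaml")
    try:
        raw = yaml.safe_load(ref.read_text())
    except FileNotFoundError:
        raise ValueError(f"no preset {name!r}; available: {preset_names()}") from None
    scenario = _scenario_from_dict(raw)
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    return scenario
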