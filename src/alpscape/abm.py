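"""Annual agent-based simulation of farm land-use decisions.

Each farm reviews, once a year, whether its workload stays below 1,800
hr/year and whether its income exceeds both an absolute floor of 20,000
€/year and the mean income of farms of the same type. The outcome of this
evaluation, together with farming type (cash crop / processing / livestock)
and farming style (traditionalist, yield optimizer, support optimizer,
idealist, innovative), sets the probabilities with which the farm picks one
of ten actions for the next year: keep everything, change the intensity of
cropland or grassland, convert between cropland and grassland, adopt energy
crops, expand via the rental market, or shrink/terminate. Abandoned parcels
enter a rental market; parcels that stay uncultivated for five consecutive
years leave agriculture for good and undergo succession to scrub and, after
a configurable lag, to forest.

Economic consequences (income, workload) are computed from exogenous
scenario timelines of gross margins, labour requirements and area subsidies
per activity, and feed the next year's evaluation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import landuse as lu
from .rasters import CELL_AREA_HA, GridGeometry

logger = logging.getLogger(__name__)

FARM_TYPES = ("cash crop", "processing", "livestock")
STYLES = (
    "traditionalist",
    "yield optimizer",
    "support optimizer",
    "idealist",
    "innovative",
)

ACTIONS = (
    "no_change",
    "intensify_cropland",
    "extensify_cropland",
    "intensify_grassland",
    "extensify_grassland",
    "convert_cropland_to_grassland",
    "convert_grassland_to_cropland",
    "adopt_energy_crops",
    "expand",
    "shrink_or_terminate",
)

PARK = -1  # passive owner id for national-park / no-use parcels

WORKLOAD_CAP = 1800.0  # hr/year
INCOME_FLOOR = 20000.0  # €/year


@dataclass
class Parcel:
    id: int
    cells: np.ndarray  # flat indices into the 25 m grid
    landuse: int
    owner: Optional[int]  # farm id, PARK, or None when on market/retired
    tenure: str = "owned"  # owned | rented | market | retired
    fallow: int = 0
    retired_year: Optional[int] = None
    forested: bool = False

    @property
    def area_ha(self) -> float:
        return len(self.cells) * CELL_AREA_HA


@dataclass
class Farm:
    id: int
    ftype: str
    intensity: int  # 1 (low input) .. 5 (intense production)
    style: str
    owned: List[int] = field(default_factory=list)
    rented: List[int] = field(default_factory=list)
    active: bool = True
    income: float = 0.0
    workload: float = 0.0

    @property
    def holdings(self) -> List[int]:
        return self.owned + self.rented


@dataclass(frozen=True)
class EvaluationState:
    workload_ok: bool
    income_ok: bool


class ScenarioTimeline:
    """Exogenous per-year, per-activity economics.

    Arrays are indexed ``[year, class_code]`` (code used directly, column 0
    unused). ``margin`` is the standard gross margin €/ha, ``labour`` the
    labour requirement hr/ha and ``subsidy`` the area subsidy €/ha.
    """

    def __init__(self, name: str, margin: np.ndarray, labour: np.ndarray,
                 subsidy: np.ndarray):
        if (labour < 0).any():
            raise ValueError("labour requirements must be non-negative")
        if not (margin.shape == labour.shape == subsidy.shape):
            raise ValueError("timeline arrays must share a shape")
        self.name = name
        self.margin = margin
        self.labour = labour
        self.subsidy = subsidy

    @property
    def n_years(self) -> int:
        return self.margin.shape[0]


# base per-hectare economics of farm activities (€/ha, hr/ha, €/ha); the
# scenario timelines scale these with multiplier paths
BASE_ECONOMICS: Dict[int, Tuple[float, float, float]] = {
    1: (300.0, 25.0, 350.0),
    2: (1100.0, 55.0, 300.0),
    3: (650.0, 40.0, 450.0),
    4: (1250.0, 50.0, 280.0),
    5: (900.0, 50.0, 300.0),
    6: (1300.0, 60.0, 300.0),
    7: (700.0, 45.0, 450.0),
    10: (500.0, 45.0, 450.0),
    11: (450.0, 35.0, 420.0),
    12: (950.0, 75.0, 250.0),
    13: (1000.0, 80.0, 250.0),
}

LOW_INPUT_CLASSES = (1, 3, 7, 10, 11)


def default_timeline(scenario: str, n_years: int) -> ScenarioTimeline:
    """Build the default BAU / SSP1 / SSP5 economics timeline.

    BAU keeps current conditions; SSP1 (sustainability-oriented) shifts
    subsidies towards low-input activities and energy crops while intensive
    margins erode; SSP5 (unconstrained growth) raises margins of intensive
    production and cuts area subsidies. Endpoint multipliers are reached
    linearly over the horizon. The numbers are illustrative defaults, not a
    calibration.
    """
    if scenario not in ("BAU", "SSP1", "SSP5"):
        raise ValueError(f"unknown scenario {scenario!r}")
    years = n_years + 1
    margin = np.zeros((years, lu.N_CLASSES + 1))
    labour = np.zeros((years, lu.N_CLASSES + 1))
    subsidy = np.zeros((years, lu.N_CLASSES + 1))
    ramp = np.linspace(0.0, 1.0, years)
    for code, (m0, l0, s0) in BASE_ECONOMICS.items():
        m_mult, s_mult = 1.0, 1.0
        if scenario == "SSP1":
            if code in LOW_INPUT_CLASSES:
                s_mult = 1.5
            else:
                s_mult, m_mult = 0.7, 0.9
            if code == lu.ENERGY_CROP:
                s_mult = 2.0
        elif scenario == "SSP5":
            s_mult = 0.5
            if code not in LOW_INPUT_CLASSES:
                m_mult = 1.4
            if code == lu.ENERGY_CROP:
                m_mult = 1.6
        margin[:, code] = m0 * (1.0 + ramp * (m_mult - 1.0))
        subsidy[:, code] = s0 * (1.0 + ramp * (s_mult - 1.0))
        labour[:, code] = l0
    return ScenarioTimeline(scenario, margin, labour, subsidy)


class DecisionTable:
    """P(action | evaluation state, farming type, farming style).

    All 4 x 3 x 5 = 60 rows must be present and sum to one.
    """

    def __init__(self, rows: Dict[tuple, np.ndarray]):
        for state in ((True, True), (True, False), (False, True), (False, False)):
            for ftype in FARM_TYPES:
                for style in STYLES:
                    key = (state, ftype, style)
                    if key not in rows:
                        raise ValueError(f"missing decision row {key}")
                    p = np.asarray(rows[key], dtype=float)
                    if p.shape != (len(ACTIONS),) or (p < 0).any():
                        raise ValueError(f"bad probability vector at {key}")
                    if abs(p.sum() - 1.0) > 1e-9:
                        raise ValueError(f"unnormalized row at {key}: sum={p.sum()}")
        self.rows = {k: np.asarray(v, float) for k, v in rows.items()}

    def row(self, state: EvaluationState, ftype: str, style: str) -> np.ndarray:
        return self.rows[((state.workload_ok, state.income_ok), ftype, style)]

    @classmethod
    def degenerate(cls, action: str = "no_change") -> "DecisionTable":
        p = np.zeros(len(ACTIONS))
        p[ACTIONS.index(action)] = 1.0
        rows = {
            ((w, i), t, s): p
            for w in (True, False)
            for i in (True, False)
            for t in FARM_TYPES
            for s in STYLES
        }
        return cls(rows)

    @classmethod
    def default(cls) -> "DecisionTable":
        """Illustrative default probabilities with the documented qualitative
        structure: satisfied farms mostly keep their system; failing the
        income test pushes towards intensification/expansion (strongly so for
        yield optimizers), failing the workload test towards extensification
        and shrinking; traditionalists inert, idealists extensify/convert to
        grassland, innovative farms favour energy crops, support optimizers
        track subsidy-rich low-input activities."""
        base = {
            (True, True): np.array([8.0, 0.2, 0.2, 0.2, 0.2, 0.1, 0.1, 0.1, 0.4, 0.1]),
            (True, False): np.array([2.0, 1.2, 0.3, 1.2, 0.3, 0.3, 0.5, 0.5, 1.5, 0.6]),
            (False, True): np.array([3.0, 0.2, 1.2, 0.2, 1.2, 0.5, 0.1, 0.2, 0.1, 1.5]),
            (False, False): np.array([1.5, 0.5, 0.8, 0.5, 0.8, 0.4, 0.3, 0.4, 0.3, 3.0]),
        }
        style_mult = {
            "traditionalist": {"no_change": 3.0},
            "yield optimizer": {
                "intensify_cropland": 3.0,
                "intensify_grassland": 3.0,
                "expand": 2.0,
            },
            "support optimizer": {
                "extensify_cropland": 2.0,
                "extensify_grassland": 2.0,
                "expand": 1.5,
            },
            "idealist": {
                "extensify_cropland": 3.0,
                "extensify_grassland": 3.0,
                "convert_cropland_to_grassland": 2.0,
            },
            "innovative": {
                "adopt_energy_crops": 4.0,
                "convert_grassland_to_cropland": 1.5,
                "convert_cropland_to_grassland": 1.5,
            },
        }
        type_mult = {
            "cash crop": {
                "intensify_grassland": 0.2,
                "extensify_grassland": 0.2,
                "convert_grassland_to_cropland": 0.3,
            },
            "livestock": {
                "intensify_cropland": 0.2,
                "extensify_cropland": 0.2,
                "adopt_energy_crops": 0.3,
                "convert_cropland_to_grassland": 0.3,
            },
            "processing": {},
        }
        rows = {}
        for state, w in base.items():
            for ftype in FARM_TYPES:
                for style in STYLES:
                    p = w.copy()
                    for act, m in style_mult[style].items():
                        p[ACTIONS.index(act)] *= m
                    for act, m in type_mult[ftype].items():
                        p[ACTIONS.index(act)] *= m
                    rows[(state, ftype, style)] = p / p.sum()
        return cls(rows)

    def to_frame(self):
        import pandas as pd

        recs = []
        for (state, ftype, style), p in sorted(self.rows.items()):
            rec = {"workload_ok": state[0], "income_ok": state[1],
                   "ftype": ftype, "style": style}
            rec.update({a: p[i] for i, a in enumerate(ACTIONS)})
            recs.append(rec)
        return pd.DataFrame(recs)

    @classmethod
    def from_frame(cls, df) -> "DecisionTable":
        rows = {}
        for _, r in df.iterrows():
            key = ((bool(r["workload_ok"]), bool(r["income_ok"])), r["ftype"], r["style"])
            rows[key] = np.array([r[a] for a in ACTIONS], float)
        return cls(rows)


@dataclass
class SimulationConfig:
    workload_cap: float = WORKLOAD_CAP
    income_floor: float = INCOME_FLOOR
    fallow_limit: int = 5  # years uncultivated before permanent retirement
    forest_lag: int = 15  # further years from scrub to forest
    conifer_elevation: float = 700.0  # parcels above this succeed to conifer
    redraw_styles: bool = True  # re-draw farming styles per replicate
    style_probs: Optional[Sequence[float]] = None  # default: uniform over STYLES


@dataclass
class SimulationState:
    """Mutable state of one simulation replicate."""

    geom: GridGeometry
    landuse: np.ndarray  # flat int array, one class code per 25 m cell
    elevation_fine: np.ndarray  # flat, metres, parent-cell elevation per 25 m cell
    farms: Dict[int, Farm]
    parcels: Dict[int, Parcel]
    market: List[int] = field(default_factory=list)
    pending: List[int] = field(default_factory=list)
    year: int = 0
    config: SimulationConfig = field(default_factory=SimulationConfig)

    def copy(self) -> "SimulationState":
        return copy.deepcopy(self)

    def landuse_map(self) -> np.ndarray:
        return self.landuse.reshape(self.geom.fine_shape)

    def check_tenure_partition(self) -> None:
        """Every parcel is farm-held, park-held, on the market or retired —
        exactly one of these."""
        held = set()
        for f in self.farms.values():
            for pid in f.holdings:
                if pid in held:
                    raise AssertionError(f"parcel {pid} held twice")
                held.add(pid)
        market = set(self.market) | set(self.pending)
        retired = {p.id for p in self.parcels.values() if p.tenure == "retired"}
        park = {p.id for p in self.parcels.values() if p.owner == PARK}
        groups = [held, market, retired, park]
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if groups[i] & groups[j]:
                    raise AssertionError("tenure sets overlap")
        if held | market | retired | park != set(self.parcels):
            raise AssertionError("tenure sets do not cover all parcels")


# -- yearly phases -------------------------------------------------------------


def compute_economics(farm: Farm, parcels: Dict[int, Parcel],
                      timeline: ScenarioTimeline, year: int) -> Tuple[float, float]:
    """income = sum area x (margin + subsidy); workload = sum area x labour."""
    if not farm.active:
        raise ValueError("economics of an inactive farm are undefined")
    income = 0.0
    workload = 0.0
    for pid in farm.holdings:
        p = parcels[pid]
        code = p.landuse
        if code in lu.FARM_CLASSES and BASE_ECONOMICS.get(code) is None:
            raise KeyError(f"activity {code} missing from timeline")
        income += p.area_ha * (timeline.margin[year, code] + timeline.subsidy[year, code])
        workload += p.area_ha * timeline.labour[year, code]
    return income, workload


def peer_mean(farms: Iterable[Farm], ftype: str) -> float:
    """Mean last-year income of active farms of a type (self included)."""
    incomes = [f.income for f in farms if f.active and f.ftype == ftype]
    if not incomes:
        logger.warning("no active farm of type %r; peer mean set to 0", ftype)
        return 0.0
    return float(np.mean(incomes))


def evaluate_farm(farm: Farm, peer_mean_income: float,
                  config: SimulationConfig = SimulationConfig()) -> EvaluationState:
    if peer_mean_income < 0:
        raise ValueError("negative peer mean income")
    workload_ok = farm.workload <= config.workload_cap
    income_ok = farm.income > config.income_floor and farm.income >= peer_mean_income
    return EvaluationState(workload_ok=workload_ok, income_ok=income_ok)


def choose_action(state: EvaluationState, farm: Farm, table: DecisionTable,
                  rng: np.random.Generator) -> str:
    p = table.row(state, farm.ftype, farm.style)
    return ACTIONS[rng.choice(len(ACTIONS), p=p)]


def _retarget_parcel(parcel: Parcel, new_code: int, landuse: np.ndarray) -> None:
    parcel.landuse = new_code
    landuse[parcel.cells] = new_code


def _apply_class_map(farm: Farm, parcels: Dict[int, Parcel], landuse: np.ndarray,
                     mapping: Dict[int, int]) -> bool:
    changed = False
    for pid in farm.holdings:
        p = parcels[pid]
        if p.landuse in mapping:
            _retarget_parcel(p, mapping[p.landuse], landuse)
            changed = True
    return changed


def apply_action(farm: Farm, action: str, state: SimulationState,
                 rng: np.random.Generator) -> bool:
    """Apply one action; returns True when the farm wants to expand.

    Intensity and conversion actions apply to all eligible parcels of the
    farm. Actions that are illegal for the current holdings resolve to
    ``no_change`` with a warning so stochastic tables stay total. Forest,
    alpine and other static classes are never produced from or converted to
    agriculture here.
    """
    parcels, landuse = state.parcels, state.landuse
    if action == "no_change":
        return False
    if action == "expand":
        return True
    if action == "shrink_or_terminate":
        holdings = farm.holdings
        if len(holdings) <= 1:
            _terminate(farm, state)
            return False
        # shrink: release the lowest-margin parcel (ties -> lowest id)
        def margin_of(pid):
            code = parcels[pid].landuse
            base = BASE_ECONOMICS.get(code, (0.0, 0.0, 0.0))
            return base[0] + base[2]

        pid = min(holdings, key=lambda q: (margin_of(q), q))
        _release_parcel(farm, pid, state)
        return False

    mapping = {
        "intensify_cropland": lu.INTENSIFY_CROPLAND,
        "extensify_cropland": lu.EXTENSIFY_CROPLAND,
        "intensify_grassland": lu.INTENSIFY_GRASSLAND,
        "extensify_grassland": lu.EXTENSIFY_GRASSLAND,
        "convert_cropland_to_grassland": lu.CROPLAND_TO_GRASSLAND,
        "convert_grassland_to_cropland": lu.GRASSLAND_TO_CROPLAND,
        "adopt_energy_crops": {c: lu.ENERGY_CROP for c in lu.CROPLAND_CLASSES if c != lu.ENERGY_CROP},
    }[action]
    if not _apply_class_map(farm, parcels, landuse, mapping):
        logger.debug("farm %d: action %s illegal for holdings; no_change", farm.id, action)
    return False


def _release_parcel(farm: Farm, pid: int, state: SimulationState) -> None:
    if pid in farm.owned:
        farm.owned.remove(pid)
    else:
        farm.rented.remove(pid)
    p = state.parcels[pid]
    p.owner = None
    p.tenure = "market"
    p.fallow = 0
    state.pending.append(pid)


def _terminate(farm: Farm, state: SimulationState) -> None:
    for pid in list(farm.holdings):
        _release_parcel(farm, pid, state)
    farm.active = False


def clear_rental_market(state: SimulationState, expanding: List[int],
                        timeline: ScenarioTimeline, year: int,
                        rng: np.random.Generator) -> Dict[int, List[int]]:
    """Offer market parcels (random order) to expanding farms (random order);
    a farm accepts parcels until its projected workload reaches the cap."""
    allocations: Dict[int, List[int]] = {}
    queue = [int(i) for i in rng.permutation(sorted(state.market))] if state.market else []
    farms_order = [int(i) for i in rng.permutation(sorted(expanding))] if expanding else []
    remaining = []
    qi = 0
    for fid in farms_order:
        farm = state.farms[fid]
        projected = farm.workload
        while qi < len(queue):
            pid = queue[qi]
            p = state.parcels[pid]
            extra = p.area_ha * timeline.labour[year, p.landuse]
            if projected + extra > state.config.workload_cap:
                break
            qi += 1
            projected += extra
            p.owner = fid
            p.tenure = "rented"
            p.fallow = 0
            farm.rented.append(pid)
            allocations.setdefault(fid, []).append(pid)
    remaining = queue[qi:]
    state.market = remaining
    return allocations


def advance_succession(state: SimulationState) -> None:
    """Increment fallow counters of uncultivated (market) parcels; retire at
    the fallow limit (cells to scrub); move long-retired parcels to forest
    by elevation band. Cultivated parcels reset to zero."""
    cfg = state.config
    still_market = []
    for pid in state.market:
        p = state.parcels[pid]
        p.fallow += 1
        if p.fallow >= cfg.fallow_limit:
            p.tenure = "retired"
            p.owner = None
            p.retired_year = state.year
            _retarget_parcel(p, lu.SCRUB_CLASS, state.landuse)
        else:
            still_market.append(pid)
    state.market = still_market
    for p in state.parcels.values():
        if p.tenure == "retired" and not p.forested:
            if state.year - p.retired_year >= cfg.forest_lag:
                elev = float(state.elevation_fine[p.cells].mean())
                target = lu.CONIFER_FOREST if elev >= cfg.conifer_elevation else lu.BROADLEAF_FOREST
                _retarget_parcel(p, target, state.landuse)
                p.forested = True
        elif p.tenure in ("owned", "rented"):
            p.fallow = 0


def step_year(state: SimulationState, timeline: ScenarioTimeline,
              table: DecisionTable, rng: np.random.Generator,
              panel: Optional[list] = None) -> SimulationState:
    """Advance the simulation by one year (mutates and returns ``state``).

    Phase order: economics -> peer means -> evaluation -> action choice ->
    action application -> rental-market clearing -> market entry of newly
    released parcels -> succession.
    """
    year = min(state.year, timeline.n_years - 1)
    active = [f for f in state.farms.values() if f.active]
    for farm in active:
        farm.income, farm.workload = compute_economics(farm, state.parcels, timeline, year)
    peers = {t: peer_mean(active, t) for t in FARM_TYPES if any(f.ftype == t for f in active)}
    expanding: List[int] = []
    for farm in sorted(active, key=lambda f: f.id):
        ev = evaluate_farm(farm, peers.get(farm.ftype, 0.0), state.config)
        action = choose_action(ev, farm, table, rng)
        if panel is not None:
            panel.append(
                {"year": state.year, "farm": farm.id, "ftype": farm.ftype,
                 "style": farm.style, "income": farm.income,
                 "workload": farm.workload, "workload_ok": ev.workload_ok,
                 "income_ok": ev.income_ok, "action": action}
            )
        if apply_action(farm, action, state, rng):
            expanding.append(farm.id)
    clear_rental_market(state, expanding, timeline, year, rng)
    state.market.extend(state.pending)
    state.pending = []
    advance_succession(state)
    state.year += 1
    return state


def run_simulation(
    initial_state: SimulationState,
    timeline: ScenarioTimeline,
    n_years: int,
    n_replicates: int,
    root_seed: int,
    table: Optional[DecisionTable] = None,
    keep_annual: bool = False,
    panel_out: Optional[list] = None,
) -> List[List[np.ndarray]]:
    """Run replicate simulations from a common initial state.

    Each replicate uses an independent seeded substream; farming styles are
    re-drawn per replicate (configurable). Returns, per replicate, the list
    of annual land-use maps (initial map first) or just ``[initial, end]``
    when ``keep_annual`` is false.
    """
    if n_years < 0 or n_replicates < 1:
        raise ValueError("need n_years >= 0 and n_replicates >= 1")
    table = table or DecisionTable.default()
    out = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([int(root_seed), r]))
        st = initial_state.copy()
        if st.config.redraw_styles:
            probs = st.config.style_probs
            for fid in sorted(st.farms):
                st.farms[fid].style = STYLES[
                    rng.choice(len(STYLES), p=probs) if probs is not None else rng.integers(len(STYLES))
                ]
        panel = [] if panel_out is not None else None
        traj = [st.landuse_map().copy()]
        for _ in range(n_years):
            step_year(st, timeline, table, rng, panel=panel)
            if keep_annual:
                traj.append(st.landuse_map().copy())
        if not keep_annual and n_years > 0:
            traj.append(st.landuse_map().copy())
        if panel_out is not None:
            for rec in panel:
                rec["replicate"] = r
            panel_out.extend(panel)
        out.append(traj)
    return out
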