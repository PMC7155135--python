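"""Synthetic landscapes, climate, farms, virtual species and plot samples.

This module generates inputs with the statistical structure the analysis
assumes, so that every downstream stage (ABM, climate downscaling, SDM
fitting, range metrics, variance partitioning) can be exercised and tested
without licensed data. The emulated region follows the study-area template:
an elevational gradient from an arable north to a high-mountain south,
forest-dominated mid elevations, and alpine habitat only above the
treeline.

All randomness flows from one root seed through named substreams, so each
generator can be re-run independently and reproducibly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from . import landuse as lu
from .abm import PARK, Farm, Parcel, SimulationConfig, SimulationState
from .climate import BIO_VARS, ClimateGrids, DeltaGrids, RCP_TMIN_DELTA
from .rasters import BLOCK, GridGeometry, broadcast_to_fine, parent_coarse_index

logger = logging.getLogger(__name__)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a root seed."""
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def _smooth_noise(rng: np.random.Generator, shape: Tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    sd = z.std()
    return z / sd if sd > 0 else z


# ---------------------------------------------------------------------------
# landscape


@dataclass
class LandscapeConfig:
    rows: int = 120  # 25 m cells
    cols: int = 120
    base_elevation: float = 400.0  # valley floor, m
    relief: float = 1500.0  # north-south elevation span, m
    noise_relief: float = 150.0  # SD of the smoothed elevation noise, m
    smooth_sigma: float = 3.0  # autocorrelation length, 100 m cells
    treeline: float = 1600.0  # alpine classes only above this elevation
    calcareous_fraction: float = 0.55
    solar_mean: float = 1050.0  # kWh/m2
    solar_sd: float = 120.0
    mixture: Dict[int, float] = field(default_factory=lambda: dict(lu.CURRENT_SHARES))


@dataclass
class Landscape:
    """Elevation/substrate/solar at 100 m plus land use at 25 m."""

    geom: GridGeometry
    elevation: np.ndarray  # (rows/4, cols/4) metres
    substrate: np.ndarray  # (rows/4, cols/4) 0/1 calcareous presence
    solar: np.ndarray  # (rows/4, cols/4) kWh/m2
    landuse: np.ndarray  # (rows, cols) class codes 1..22

    def __post_init__(self) -> None:
        if self.elevation.shape != self.geom.coarse_shape:
            raise ValueError("elevation shape does not match geometry")
        if self.landuse.shape != self.geom.fine_shape:
            raise ValueError("land-use shape does not match geometry")
        if (self.elevation < 0).any():
            raise ValueError("negative elevation")
        codes = np.unique(self.landuse)
        if codes.min() < 1 or codes.max() > lu.N_CLASSES:
            raise ValueError("land-use codes outside 1..22")

    @property
    def elevation_fine(self) -> np.ndarray:
        return broadcast_to_fine(self.elevation)

    def class_shares(self) -> Dict[int, float]:
        vals, counts = np.unique(self.landuse, return_counts=True)
        total = self.landuse.size
        return {int(v): 100.0 * c / total for v, c in zip(vals, counts)}


def generate_landscape(config: LandscapeConfig, seed: int) -> Landscape:
    """Generate a landscape whose class shares approximate the mixture.

    Elevation is a monotone north(top)-south(bottom) ramp plus smoothed
    noise. Habitat groups are placed by elevation band: agricultural classes
    occupy the lowest cells, alpine classes the highest (above the
    treeline), grasslands and forests share the middle; within a band,
    classes are drawn from the renormalized mixture weights.
    """
    mixture = {c: w for c, w in config.mixture.items() if w > 0}
    if not mixture:
        raise ValueError("mixture weights are all zero")
    if any(w < 0 for w in config.mixture.values()):
        raise ValueError("negative mixture weight")
    geom = GridGeometry(rows=config.rows, cols=config.cols)
    rng = substream(seed, "landscape")
    cr, cc = geom.coarse_shape
    ramp = np.linspace(0.0, 1.0, cr)[:, None] * np.ones((1, cc))
    elev = (
        config.base_elevation
        + config.relief * ramp
        + config.noise_relief * _smooth_noise(rng, (cr, cc), config.smooth_sigma)
    )
    elev = np.maximum(elev, 0.0)

    # calcareous presence: threshold a smoothed field at the requested fraction
    calc_field = _smooth_noise(rng, (cr, cc), config.smooth_sigma)
    substrate = (calc_field < np.quantile(calc_field, config.calcareous_fraction)).astype(np.int8)

    solar = config.solar_mean + config.solar_sd * _smooth_noise(
        rng, (cr, cc), config.smooth_sigma / 2
    )

    total = sum(mixture.values())
    shares = {c: w / total for c, w in mixture.items()}
    groups = {g: [c for c in shares if lu.HABITAT_GROUP_LOOKUP[c] == g] for g in lu.HABITAT_GROUPS}
    w_agri = sum(shares[c] for c in groups[lu.AGRICULTURAL])
    w_alp = sum(shares[c] for c in groups[lu.ALPINE])

    elev_fine = broadcast_to_fine(elev).ravel()
    # stable elevation order with a seeded jitter to break block ties
    order_key = elev_fine + rng.random(elev_fine.size) * 1e-6
    order = np.argsort(order_key, kind="stable")
    n = elev_fine.size
    n_agri = int(round(w_agri * n))
    n_alp = int(round(w_alp * n))
    landuse = np.empty(n, dtype=np.int32)

    def _fill(cells: np.ndarray, codes: List[int]) -> None:
        if len(cells) == 0:
            return
        w = np.array([shares[c] for c in codes], float)
        w /= w.sum()
        landuse[cells] = rng.choice(codes, size=len(cells), p=w)

    agri_cells = order[:n_agri]
    alp_candidates = order[n - n_alp:] if n_alp else np.empty(0, dtype=int)
    # alpine only above the treeline; lower candidates fall back to the middle
    above = alp_candidates[elev_fine[alp_candidates] > config.treeline]
    below = alp_candidates[elev_fine[alp_candidates] <= config.treeline]
    mid_cells = np.concatenate([order[n_agri:n - n_alp], below]) if n_alp else order[n_agri:]
    mid_codes = groups[lu.GRASSLANDS] + groups[lu.FORESTS]
    _fill(agri_cells, groups[lu.AGRICULTURAL] or list(shares))
    _fill(above, groups[lu.ALPINE])
    if mid_codes:
        _fill(mid_cells, mid_codes)
    else:  # degenerate mixtures (e.g. all weight on one class)
        _fill(mid_cells, list(shares))
    return Landscape(
        geom=geom,
        elevation=elev,
        substrate=substrate,
        solar=solar,
        landuse=landuse.reshape(geom.fine_shape),
    )


# ---------------------------------------------------------------------------
# climate


@dataclass
class ClimateConfig:
    lapse_rate: float = 0.0055  # °C per m of elevation (cooling upward)
    tmean_base: float = 8.5  # annual mean at the reference elevation, °C
    seasonal_amplitude: float = 9.0  # half-range of the annual cycle, °C
    reference_elevation: float = 400.0
    diurnal_base: float = 4.0  # half of the daily temperature range, °C
    diurnal_sd: float = 0.8  # spatial SD of the diurnal range field
    temp_noise_sd: float = 0.4  # spatial SD of the temperature offset field
    prec_base: float = 110.0  # mean monthly precipitation at reference, mm
    prec_orographic: float = 0.02  # mm per m of elevation per month
    prec_season_amp: float = 0.30  # mean relative summer surplus
    prec_season_sd: float = 0.15  # spatial SD of the seasonality field
    prec_level_sd: float = 0.18  # spatial SD of the (log) precipitation level
    prec_noise_cv: float = 0.08  # multiplicative monthly noise
    smooth_sigma: float = 3.0


def generate_climate(landscape: Landscape, lapse_rate: Optional[float] = None,
                     seed: int = 0, config: Optional[ClimateConfig] = None) -> ClimateGrids:
    """Current monthly climate on the 100 m grid.

    Temperature cools with elevation at the configured lapse rate; the
    annual-range field and the precipitation-seasonality field vary on
    independent smoothed noise, which keeps the pairwise correlations of the
    four derived bioclim predictors below 0.75.
    """
    cfg = config or ClimateConfig()
    if lapse_rate is not None:
        cfg = ClimateConfig(**{**cfg.__dict__, "lapse_rate": lapse_rate})
    if cfg.lapse_rate < 0:
        raise ValueError("lapse rate must be positive (cooling with elevation)")
    rng = substream(seed, "climate")
    shape = landscape.geom.coarse_shape
    elev = landscape.elevation
    months = np.arange(12)
    season = -np.cos(2.0 * np.pi * months / 12.0)  # -1 in January, +1 in July

    t_offset = cfg.temp_noise_sd * _smooth_noise(rng, shape, cfg.smooth_sigma)
    diurnal = np.maximum(
        cfg.diurnal_base + cfg.diurnal_sd * _smooth_noise(rng, shape, cfg.smooth_sigma), 0.5
    )
    tmean = np.stack([
        cfg.tmean_base
        + cfg.seasonal_amplitude * season[m]
        - cfg.lapse_rate * (elev - cfg.reference_elevation)
        + t_offset
        for m in range(12)
    ])
    dr_month = 1.0 + 0.15 * season  # slightly wider daily range in summer
    tmin = tmean - dr_month[:, None, None] * diurnal
    tmax = tmean + dr_month[:, None, None] * diurnal

    season_field = np.clip(
        cfg.prec_season_amp + cfg.prec_season_sd * _smooth_noise(rng, shape, cfg.smooth_sigma),
        0.0, 0.9,
    )
    # a month-invariant level field moves SD and mean together, so it shifts
    # BIO18 without moving the seasonality index BIO15
    level = np.exp(
        cfg.prec_level_sd * _smooth_noise(rng, shape, cfg.smooth_sigma)
        - 0.5 * cfg.prec_level_sd**2
    )
    base = (
        cfg.prec_base + cfg.prec_orographic * (elev - cfg.reference_elevation)
    ) * level
    prec = np.stack([
        np.maximum(
            (base * (1.0 + season_field * season[m]))
            * np.exp(cfg.prec_noise_cv * rng.standard_normal(shape) - 0.5 * cfg.prec_noise_cv**2),
            0.0,
        )
        for m in range(12)
    ])
    return ClimateGrids(tmin=tmin, tmean=tmean, tmax=tmax, prec=prec, period="current")


def generate_scenario_deltas(
    rcp: str,
    coarse_shape: Tuple[int, int] = (6, 6),
    seed: int = 0,
    spatial_amplitude: float = 0.2,
    prec_change: float = -5.0,
) -> DeltaGrids:
    """Coarse-grid monthly anomalies for one climate scenario.

    The coldest-month tmin shift equals the scenario's headline value (+2.4,
    +3.0, +3.8 °C for RCP2.6/4.5/8.5); other months and variables shift by
    similar magnitudes, with a gentle seeded spatial pattern of amplitude
    ``spatial_amplitude`` (°C) and a small summer precipitation change.
    """
    if rcp not in RCP_TMIN_DELTA:
        raise ValueError(f"unknown climate scenario {rcp!r}")
    base = RCP_TMIN_DELTA[rcp]
    rng = substream(seed, f"deltas:{rcp}")
    months = np.arange(12)
    # exactly the headline shift in January (the coldest month); summer
    # months warm somewhat less
    seasonal = 1.0 + 0.1 * (np.cos(2.0 * np.pi * months / 12.0) - 1.0)
    pattern = spatial_amplitude * _smooth_noise(rng, coarse_shape, 1.0) if spatial_amplitude else np.zeros(coarse_shape)
    temp = np.stack([base * seasonal[m] + pattern for m in range(12)])
    p_season = -np.cos(2.0 * np.pi * months / 12.0)  # summer drying by default
    prec = np.stack([prec_change * max(p_season[m], 0.0) + 0.0 * pattern for m in range(12)])
    return DeltaGrids(tmin=temp, tmean=temp.copy(), tmax=temp.copy(), prec=prec, label=rcp)


# ---------------------------------------------------------------------------
# farms


def generate_farms(
    landscape: Landscape,
    n_farms: int,
    seed: int,
    park_fraction: float = 0.10,
    style_probs: Optional[Sequence[float]] = None,
    config: Optional[SimulationConfig] = None,
) -> SimulationState:
    """Partition agricultural/grassland cells into parcels and farms.

    Parcels are the maximal sets of same-class 25 m cells within one 100 m
    cell. A random ``park_fraction`` of parcels goes to the passive
    national-park pool; the rest is split among ``n_farms`` spatially
    coherent farms (nearest seed parcel). Farming type follows the farm's
    sector mix, the intensity level its share of intensive classes, and the
    style is drawn from ``style_probs`` (uniform by default).
    """
    from .abm import FARM_TYPES, STYLES  # local to avoid circularity at import

    if n_farms < 1:
        raise ValueError("n_farms must be >= 1")
    rng = substream(seed, "farms")
    geom = landscape.geom
    flat_lu = landscape.landuse.ravel()
    parent = parent_coarse_index(geom).ravel()
    farm_mask = np.isin(flat_lu, lu.FARM_CLASSES)
    cells = np.flatnonzero(farm_mask)
    if cells.size == 0:
        raise ValueError("landscape has no agricultural or grassland cells")

    # parcels: group farm cells by (parent 100 m cell, class)
    keys = parent[cells].astype(np.int64) * 100 + flat_lu[cells]
    order = np.argsort(keys, kind="stable")
    cells_sorted = cells[order]
    keys_sorted = keys[order]
    boundaries = np.flatnonzero(np.diff(keys_sorted)) + 1
    groups = np.split(cells_sorted, boundaries)
    parcels: Dict[int, Parcel] = {}
    for pid, grp in enumerate(groups):
        parcels[pid] = Parcel(
            id=pid, cells=grp, landuse=int(flat_lu[grp[0]]), owner=None, tenure="owned"
        )
    n_parcels = len(parcels)
    n_park = int(round(park_fraction * n_parcels))
    if n_farms > n_parcels - n_park:
        raise ValueError(
            f"n_farms={n_farms} exceeds the {n_parcels - n_park} available parcels"
        )
    ids = rng.permutation(n_parcels)
    park_ids, farm_parcel_ids = ids[:n_park], ids[n_park:]
    for pid in park_ids:
        parcels[int(pid)].owner = PARK

    # parcel centroids (coarse row/col) for spatially coherent assignment
    cshape = geom.coarse_shape
    centroids = np.array(
        [
            [
                (parent[parcels[int(p)].cells[0]] // cshape[1]),
                (parent[parcels[int(p)].cells[0]] % cshape[1]),
            ]
            for p in farm_parcel_ids
        ],
        dtype=float,
    )
    seed_idx = rng.choice(len(farm_parcel_ids), size=n_farms, replace=False)
    seed_xy = centroids[seed_idx]
    d2 = ((centroids[:, None, :] - seed_xy[None, :, :]) ** 2).sum(-1)
    assignment = d2.argmin(axis=1)
    # make sure each farm holds at least its seed parcel
    assignment[seed_idx] = np.arange(n_farms)

    farms: Dict[int, Farm] = {}
    for fid in range(n_farms):
        held = [int(farm_parcel_ids[i]) for i in np.flatnonzero(assignment == fid)]
        crop = sum(len(parcels[p].cells) for p in held if parcels[p].landuse in lu.CROPLAND_CLASSES)
        grass = sum(len(parcels[p].cells) for p in held if parcels[p].landuse in lu.GRASSLAND_FARM_CLASSES)
        total = max(crop + grass, 1)
        if crop / total > 0.7:
            ftype = "cash crop"
        elif grass / total > 0.7:
            ftype = "livestock"
        else:
            ftype = "processing"
        intensive = sum(
            len(parcels[p].cells) for p in held if parcels[p].landuse in lu.INTENSIVE_CLASSES
        )
        intensity = 1 + int(round(4 * intensive / total))
        style = STYLES[
            rng.choice(len(STYLES), p=style_probs) if style_probs is not None else rng.integers(len(STYLES))
        ]
        for p in held:
            parcels[p].owner = fid
        farms[fid] = Farm(id=fid, ftype=ftype, intensity=intensity, style=style, owned=held)

    cfg = config or SimulationConfig()
    if style_probs is not None:
        cfg.style_probs = list(style_probs)
    return SimulationState(
        geom=geom,
        landuse=flat_lu.copy(),
        elevation_fine=landscape.elevation_fine.ravel(),
        farms=farms,
        parcels=parcels,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# virtual species


@dataclass
class SpeciesNiche:
    """Virtual-species response: independent Gaussian climate responses times
    a categorical land-use affinity and a substrate factor.

    The continuous suitability product is converted to a presence
    probability through a steep logistic (midpoint/slope below), the usual
    virtual-species device that keeps niches crisp enough for a distribution
    model to recover them while preserving an analytic truth map
    (suitability >= midpoint)."""

    species_id: str
    bio_optimum: Dict[str, float]
    bio_breadth: Dict[str, float]
    affinity: np.ndarray  # length 22, values in [0, 1]
    substrate_pref: str = "none"  # calcareous | siliceous | none
    prevalence: float = 0.95
    logistic_midpoint: float = 0.40  # suitability at which P(presence) = prevalence/2
    logistic_slope: float = 0.05
    planted_group: Optional[str] = None  # habitat group for planted specialists
    climate_dominant: bool = False

    def __post_init__(self) -> None:
        self.affinity = np.asarray(self.affinity, float)
        if self.affinity.shape != (lu.N_CLASSES,):
            raise ValueError("affinity vector must have length 22")
        if not (self.affinity > 0).any():
            raise ValueError("affinity vector needs at least one positive entry")
        if any(b <= 0 for b in self.bio_breadth.values()):
            raise ValueError("climate breadths must be positive")

    def climate_suitability(self, bio: Dict[str, np.ndarray]) -> np.ndarray:
        s = 1.0
        for var in BIO_VARS:
            z = (np.asarray(bio[var], float) - self.bio_optimum[var]) / self.bio_breadth[var]
            s = s * np.exp(-0.5 * z * z)
        return s

    def suitability(self, bio: Dict[str, np.ndarray], landuse_codes: np.ndarray,
                    substrate: np.ndarray) -> np.ndarray:
        """Continuous suitability in [0, 1] (climate x land use x substrate)."""
        s = self.climate_suitability(bio) * self.affinity[np.asarray(landuse_codes) - 1]
        if self.substrate_pref == "calcareous":
            s = s * np.where(np.asarray(substrate) > 0, 1.0, 0.25)
        elif self.substrate_pref == "siliceous":
            s = s * np.where(np.asarray(substrate) > 0, 0.25, 1.0)
        return np.clip(s, 0.0, 1.0)

    def presence_probability(self, bio: Dict[str, np.ndarray], landuse_codes: np.ndarray,
                             substrate: np.ndarray) -> np.ndarray:
        s = self.suitability(bio, landuse_codes, substrate)
        logistic = 1.0 / (1.0 + np.exp(-(s - self.logistic_midpoint) / self.logistic_slope))
        return self.prevalence * logistic


@dataclass
class SpeciesPoolConfig:
    bio6_range: Tuple[float, float] = (-12.5, -3.0)  # span of BIO6 under the default climate
    narrow_bio6: Tuple[float, float] = (0.8, 1.5)  # climate-dominant breadth, °C
    wide_bio6: Tuple[float, float] = (4.0, 8.0)
    wide_breadths: Dict[str, float] = field(
        default_factory=lambda: {"bio7": 8.0, "bio15": 25.0, "bio18": 250.0}
    )
    bio_typical: Dict[str, float] = field(
        default_factory=lambda: {"bio7": 26.0, "bio15": 28.0, "bio18": 380.0}
    )
    specialist_mass: float = 0.90  # affinity mass inside the planted group
    prevalence: float = 0.95
    substrate_sensitive_fraction: float = 0.3


def pool_config_for_climate(climate: ClimateGrids, **overrides) -> SpeciesPoolConfig:
    """Pool configuration anchored to a generated climate: niche optima are
    placed relative to the region's actual BIO6 span (and typical values of
    the other bioclim variables), so cold-edge and warm-edge species end up
    where the construction intends regardless of relief or seed."""
    bio = climate.bio()
    cfg = SpeciesPoolConfig(
        bio6_range=(float(bio["bio6"].min()), float(bio["bio6"].max())),
        bio_typical={
            "bio7": float(np.median(bio["bio7"])),
            "bio15": float(np.median(bio["bio15"])),
            "bio18": float(np.median(bio["bio18"])),
        },
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def generate_species_pool(
    n_species: int,
    specialist_fractions: Optional[Dict[str, float]] = None,
    seed: int = 0,
    climate_dominant_fraction: float = 0.5,
    config: Optional[SpeciesPoolConfig] = None,
) -> List[SpeciesNiche]:
    """Generate virtual species niches.

    ``specialist_fractions`` maps habitat groups to the fraction of species
    planted as specialists of that group (>= ``specialist_mass`` of affinity
    inside the group); the remainder are generalists. A
    ``climate_dominant_fraction`` of species gets a narrow BIO6 response
    (climate-limited); the rest get wide climate responses with contrasting
    land-use affinities (land-use-limited). Alpine specialists receive cold
    BIO6 optima; agricultural and grassland specialists warm ones, so
    warming scenarios displace them in opposite directions.
    """
    cfg = config or SpeciesPoolConfig()
    fractions = dict(specialist_fractions or {})
    if any(f < 0 for f in fractions.values()) or sum(fractions.values()) > 1 + 1e-9:
        raise ValueError("specialist fractions must be >= 0 and sum to <= 1")
    rng = substream(seed, "species")
    counts = {g: int(round(f * n_species)) for g, f in fractions.items()}
    while sum(counts.values()) > n_species:
        g = max(counts, key=counts.get)
        counts[g] -= 1
    planted: List[Optional[str]] = []
    for g, k in counts.items():
        planted.extend([g] * k)
    planted.extend([None] * (n_species - len(planted)))

    lo6, hi6 = cfg.bio6_range
    pool: List[SpeciesNiche] = []
    for i, group in enumerate(planted):
        climate_dom = rng.random() < climate_dominant_fraction
        if group == lu.ALPINE:
            # optimum at the region's cold edge: the warm-side decline of the
            # response is then visible inside today's alpine belt, and any
            # regional warming moves every cell away from the optimum
            opt6 = rng.uniform(lo6, lo6 + 0.5)
        elif group in (lu.AGRICULTURAL, lu.GRASSLANDS):
            # warm-adapted: optimum at or beyond today's warm edge, so
            # warming moves the lowlands towards (never past) the optimum
            opt6 = rng.uniform(hi6, hi6 + 2.0)
        else:
            opt6 = rng.uniform(lo6, hi6)
        breadth6 = rng.uniform(*(cfg.narrow_bio6 if climate_dom else cfg.wide_bio6))
        if climate_dom and group == lu.ALPINE:
            # narrow enough that the cold-edge response is visible within
            # today's alpine belt, far narrower than a scenario-scale warming
            breadth6 = rng.uniform(1.0, 1.5)
        elif climate_dom and group in (lu.AGRICULTURAL, lu.GRASSLANDS):
            # broad enough that warm-adapted species are widespread today
            breadth6 = rng.uniform(1.8, 2.8)
        optimum = {"bio6": float(opt6)}
        breadth = {"bio6": float(breadth6)}
        for var in ("bio7", "bio15", "bio18"):
            optimum[var] = cfg.bio_typical[var] * rng.uniform(0.9, 1.1)
            breadth[var] = cfg.wide_breadths[var]

        affinity = np.zeros(lu.N_CLASSES)
        if group is not None:
            in_codes = [c - 1 for c in lu.ALL_CODES if lu.HABITAT_GROUP_LOOKUP[c] == group]
            out_codes = [c for c in range(lu.N_CLASSES) if c not in in_codes]
            affinity[in_codes] = rng.uniform(0.7, 1.0, len(in_codes))
            affinity[out_codes] = rng.uniform(0.0, 0.15, len(out_codes))
            # rescale spill-over so the planted mass fraction holds exactly
            m_in = affinity[in_codes].sum()
            m_out = affinity[out_codes].sum()
            target_out = m_in * (1.0 - cfg.specialist_mass) / cfg.specialist_mass
            if m_out > target_out and m_out > 0:
                affinity[out_codes] *= target_out / m_out
        elif climate_dom:
            affinity[:] = rng.uniform(0.6, 1.0, lu.N_CLASSES)  # climate decides
        else:
            # land-use-limited generalist: contrasting affinities
            on = rng.random(lu.N_CLASSES) < 0.5
            if not on.any():
                on[rng.integers(lu.N_CLASSES)] = True
            affinity[on] = rng.uniform(0.6, 1.0, on.sum())
            affinity[~on] = rng.uniform(0.0, 0.1, (~on).sum())
        if rng.random() < cfg.substrate_sensitive_fraction:
            pref = "calcareous" if rng.random() < 0.5 else "siliceous"
        else:
            pref = "none"
        pool.append(
            SpeciesNiche(
                species_id=f"sp{i:03d}",
                bio_optimum=optimum,
                bio_breadth=breadth,
                affinity=affinity,
                substrate_pref=pref,
                prevalence=cfg.prevalence,
                planted_group=group,
                climate_dominant=climate_dom,
            )
        )
    return pool


# ---------------------------------------------------------------------------
# plots


PREDICTOR_COLUMNS = ("landuse", "bio6", "bio7", "bio15", "bio18", "substrate", "solar")


@dataclass
class PlotTable:
    """Plot x (predictors, presence/absence) table for SDM fitting."""

    data: pd.DataFrame  # plot_id, cell, coarse_cell, predictors, presence cols
    species_ids: List[str]
    min_occurrences: int
    excluded: List[str]  # species below the occurrence filter

    @property
    def n_plots(self) -> int:
        return len(self.data)

    def presence(self, species_id: str) -> np.ndarray:
        return self.data[species_id].to_numpy()

    def predictors(self) -> pd.DataFrame:
        return self.data[list(PREDICTOR_COLUMNS)]

    def occurrences(self) -> pd.Series:
        return self.data[self.species_ids].sum()

    def usable_species(self) -> List[str]:
        return [s for s in self.species_ids if s not in self.excluded]


def sample_plots(
    pool: List[SpeciesNiche],
    landscape: Landscape,
    climate: ClimateGrids,
    n_plots: int,
    seed: int = 0,
    min_occurrences: int = 50,
    uniform_class_weight: float = 0.5,
) -> PlotTable:
    """Place plots on 25 m cells and draw presence/absence per species.

    Plot allocation blends area-proportional with uniform-by-class sampling
    (``uniform_class_weight``) so that rare land-use classes are represented
    — the synthetic counterpart of targeted supplementary surveying of
    under-sampled types. Presence is Bernoulli with probability given by the
    species' suitability at the plot's cell. Species with fewer than
    ``min_occurrences`` presences are flagged for exclusion.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    rng = substream(seed, "plots")
    geom = landscape.geom
    flat_lu = landscape.landuse.ravel()
    parent = parent_coarse_index(geom).ravel()
    codes, counts = np.unique(flat_lu, return_counts=True)
    prop = counts / counts.sum()
    unif = np.ones(len(codes)) / len(codes)
    alloc_w = (1 - uniform_class_weight) * prop + uniform_class_weight * unif
    alloc = np.floor(alloc_w * n_plots).astype(int)
    while alloc.sum() < n_plots:
        alloc[rng.integers(len(codes))] += 1
    chosen = []
    for code, k in zip(codes, alloc):
        if k == 0:
            continue
        cells = np.flatnonzero(flat_lu == code)
        replace = len(cells) < k
        chosen.append(rng.choice(cells, size=k, replace=replace))
    cell_idx = np.concatenate(chosen)
    rng.shuffle(cell_idx)

    bio = climate.bio()
    coarse = parent[cell_idx]
    tbl = pd.DataFrame(
        {
            "plot_id": np.arange(len(cell_idx)),
            "cell": cell_idx,
            "coarse_cell": coarse,
            "landuse": flat_lu[cell_idx].astype(int),
            "bio6": bio["bio6"].ravel()[coarse],
            "bio7": bio["bio7"].ravel()[coarse],
            "bio15": bio["bio15"].ravel()[coarse],
            "bio18": bio["bio18"].ravel()[coarse],
            "substrate": landscape.substrate.ravel()[coarse].astype(int),
            "solar": landscape.solar.ravel()[coarse],
        }
    )
    plot_bio = {v: tbl[v].to_numpy() for v in BIO_VARS}
    presence = {}
    for niche in pool:
        p = niche.presence_probability(plot_bio, tbl["landuse"].to_numpy(), tbl["substrate"].to_numpy())
        presence[niche.species_id] = (rng.random(len(tbl)) < p).astype(np.int8)
    tbl = pd.concat([tbl, pd.DataFrame(presence, index=tbl.index)], axis=1)
    occ = tbl[[n.species_id for n in pool]].sum()
    excluded = [s for s, k in occ.items() if k < min_occurrences]
    if excluded:
        logger.info("%d species below the %d-occurrence filter", len(excluded), min_occurrences)
    return PlotTable(
        data=tbl,
        species_ids=[n.species_id for n in pool],
        min_occurrences=min_occurrences,
        excluded=excluded,
    )


def truth_map(niche: SpeciesNiche, landscape: Landscape, climate: ClimateGrids,
              threshold: Optional[float] = None) -> np.ndarray:
    """The generator's own binary suitability raster for a species (25 m):
    cells whose suitability reaches the niche's logistic midpoint."""
    bio = climate.bio()
    parent = parent_coarse_index(landscape.geom).ravel()
    cell_bio = {v: bio[v].ravel()[parent] for v in BIO_VARS}
    s = niche.suitability(
        cell_bio, landscape.landuse.ravel(), landscape.substrate.ravel()[parent]
    )
    thr = niche.logistic_midpoint if threshold is None else threshold
    return (s >= thr).astype(np.int8).reshape(landscape.geom.fine_shape)
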