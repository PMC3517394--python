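"""Seeded synthetic study areas with known ground truth.

No public release of the original field data exists, so every other module
is exercised against generated inputs whose true parameters are recorded:

* a regular nx x ny grid of square census blocks (planar coordinates);
* parcels placed strictly interior to blocks, with presence/absence
  observations drawn as independent Bernoulli trials at configurable
  prevalences, optionally modulated by a smooth spatial latent field so
  that chosen indices share planted cross-correlation;
* situs/owner address pairs: owner address copied verbatim for
  owner-occupied parcels, replaced by an unrelated address for renters;
* public-space nuisance points and per-block Poisson crime incidents;
* rater matrices with a planted one-way intraclass correlation.

Default sizes and rates emulate the published field campaign they stand in
for: a 31 x 31 grid (961 blocks, the nearest square grid to the study's 944
blocks) at 18 parcels per block (~17.3k parcels against a 17,242-parcel
roster), per-variable prevalences calibrated to the printed per-variable
observation counts, and a planted ICC of 0.70 matching the reported
single-rater agreement.  All randomness flows from a single integer seed
through independently spawned child generators, so each output stream is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box, mapping

from .crime import CATEGORIES, default_offense_mapping
from .registry import ValueKind, VariableRegistry, default_registry

__all__ = ["SyntheticConfig", "CityData", "generate_city", "generate_ratings",
           "generate_roster", "city_to_geojson"]


# Prevalences for parcel variables with printed observation counts
# (n / 16,644 assessable parcels); unlisted binary variables fall back to
# `base_prevalence`.
PARCEL_PREVALENCE = {
    "boarded_windows": 0.135,
    "peeling_paint": 0.209,
    "driveway_present": 0.753,
    "greenery": 0.635,
    "litter": 0.307,
    "high_weeds": 0.126,
    "security_sign": 0.243,
    "window_ac_unit": 0.136,
    "roof_damage": 0.026,
    "foundation_damage": 0.002,
    "condemned": 0.002,
    "eviction_notice": 0.002,
    "garden": 0.027,
    "for_sale_sign": 0.022,
    "for_rent_sign": 0.018,
    "graffiti_private": 0.0014,
}

# Per-point probabilities for public-space variables, proportional to the
# printed relative frequencies among the 31,652 recorded nuisances.
PUBLIC_PREVALENCE = {
    "litter_public": 0.378,
    "food_garbage": 0.174,
    "broken_glass_public": 0.132,
    "cigarette_butts": 0.120,
    "high_weeds_public": 0.064,
    "alcohol_container": 0.040,
    "condoms": 0.003,
    "discarded_tires_public": 0.002,
    "discarded_appliances_public": 0.002,
    "drug_paraphernalia": 0.0004,
    "graffiti_public": 0.0001,
}

DEFAULT_CRIME_RATE = {
    "violent": 0.5,
    "property": 1.5,
    "vice": 0.3,
    "theft": 1.0,
    "vehicular": 0.7,
}

# Latent-field loadings reproducing the qualitative correlation structure of
# the published index matrix: property disorder and nuisances co-vary most
# strongly, tenure runs opposite the disorder indices.
DEFAULT_LOADINGS = {
    "property_disorder": 1.0,
    "nuisances": 1.0,
    "housing_damage": 0.6,
    "territoriality": 0.35,
    "vacancy": 0.35,
    "crime": 0.35,
    "tenure": -0.3,
}

_DOMAIN_OF_INDEX = {
    "housing_damage": "housing_damage",
    "property_disorder": "property_disorder",
    "territoriality": "territoriality",
    "nuisances": "nuisance",
}


@dataclass
class SyntheticConfig:
    """Study-area generator parameters (see module docstring for defaults)."""

    grid_nx: int = 31
    grid_ny: int = 31
    block_size: float = 100.0
    parcels_per_block: int = 18
    base_prevalence: float = 0.02
    prevalence: Mapping[str, float] = dc_field(default_factory=lambda: dict(PARCEL_PREVALENCE))
    public_prevalence: Mapping[str, float] = dc_field(
        default_factory=lambda: dict(PUBLIC_PREVALENCE)
    )
    # ~36 points/block x ~0.92 expected observations/point reproduces the
    # published volume of ~33.5 public-space nuisance observations per block
    nuisance_points_per_block: float = 36.0
    renter_fraction: float = 0.30
    crime_rate: Mapping[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_CRIME_RATE))
    latent_factor_loadings: Mapping[str, float] = dc_field(default_factory=dict)
    latent_field_sigma: float = 1.5
    vacancy_fraction: float = 0.075
    planted_icc: float = 0.70
    seed: int = 0

    def validate(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        probs = [self.base_prevalence, self.renter_fraction, self.vacancy_fraction,
                 *self.prevalence.values(), *self.public_prevalence.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if not 0.0 <= self.planted_icc < 1.0:
            raise ValueError("planted_icc must be in [0, 1)")


@dataclass
class CityData:
    """One generated study area plus the ground truth that produced it."""

    blocks: dict
    parcels: pd.DataFrame
    nuisances: pd.DataFrame
    crimes: pd.DataFrame
    truth: dict


def _street_corpus() -> list[str]:
    ref = resources.files("blockscape.data").joinpath("street_names.txt")
    return ref.read_text(encoding="utf-8").split()


def _grid_blocks(cfg: SyntheticConfig) -> dict:
    size = cfg.block_size
    blocks = {}
    for iy in range(cfg.grid_ny):
        for ix in range(cfg.grid_nx):
            bid = f"B{iy:03d}{ix:03d}"
            blocks[bid] = box(ix * size, iy * size, (ix + 1) * size, (iy + 1) * size)
    return blocks


def _latent_field(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth standardized spatial field over the block grid (row-major)."""
    noise = rng.standard_normal((cfg.grid_ny, cfg.grid_nx))
    smooth = gaussian_filter(noise, sigma=cfg.latent_field_sigma, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth = (smooth - smooth.mean()) / sd
    return smooth.ravel()


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _loading_for_variable(cfg: SyntheticConfig, registry: VariableRegistry,
                          name: str) -> float:
    domain = registry[name].domain.value
    for index_name, dom in _DOMAIN_OF_INDEX.items():
        if dom == domain:
            return float(cfg.latent_factor_loadings.get(index_name, 0.0))
    return 0.0


def generate_city(
    config: Optional[SyntheticConfig] = None,
    registry: Optional[VariableRegistry] = None,
) -> CityData:
    """Generate blocks, parcels, nuisance points, and crime incidents.

    Identical configs (same seed) produce identical outputs.  Parcels are
    strictly interior to their blocks, so spatial assignment recovers the
    generating block exactly; the truth record stores every planted
    quantity, including per-parcel tenure.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    registry = registry or default_registry()
    root = np.random.SeedSequence(cfg.seed)
    r_field, r_parcel, r_obs, r_addr, r_nuis, r_crime = (
        np.random.default_rng(s) for s in root.spawn(6)
    )

    blocks = _grid_blocks(cfg)
    block_ids = list(blocks)
    n_blocks = len(block_ids)
    field = _latent_field(cfg, r_field)
    streets = _street_corpus()
    street_types = ["ST", "AVE", "RD", "DR", "LN"]

    # --- parcels -----------------------------------------------------------
    n_per = cfg.parcels_per_block
    n_parcels = n_blocks * n_per
    block_of = np.repeat(np.arange(n_blocks), n_per)
    size = cfg.block_size
    margin = 0.05 * size
    bx = block_of % cfg.grid_nx
    by = block_of // cfg.grid_nx
    xs = bx * size + margin + r_parcel.uniform(0, size - 2 * margin, n_parcels)
    ys = by * size + margin + r_parcel.uniform(0, size - 2 * margin, n_parcels)

    parcels = pd.DataFrame(
        {
            "parcel_id": [f"P{i:06d}" for i in range(n_parcels)],
            "x": xs,
            "y": ys,
        }
    )
    # property types: mostly residential; a slice of vacant lots and others
    type_probs = {"residential": 0.805, "commercial": 0.041, "religious": 0.009,
                  "community": 0.014, "unoccupied_lot": 0.075, "other": 0.056}
    parcels["property_type"] = r_parcel.choice(
        list(type_probs), p=list(type_probs.values()), size=n_parcels
    )
    subtype_probs = {"single_family": 0.835, "apartment": 0.038,
                     "senior_care_duplex_other": 0.127}
    subtype = r_parcel.choice(list(subtype_probs), p=list(subtype_probs.values()),
                              size=n_parcels)
    parcels["property_subtype"] = np.where(
        parcels["property_type"] == "residential", subtype, ""
    )

    vac_load = float(cfg.latent_factor_loadings.get("vacancy", 0.0))
    p_vac = _sigmoid(_logit(np.full(n_parcels, cfg.vacancy_fraction))
                     + vac_load * field[block_of])
    unocc = r_parcel.random(n_parcels) < p_vac
    parcels["occupancy"] = np.where(
        parcels["property_type"] == "unoccupied_lot", "unoccupied",
        np.where(unocc, "unoccupied", "occupied"),
    )

    # observations: Bernoulli per binary parcel variable
    for var in registry.parcel_variables:
        if var.value_kind is not ValueKind.BINARY:
            continue
        if var.name in ("occupied", "unoccupied", "demolished"):
            continue  # derived from the occupancy column
        p0 = float(cfg.prevalence.get(var.name, cfg.base_prevalence))
        load = _loading_for_variable(cfg, registry, var.name)
        p = _sigmoid(_logit(np.full(n_parcels, p0)) + load * field[block_of])
        parcels[var.name] = (r_obs.random(n_parcels) < p).astype(int)

    # addresses: situs unique per parcel; owners copy it or get an unrelated one
    situs_street = r_addr.integers(0, len(streets), n_parcels)
    situs_type = r_addr.integers(0, len(street_types), n_parcels)
    house = r_addr.integers(100, 9900, n_parcels)
    parcels["situs_address"] = [
        f"{house[i]} {streets[situs_street[i]]} {street_types[situs_type[i]]}"
        for i in range(n_parcels)
    ]
    ten_load = float(cfg.latent_factor_loadings.get("tenure", 0.0))
    p_rent = _sigmoid(_logit(np.full(n_parcels, cfg.renter_fraction))
                      + ten_load * field[block_of])
    renter = r_addr.random(n_parcels) < p_rent
    owner_street = (situs_street + 1 + r_addr.integers(0, len(streets) - 1, n_parcels)) % len(streets)
    owner_house = house + 1 + r_addr.integers(0, 500, n_parcels)
    owner_addr = [
        f"{owner_house[i]} {streets[owner_street[i]]} "
        f"{street_types[(situs_type[i] + 1) % len(street_types)]}"
        for i in range(n_parcels)
    ]
    parcels["owner_address"] = np.where(renter, owner_addr, parcels["situs_address"])
    parcels["true_block_id"] = [block_ids[b] for b in block_of]

    # --- nuisance points (latent field acts on per-point prevalences, not
    # on the point count, so the count stays stationary) --------------------
    n_points = r_nuis.poisson(cfg.nuisance_points_per_block, n_blocks)
    rows = []
    for b, npts in enumerate(n_points):
        for j in range(npts):
            px = (b % cfg.grid_nx) * size + margin + r_nuis.uniform(0, size - 2 * margin)
            py = (b // cfg.grid_nx) * size + margin + r_nuis.uniform(0, size - 2 * margin)
            rows.append((f"N{b:05d}_{j:02d}", px, py, b))
    nuisances = pd.DataFrame(rows, columns=["nuisance_id", "x", "y", "_block"])
    for var in registry.public_space_variables:
        if var.value_kind is not ValueKind.BINARY:
            continue
        p0 = float(cfg.public_prevalence.get(var.name, 0.005))
        load = _loading_for_variable(cfg, registry, var.name)
        if len(nuisances):
            p = _sigmoid(_logit(np.full(len(nuisances), p0))
                         + load * field[nuisances["_block"].to_numpy()])
            nuisances[var.name] = (r_nuis.random(len(nuisances)) < p).astype(int)
        else:
            nuisances[var.name] = pd.Series([], dtype=int)
    nuisances = nuisances.drop(columns=["_block"])

    # --- crime incidents ---------------------------------------------------
    crime_load = float(cfg.latent_factor_loadings.get("crime", 0.0))
    mapping_inv: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for label, cat in default_offense_mapping().items():
        mapping_inv[cat].append(label)
    rows = []
    for cat in CATEGORIES:
        rate = float(cfg.crime_rate.get(cat, 0.0))
        if rate <= 0:
            continue
        lam = rate * np.exp(crime_load * field)
        counts = r_crime.poisson(lam)
        labels = mapping_inv[cat]
        for b, m in enumerate(counts):
            for j in range(m):
                px = (b % cfg.grid_nx) * size + margin + r_crime.uniform(0, size - 2 * margin)
                py = (b // cfg.grid_nx) * size + margin + r_crime.uniform(0, size - 2 * margin)
                label = labels[r_crime.integers(0, len(labels))]
                rows.append((f"C{cat[:3]}{b:05d}_{j:02d}", px, py, label, cat))
    crimes = pd.DataFrame(rows, columns=["incident_id", "x", "y", "offense_label",
                                         "true_category"])

    truth = {
        "config": cfg,
        "n_blocks": n_blocks,
        "n_parcels": n_parcels,
        "renter": pd.Series(renter, index=parcels["parcel_id"].values),
        "renter_fraction_realized": float(renter.mean()),
        "block_of_parcel": pd.Series(parcels["true_block_id"].values,
                                     index=parcels["parcel_id"].values),
        "latent_field": pd.Series(field, index=block_ids),
        "crime_by_category": crimes.groupby("true_category").size().to_dict()
        if len(crimes) else {},
    }
    return CityData(blocks=blocks, parcels=parcels, nuisances=nuisances,
                    crimes=crimes, truth=truth)


def generate_ratings(
    n: int, k: int, planted_icc: float, seed: int, binary: bool = False
) -> tuple[np.ndarray, dict]:
    """n x k rating matrix with planted one-way intraclass correlation.

    Scores are target effect (variance rho) plus rater noise (variance
    1 - rho), so the population ICC(1) is exactly ``planted_icc``.  With
    ``binary=True`` scores are thresholded at 0, which attenuates the ICC of
    the dichotomized ratings; the truth record stores the continuous rho.
    """
    if not 0.0 <= planted_icc < 1.0:
        raise ValueError("planted_icc must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    target = rng.standard_normal(n) * np.sqrt(planted_icc)
    noise = rng.standard_normal((n, k)) * np.sqrt(1.0 - planted_icc)
    scores = target[:, None] + noise
    if binary:
        scores = (scores > 0).astype(float)
    truth = {"planted_icc": planted_icc, "n": n, "k": k, "binary": binary}
    return scores, truth


def generate_roster(
    total: int,
    excluded: int,
    residential: int,
    commercial: int,
    religious: int,
    community: int,
    unoccupied_lots: int,
    single_family: int,
    apartments: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Assessment roster with the given exclusion and category composition.

    Builds one row per parcel: ``excluded`` parcels are flagged, the
    remaining assessable parcels receive property types in the given counts
    (the shortfall versus the assessable total becomes ``other``), and
    residential parcels receive subtypes (shortfall becomes the residual
    senior/care/duplex/other group).  Row order is shuffled by ``seed`` so
    the tabulation, not the construction order, is what is exercised.
    """
    assessable = total - excluded
    named = residential + commercial + religious + community + unoccupied_lots
    if excluded < 0 or named > assessable:
        raise ValueError("category counts exceed the assessable total")
    if single_family + apartments > residential:
        raise ValueError("subtype counts exceed the residential total")

    types = (
        ["residential"] * residential
        + ["commercial"] * commercial
        + ["religious"] * religious
        + ["community"] * community
        + ["unoccupied_lot"] * unoccupied_lots
        + ["other"] * (assessable - named)
    )
    subtypes = (
        ["single_family"] * single_family
        + ["apartment"] * apartments
        + ["senior_care_duplex_other"] * (residential - single_family - apartments)
    )
    sub_iter = iter(subtypes)
    roster = pd.DataFrame(
        {
            "parcel_id": [f"R{i:06d}" for i in range(total)],
            "excluded": [True] * excluded + [False] * assessable,
            "property_type": [""] * excluded + types,
        }
    )
    roster["property_subtype"] = [
        next(sub_iter) if t == "residential" else "" for t in roster["property_type"]
    ]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return roster.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31))
                         ).reset_index(drop=True)


def city_to_geojson(blocks: dict) -> dict:
    """Block layer as a GeoJSON FeatureCollection (planar coordinates)."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"GEOID": bid},
                "geometry": mapping(geom),
            }
            for bid, geom in blocks.items()
        ],
    }
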