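"""Resource-niche growth simulator.

Each species occupies a disk in a 2-D unit resource box.  A community
captures the union of its member disks; resource cells covered by several
species are split between them (equally by default, or proportionally to
per-species competitive weights).  Captured resource translates into annual
diameter growth with multiplicative lognormal noise, yielding tree-level
inventories with the qualitative structure expected of the field system:

- ``complementarity``: disjoint niches and equal rates, so mixtures exploit
  more resource space per capita than monocultures;
- ``selection``: fully overlapping niches with one competitively dominant,
  fast-growing species;
- ``neutral``: identical niches and rates, so mixtures add nothing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import PlantingLayout, PlotDesign, layouts_for_design
from .traits import SpeciesPools

logger = logging.getLogger(__name__)

SCENARIOS = ("complementarity", "selection", "neutral")

DEFAULT_AMF_REGION = (0.0, 0.0, 0.5, 1.0)
DEFAULT_EMF_REGION = (0.5, 0.0, 1.0, 1.0)

INVENTORY_COLUMNS = [
    "plot_id",
    "row",
    "col",
    "species_id",
    "year",
    "diameter_cm",
    "alive",
]


@dataclass(frozen=True)
class SpeciesNiche:
    """One species' resource niche: a disk plus growth and competition traits.

    ``intrinsic_rate`` is cm diameter growth per unit per-capita captured
    resource per year; ``weight`` is the share multiplier applied in
    contested resource cells (1.0 = equal split).
    """

    center: tuple[float, float]
    radius: float
    intrinsic_rate: float
    weight: float = 1.0

    def __post_init__(self):
        x, y = self.center
        if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            raise ValueError(f"niche center {self.center} outside the unit box")
        if not (0.0 < self.radius <= 0.5):
            raise ValueError(f"niche radius {self.radius} outside (0, 0.5]")
        if self.intrinsic_rate <= 0:
            raise ValueError("intrinsic_rate must be positive")
        if self.weight <= 0:
            raise ValueError("competitive weight must be positive")


@dataclass
class NicheConfig:
    """Ground-truth niche geometry and growth parameters for all species."""

    niches: dict[str, SpeciesNiche]
    scenario: str
    seed: int | None = None
    amf_region: tuple[float, float, float, float] = DEFAULT_AMF_REGION
    emf_region: tuple[float, float, float, float] = DEFAULT_EMF_REGION
    overlap_level: float = 0.0

    def __post_init__(self):
        for region in (self.amf_region, self.emf_region):
            x0, y0, x1, y1 = region
            if not (0 <= x0 < x1 <= 1 and 0 <= y0 < y1 <= 1):
                raise ValueError(f"region {region} not a rectangle inside the unit box")
        if not 0.0 <= self.overlap_level <= 1.0:
            raise ValueError("overlap_level must lie in [0, 1]")

    # -- JSON replay metadata ---------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "amf_region": list(self.amf_region),
            "emf_region": list(self.emf_region),
            "overlap_level": self.overlap_level,
            "niches": {
                sp: {
                    "center": list(n.center),
                    "radius": n.radius,
                    "intrinsic_rate": n.intrinsic_rate,
                    "weight": n.weight,
                }
                for sp, n in sorted(self.niches.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "NicheConfig":
        with open(path) as fh:
            payload = json.load(fh)
        niches = {
            sp: SpeciesNiche(
                center=tuple(v["center"]),
                radius=v["radius"],
                intrinsic_rate=v["intrinsic_rate"],
                weight=v.get("weight", 1.0),
            )
            for sp, v in payload["niches"].items()
        }
        return cls(
            niches=niches,
            scenario=payload["scenario"],
            seed=payload.get("seed"),
            amf_region=tuple(payload["amf_region"]),
            emf_region=tuple(payload["emf_region"]),
            overlap_level=payload.get("overlap_level", 0.0),
        )


def _sample_disjoint_centers(
    rng: np.random.Generator,
    regions: Sequence[tuple[float, float, float, float]],
    radius: float,
    min_separation: float,
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    """Uniform centers, one per region entry, pairwise >= min_separation apart.

    Centers are clamped inward so disks stay inside the unit box (keeping all
    disk areas exactly pi r^2).
    """
    for _ in range(max_tries):
        centers = []
        for x0, y0, x1, y1 in regions:
            lo_x, hi_x = max(x0, radius), min(x1, 1 - radius)
            lo_y, hi_y = max(y0, radius), min(y1, 1 - radius)
            if lo_x >= hi_x or lo_y >= hi_y:
                raise ValueError("region too small for the requested radius")
            centers.append((rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)))
        pts = np.asarray(centers)
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(len(pts), k=1)
        if (dist[iu] >= min_separation).all():
            return centers
    raise RuntimeError(
        f"could not place {len(regions)} disjoint niche centers in {max_tries} tries"
    )


def sample_niche_config(
    pools: SpeciesPools,
    scenario: str = "complementarity",
    seed: int | None = 0,
    radius: float | None = None,
    base_rate: float = 1500.0,
    amf_rate_factor: float = 1.0,
    dominance_factor: float = 4.0,
    dominant_species: str | None = None,
    amf_region: tuple[float, float, float, float] = DEFAULT_AMF_REGION,
    emf_region: tuple[float, float, float, float] = DEFAULT_EMF_REGION,
    overlap_level: float = 0.0,
) -> NicheConfig:
    """Draw a ground-truth niche configuration for one of the three scenarios.

    - ``complementarity``: per-species centers drawn uniformly in the
      matching type region (AMF left, EMF right by default) and re-drawn
      until all disks are pairwise disjoint; ``overlap_level`` > 0 relaxes
      the required separation towards touching.  Equal rates.
    - ``selection``: all species share an identical central disk; the
      dominant species (first of the AMF pool unless given) gets its
      competitive weight and intrinsic rate multiplied by
      ``dominance_factor``.
    - ``neutral``: identical central disks, equal rates and weights.

    ``amf_rate_factor`` scales all AMF rates, mimicking a nutrient regime
    favouring one mycorrhizal type.  Deterministic for a fixed seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    amf = sorted(pools.amf_pool)
    emf = sorted(pools.emf_pool)
    species = amf + emf
    niches: dict[str, SpeciesNiche] = {}

    if scenario == "complementarity":
        r = 0.07 if radius is None else radius
        regions = [amf_region] * len(amf) + [emf_region] * len(emf)
        min_sep = 2.0 * r * (1.0 - overlap_level) + 1e-9
        centers = _sample_disjoint_centers(rng, regions, r, min_sep)
        for sp, center in zip(species, centers):
            rate = base_rate * (amf_rate_factor if sp in amf else 1.0)
            niches[sp] = SpeciesNiche(center=center, radius=r, intrinsic_rate=rate)
    else:
        r = 0.15 if radius is None else radius
        center = (0.5, 0.5)
        if scenario == "selection" and dominant_species is None:
            dominant_species = species[0]
        if scenario == "selection" and dominant_species not in species:
            raise ValueError(f"dominant species {dominant_species!r} not in pools")
        for sp in species:
            rate = base_rate * (amf_rate_factor if sp in amf else 1.0)
            weight = 1.0
            if scenario == "selection" and sp == dominant_species:
                rate *= dominance_factor
                weight *= dominance_factor
            niches[sp] = SpeciesNiche(
                center=center, radius=r, intrinsic_rate=rate, weight=weight
            )

    return NicheConfig(
        niches=niches,
        scenario=scenario,
        seed=seed,
        amf_region=amf_region,
        emf_region=emf_region,
        overlap_level=overlap_level,
    )


# ---------------------------------------------------------------------------
# resource capture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaptureResult:
    """Per-species captured resource area plus the community's union area."""

    per_species: dict[str, float]
    union_area: float

    @property
    def total(self) -> float:
        return float(sum(self.per_species.values()))


def _disk_masks(
    config: NicheConfig, species: Sequence[str], resolution: int
) -> np.ndarray:
    coords = (np.arange(resolution) + 0.5) / resolution
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    masks = np.empty((len(species), resolution * resolution), dtype=bool)
    for i, sp in enumerate(species):
        n = config.niches[sp]
        cx, cy = n.center
        masks[i] = (((xx - cx) ** 2 + (yy - cy) ** 2) <= n.radius**2).ravel()
    return masks


def community_capture(
    config: NicheConfig,
    species: Iterable[str],
    resolution: int = 200,
) -> CaptureResult:
    """Grid quadrature of per-species resource capture in the unit box.

    The box is discretised into ``resolution**2`` cells; each covered cell's
    area is split among the covering species proportionally to their
    competitive weights (equal weights give an equal split).  The union of
    the member disks is the community's total exploitation.
    """
    species = sorted(set(species))
    if not species:
        raise ValueError("empty species set")
    missing = [s for s in species if s not in config.niches]
    if missing:
        raise KeyError(f"species not in niche config: {missing}")
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    masks = _disk_masks(config, species, resolution)
    weights = np.array([config.niches[s].weight for s in species])
    weighted = masks * weights[:, None]
    denom = weighted.sum(axis=0)
    cell_area = 1.0 / resolution**2
    covered = denom > 0
    shares = np.zeros_like(weighted)
    shares[:, covered] = weighted[:, covered] / denom[covered]
    per_species = {
        sp: float(shares[i].sum() * cell_area) for i, sp in enumerate(species)
    }
    union_area = float(covered.sum() * cell_area)
    return CaptureResult(per_species=per_species, union_area=union_area)


# ---------------------------------------------------------------------------
# inventory simulation
# ---------------------------------------------------------------------------


def simulate_inventory(
    plots: Sequence[PlotDesign],
    config: NicheConfig,
    layouts: Mapping[str, PlantingLayout] | None = None,
    years: int = 2,
    noise_sd: float = 0.05,
    mortality_rate: float = 0.0,
    seed: int | None = 0,
    resolution: int = 200,
    initial_diameter: float = 1.0,
    initial_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate tree-level diameter time series for a designed experiment.

    Growth law: each tree of species ``i`` in a plot receives the per-capita
    resource share ``capture_i / n_i`` (``n_i`` = planted individuals of the
    species in the plot) and grows ``intrinsic_rate_i * share * exp(eps)``
    cm/yr with ``eps ~ Normal(0, noise_sd^2)`` i.i.d. per tree-year.  Trees
    die independently with probability ``mortality_rate`` per year; dead
    trees keep their last diameter and stay flagged dead.  Year 0 records the
    planting diameters.  Deterministic for a fixed seed.
    """
    if years < 2:
        raise ValueError("years must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= mortality_rate < 1.0:
        raise ValueError("mortality_rate must lie in [0, 1)")
    if initial_diameter <= 0:
        raise ValueError("initial_diameter must be positive")
    if layouts is None:
        layouts = layouts_for_design(plots, seed=seed)

    rng = np.random.default_rng(seed)
    capture_cache: dict[tuple[str, ...], dict[str, float]] = {}
    frames = []
    for plot in sorted(plots, key=lambda p: p.plot_id):
        layout = layouts[plot.plot_id]
        comp = plot.composition.species
        if comp not in capture_cache:
            capture_cache[comp] = community_capture(
                config, comp, resolution=resolution
            ).per_species
        capture = capture_cache[comp]
        counts = layout.species_counts()
        rate = {
            sp: config.niches[sp].intrinsic_rate * capture[sp] / counts[sp]
            for sp in comp
        }

        rows = np.array([p[0] for p in layout.positions])
        cols = np.array([p[1] for p in layout.positions])
        sp_arr = np.array([p[2] for p in layout.positions])
        n = len(sp_arr)
        base = np.array([rate[s] for s in sp_arr])

        if initial_sd > 0:
            diam = initial_diameter * np.exp(rng.normal(0.0, initial_sd, n))
        else:
            diam = np.full(n, float(initial_diameter))
        alive = np.ones(n, dtype=bool)

        def snapshot(year, diam, alive):
            return pd.DataFrame(
                {
                    "plot_id": plot.plot_id,
                    "row": rows,
                    "col": cols,
                    "species_id": sp_arr,
                    "year": year,
                    "diameter_cm": diam.copy(),
                    "alive": alive.copy(),
                }
            )

        frames.append(snapshot(0, diam, alive))
        for year in range(1, years + 1):
            if mortality_rate > 0:
                dies = alive & (rng.random(n) < mortality_rate)
                alive = alive & ~dies
            if noise_sd > 0:
                growth = base * np.exp(rng.normal(0.0, noise_sd, n))
            else:
                growth = base
            diam = np.where(alive, diam + growth, diam)
            frames.append(snapshot(year, diam, alive))
    inv = pd.concat(frames, ignore_index=True)
    return inv[INVENTORY_COLUMNS]


def write_inventory_csv(inventory: pd.DataFrame, path) -> None:
    out = inventory.copy()
    out["alive"] = out["alive"].astype(int)
    out.to_csv(path, index=False)


def read_inventory_csv(path) -> pd.DataFrame:
    inv = pd.read_csv(path)
    missing = set(INVENTORY_COLUMNS) - set(inv.columns)
    if missing:
        raise ValueError(f"inventory CSV missing columns: {sorted(missing)}")
    inv["alive"] = inv["alive"].astype(bool)
    return inv[INVENTORY_COLUMNS]
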