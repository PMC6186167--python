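"""Basal-area productivity and additive partitioning of mixture yields.

Mixture productivity is split into a net biodiversity effect (observed
minus expected yield), a complementarity effect (average relative-yield
deviation across species) and a selection effect (covariance between
relative-yield deviation and monoculture yield).  The identity
``NE = CE + SE`` holds exactly because the selection covariance divides
by the species number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PlotDesign

logger = logging.getLogger(__name__)


def basal_area_m2(diameter_cm) -> np.ndarray:
    """Stem cross-sectional area in m^2 from diameter in cm."""
    d = np.asarray(diameter_cm, dtype=float)
    return np.pi * (d / 200.0) ** 2


def basal_area_increment(
    inventory: pd.DataFrame,
    year_from: int = 1,
    year_to: int = 2,
    years_elapsed: float | None = None,
) -> pd.DataFrame:
    """Annualised basal-area increment per plot and species (m^2/yr).

    Trees dead by ``year_to`` contribute zero increment; negative increments
    of living trees are kept with a warning.  ``years_elapsed`` overrides the
    default ``year_to - year_from`` divisor (fractional years supported for
    measurement windows that do not span whole years).
    """
    years_present = set(inventory["year"].unique())
    for y in (year_from, year_to):
        if y not in years_present:
            raise ValueError(f"year {y} not present in inventory")
    if year_to <= year_from:
        raise ValueError("year_to must exceed year_from")
    elapsed = float(year_to - year_from) if years_elapsed is None else float(years_elapsed)
    if elapsed <= 0:
        raise ValueError("elapsed time must be positive")

    key = ["plot_id", "row", "col", "species_id"]
    a = inventory[inventory["year"] == year_from].set_index(key)
    b = inventory[inventory["year"] == year_to].set_index(key)
    joined = a[["diameter_cm"]].join(
        b[["diameter_cm", "alive"]], how="inner", lsuffix="_from", rsuffix="_to"
    )
    if len(joined) != len(b):
        raise ValueError("inventory years do not cover the same trees")
    d_from = joined["diameter_cm_from"].to_numpy()
    d_to = joined["diameter_cm_to"].to_numpy()
    alive = joined["alive"].to_numpy(dtype=bool)
    delta = basal_area_m2(d_to) - basal_area_m2(d_from)
    n_neg = int(((delta < 0) & alive).sum())
    if n_neg:
        logger.warning(
            "%d living trees have negative basal-area increments (kept)", n_neg
        )
    delta = np.where(alive, delta, 0.0) / elapsed
    out = joined.reset_index()[["plot_id", "species_id"]].copy()
    out["yield_m2"] = delta
    return (
        out.groupby(["plot_id", "species_id"], as_index=False)["yield_m2"]
        .sum()
        .sort_values(["plot_id", "species_id"], ignore_index=True)
    )


@dataclass(frozen=True)
class YieldTable:
    """Observed mixture yields with monoculture references for one plot."""

    plot_id: str
    species: tuple[str, ...]
    y_obs: np.ndarray  # observed per-species yield in the mixture, m^2/yr
    m_ref: np.ndarray  # monoculture reference yields, m^2/yr
    ry_expected: np.ndarray  # expected relative yields (planted proportions)

    def __post_init__(self):
        y = np.asarray(self.y_obs, dtype=float)
        m = np.asarray(self.m_ref, dtype=float)
        ry = np.asarray(self.ry_expected, dtype=float)
        n = len(self.species)
        if not (len(y) == len(m) == len(ry) == n):
            raise ValueError("yield table arrays must match the species list")
        if (m <= 0).any():
            raise ValueError("monoculture references must be positive")
        if (y < 0).any():
            raise ValueError("observed yields must be nonnegative")
        if abs(ry.sum() - 1.0) > 1e-9:
            raise ValueError("expected relative yields must sum to 1")
        object.__setattr__(self, "y_obs", y)
        object.__setattr__(self, "m_ref", m)
        object.__setattr__(self, "ry_expected", ry)

    @property
    def richness(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class PartitionResult:
    """Additive partition of one mixture plot's net biodiversity effect."""

    plot_id: str
    net_effect: float
    complementarity_effect: float
    selection_effect: float
    mean_delta_ry: float
    mean_m: float

    def __post_init__(self):
        resid = abs(
            self.net_effect - (self.complementarity_effect + self.selection_effect)
        )
        if resid > 1e-9 * max(1.0, abs(self.net_effect)):
            raise ValueError("NE != CE + SE beyond tolerance")


def monoculture_references(
    yields: pd.DataFrame, plots: list[PlotDesign]
) -> pd.Series:
    """Mean monoculture yield per species over its replicate monoculture plots."""
    mono_ids = {
        p.plot_id: p.composition.species[0]
        for p in plots
        if p.treatment.richness == 1
    }
    mono = yields[yields["plot_id"].isin(mono_ids)].copy()
    mono["species_id"] = mono["plot_id"].map(mono_ids)
    return mono.groupby("species_id")["yield_m2"].mean()


def build_yield_table(
    yields: pd.DataFrame, plots: list[PlotDesign]
) -> list[YieldTable]:
    """Per-mixture-plot yield tables with equal expected relative yields.

    Mixture plots whose species lack a positive monoculture reference are
    excluded with a log message; monoculture plots never yield rows.
    """
    refs = monoculture_references(yields, plots)
    by_plot = {
        pid: dict(zip(grp["species_id"], grp["yield_m2"]))
        for pid, grp in yields.groupby("plot_id")
    }
    tables = []
    for plot in sorted(plots, key=lambda p: p.plot_id):
        n = plot.treatment.richness
        if n == 1:
            continue
        species = plot.composition.species
        missing = [s for s in species if s not in refs.index or refs[s] <= 0]
        if missing:
            logger.warning(
                "plot %s excluded: no positive monoculture reference for %s",
                plot.plot_id,
                missing,
            )
            continue
        obs = by_plot.get(plot.plot_id, {})
        tables.append(
            YieldTable(
                plot_id=plot.plot_id,
                species=species,
                y_obs=np.array([max(obs.get(s, 0.0), 0.0) for s in species]),
                m_ref=np.array([refs[s] for s in species]),
                ry_expected=np.full(n, 1.0 / n),
            )
        )
    return tables


def partition(yt: YieldTable) -> PartitionResult:
    """Additive partition of the net biodiversity effect for one plot.

    ``NE = sum(Y_obs) - sum(RY_E * M)``; ``CE = N * mean(dRY) * mean(M)``;
    ``SE = N * cov(dRY, M)`` with the population covariance (divide by N),
    where ``dRY_i = Y_obs_i / M_i - RY_E_i``.
    """
    n = yt.richness
    ry_obs = yt.y_obs / yt.m_ref
    d_ry = ry_obs - yt.ry_expected
    ne = float(yt.y_obs.sum() - (yt.ry_expected * yt.m_ref).sum())
    mean_dry = float(d_ry.mean())
    mean_m = float(yt.m_ref.mean())
    ce = n * mean_dry * mean_m
    cov = float(((d_ry - mean_dry) * (yt.m_ref - mean_m)).sum() / n)
    se = n * cov
    return PartitionResult(
        plot_id=yt.plot_id,
        net_effect=ne,
        complementarity_effect=ce,
        selection_effect=se,
        mean_delta_ry=mean_dry,
        mean_m=mean_m,
    )


def partition_design(
    yields: pd.DataFrame, plots: list[PlotDesign]
) -> pd.DataFrame:
    """Partition every mixture plot; returns a tidy frame with treatment info."""
    info = {
        p.plot_id: (
            p.treatment.richness,
            p.treatment.myco_level,
            ";".join(p.composition.species),
        )
        for p in plots
    }
    rows = []
    for yt in build_yield_table(yields, plots):
        res = partition(yt)
        richness, level, comp = info[yt.plot_id]
        rows.append(
            {
                "plot_id": res.plot_id,
                "richness": richness,
                "myco_level": level,
                "composition": comp,
                "NE": res.net_effect,
                "CE": res.complementarity_effect,
                "SE": res.selection_effect,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["plot_id", "richness", "myco_level", "composition", "NE", "CE", "SE"],
    )


def plot_productivity(yields: pd.DataFrame, plots: list[PlotDesign]) -> pd.DataFrame:
    """Total basal-area increment per plot with treatment metadata."""
    info = {
        p.plot_id: (
            p.treatment.richness,
            p.treatment.myco_level,
            ";".join(p.composition.species),
        )
        for p in plots
    }
    total = yields.groupby("plot_id", as_index=False)["yield_m2"].sum()
    total = total.rename(columns={"yield_m2": "productivity"})
    total["richness"] = total["plot_id"].map(lambda p: info[p][0])
    total["myco_level"] = total["plot_id"].map(lambda p: info[p][1])
    total["composition"] = total["plot_id"].map(lambda p: info[p][2])
    return total
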