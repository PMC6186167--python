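"""Bundled example inputs.

The species label set matches ten temperate deciduous trees commonly used
in mycorrhizal-type experiments (five predominantly arbuscular, five
predominantly ectomycorrhizal).  Trait values are synthetic draws from
plausible ranges — they are demo inputs for exercising the pipeline, not
measurements.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .traits import TraitTable

EXAMPLE_SPECIES = {
    "Acer pseudoplatanus": "AMF",
    "Aesculus hippocastanum": "AMF",
    "Fraxinus excelsior": "AMF",
    "Prunus avium": "AMF",
    "Sorbus aucuparia": "AMF",
    "Betula pendula": "EMF",
    "Carpinus betulus": "EMF",
    "Fagus sylvatica": "EMF",
    "Quercus petraea": "EMF",
    "Tilia platyphyllos": "EMF",
}

TRAIT_UNITS = {
    "leaf_out_day": "day of year",
    "sla_mm2_mg": "mm^2/mg",
    "max_height_m": "m",
    "wood_density_g_cm3": "g/cm^3",
    "leaf_cn_ratio": "dimensionless",
    "seed_mass_mg": "mg",
    "shade_tolerance": "categorical {low, mid, high}",
}

_TRAIT_RANGES = {
    "leaf_out_day": (95.0, 140.0),
    "sla_mm2_mg": (8.0, 35.0),
    "max_height_m": (12.0, 40.0),
    "wood_density_g_cm3": (0.42, 0.75),
    "leaf_cn_ratio": (15.0, 35.0),
    "seed_mass_mg": (0.2, 8000.0),
}


def demo_trait_table(seed: int | None = 0, extra_per_type: int = 0) -> TraitTable:
    """Synthetic trait table over the example species labels.

    ``extra_per_type`` appends additional made-up candidate species per
    mycorrhizal type (useful for exercising pool selection on more than
    five candidates per type).
    """
    rng = np.random.default_rng(seed)
    species = dict(EXAMPLE_SPECIES)
    for i in range(extra_per_type):
        species[f"Amf candidatus {i + 1}"] = "AMF"
        species[f"Emf candidatus {i + 1}"] = "EMF"
    rows = []
    shade_levels = np.array(["low", "mid", "high"])
    for sp, myco in species.items():
        row = {"species": sp, "mycorrhizal_type": myco}
        for trait, (lo, hi) in _TRAIT_RANGES.items():
            if trait == "seed_mass_mg":
                # seed masses span orders of magnitude; sample on log scale
                row[trait] = float(
                    np.exp(rng.uniform(np.log(lo), np.log(hi)))
                )
            else:
                row[trait] = float(rng.uniform(lo, hi))
        row["shade_tolerance"] = str(rng.choice(shade_levels))
        rows.append(row)
    return TraitTable(pd.DataFrame(rows))


def write_trait_units_json(path) -> None:
    """Sidecar metadata documenting trait units for the demo table."""
    with open(path, "w") as fh:
        json.dump(TRAIT_UNITS, fh, indent=2, sort_keys=True)
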