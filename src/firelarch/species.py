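"""Species trait table for the six boreal conifers of eastern Siberia.

The demographic core is deliberately parameter-driven: every functional
constant of growth, dispersal, establishment, mortality, and fire response
lives in this table, so the demography can be re-tuned without code
changes.  Values for the non-fire traits are documented stand-ins for the
base model's calibration; the active-layer establishment gates (20 cm for
Dahurian larch, 100 cm for Scots pine, 200 cm for Siberian spruce and
Siberian pine) are the published species thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

__all__ = ["SpeciesTraits", "default_species", "load_species_csv",
           "write_species_csv", "SPECIES_NAMES"]


@dataclass(frozen=True)
class SpeciesTraits:
    name: str
    deciduous: bool                 # larches shed needles; the evergreens do not
    min_active_layer_cm: float      # establishment gate on seasonal thaw depth
    bark_coef: float                # cm bark per cm tree height (insulation proxy)
    resprout_prob: float            # probability of resprouting after fire top-kill
    growth_rate_cm_per_yr: float    # annual height increment at optimum, no competition
    temp_optimum_c: float           # growing-season mean temperature optimum
    temp_tolerance_c: float         # Gaussian suitability width
    maturity_height_cm: float       # minimum height for seed production
    seeds_per_year: float           # cone seed production at maturity
    dispersal_sd_m: float           # sd of the isotropic Gaussian dispersal kernel
    max_age_yr: float               # senescence limit; death is certain beyond it
    background_mortality: float     # annual baseline death probability
    max_height_cm: float            # asymptotic height

    def __post_init__(self) -> None:
        if self.min_active_layer_cm <= 0:
            raise ValueError("min_active_layer_cm must be > 0")
        if self.bark_coef < 0:
            raise ValueError("bark_coef must be >= 0")


# Published active-layer gates: Dahurian larch 0.2 m, Scots pine 1.0 m,
# Siberian spruce and Siberian pine 2.0 m.  Other larches use documented
# stand-in values between the Dahurian gate and the evergreen gates.
_DEFAULTS = [
    #        name            decid  AL    bark    respr grow  Topt  Ttol  mat  seeds  sd   age  bg      hmax
    ("Dahurian larch",        True,  20.0, 0.0050, 0.15, 35.0, 11.5, 6.0, 200.0, 60.0, 5.0, 350, 0.015, 1450.0),
    ("Cajander larch",        True,  25.0, 0.0045, 0.10, 30.0, 10.0, 5.0, 200.0, 50.0, 5.0, 350, 0.016, 1300.0),
    ("Siberian larch",        True,  30.0, 0.0045, 0.10, 33.0, 13.0, 5.0, 200.0, 55.0, 5.0, 350, 0.015, 1400.0),
    ("Siberian spruce",       False, 200.0, 0.0010, 0.0, 25.0, 13.5, 5.0, 250.0, 60.0, 4.0, 300, 0.018, 1300.0),
    ("Scots pine",            False, 100.0, 0.0040, 0.0, 30.0, 14.0, 5.0, 220.0, 50.0, 6.0, 320, 0.016, 1400.0),
    ("Siberian pine",         False, 200.0, 0.0030, 0.0, 22.0, 13.0, 5.0, 260.0, 40.0, 4.0, 400, 0.015, 1350.0),
]

SPECIES_NAMES = [row[0] for row in _DEFAULTS]


def default_species() -> dict[str, SpeciesTraits]:
    """The shipped trait table for the six species, keyed by name."""
    cols = [f.name for f in fields(SpeciesTraits)]
    return {row[0]: SpeciesTraits(**dict(zip(cols, row))) for row in _DEFAULTS}


def load_species_csv(path) -> dict[str, SpeciesTraits]:
    df = pd.read_csv(path)
    cols = [f.name for f in fields(SpeciesTraits)]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: species table missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in cols}
        kwargs["name"] = str(kwargs["name"])
        kwargs["deciduous"] = bool(kwargs["deciduous"])
        out[kwargs["name"]] = SpeciesTraits(**kwargs)
    return out


def write_species_csv(species: dict[str, SpeciesTraits], path) -> None:
    cols = [f.name for f in fields(SpeciesTraits)]
    rows = [{c: getattr(tr, c) for c in cols} for tr in species.values()]
    pd.DataFrame(rows).to_csv(path, index=False)
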