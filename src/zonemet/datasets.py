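"""Published benchmark summaries from the 2016 Swedish winter-wheat
official cultivar-testing series (25 genotypes, 18 tested locations in
three zones, 4 new locations: N01/N02 in the North zone, S01/S02 in the
South).  The plot-level data of that series are not publicly deposited;
these model-comparison summaries are included for context, worked
examples and internal-consistency checks.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["swedish_2016_sepv_averages", "swedish_2016_sepd_averages",
           "swedish_2016_msep"]

# Average SEPV over the 25 genotypes, per new location and model (g/m^2).
_SEPV = {
    "RC2": (113.13, 121.42, 88.10, 89.38),
    "RC3": (114.23, 122.10, 88.14, 89.20),
    "RC1": (113.18, 121.46, 88.16, 89.45),
    "FGI3": (114.98, 122.89, 88.19, 89.20),
    "RGCQ": (114.24, 122.06, 91.65, 92.57),
    "FGCQ": (114.73, 122.52, 92.51, 93.42),
    "FGI1": (127.76, 142.03, 92.88, 97.02),
    "FGI2": (127.76, 142.03, 92.88, 97.02),
    "RG1": (174.11, 174.11, 141.55, 141.55),
    "FG1": (174.42, 174.42, 142.17, 142.17),
    "RGC": (207.01, 215.71, 150.87, 147.69),
    "FGC": (207.27, 215.96, 151.45, 148.28),
    "RG2": (235.22, 235.22, 231.91, 231.91),
    "FG2": (235.50, 235.50, 232.21, 232.21),
}

# Average SEPD over the 25 genotypes, per new location and model (g/m^2).
_SEPD = {
    "RC2": (29.49, 32.54, 28.92, 30.98),
    "RC1": (29.52, 32.50, 29.22, 31.26),
    "FGI1": (31.36, 37.77, 24.74, 33.16),
    "FGI2": (31.36, 37.77, 24.74, 33.16),
    "RC3": (36.85, 37.03, 29.61, 30.30),
    "RG1": (36.97, 36.97, 48.39, 48.39),
    "RGCQ": (36.97, 36.97, 48.41, 48.41),
    "RGC": (36.97, 36.97, 48.39, 48.39),
    "FG1": (40.03, 40.03, 51.53, 51.53),
    "FGCQ": (40.03, 40.03, 51.55, 51.55),
    "FGC": (40.03, 40.03, 51.53, 51.53),
    "FGI3": (41.62, 42.37, 29.79, 30.16),
    "RG2": (45.84, 45.84, 45.85, 45.85),
    "FG2": (49.55, 49.55, 49.66, 49.66),
}

# Leave-one-location-out MSEP of pairwise differences (g^2/m^4) and rank.
_MSEP = [
    ("RGCQ", 3681), ("RG1", 3681), ("RGC", 3681), ("RG2", 3688),
    ("RC2", 3797), ("RC3", 3839), ("RC1", 3848), ("FG2", 4000),
    ("FGCQ", 4008), ("FG1", 4008), ("FGC", 4008), ("FGI3", 4393),
    ("FGI1", 7217), ("FGI2", 7217),
]


def swedish_2016_sepv_averages() -> pd.DataFrame:
    """Average SEPV per new location and model; index model, columns the
    four new locations."""
    return pd.DataFrame.from_dict(
        _SEPV, orient="index", columns=["N01", "N02", "S01", "S02"])


def swedish_2016_sepd_averages() -> pd.DataFrame:
    """Average SEPD per new location and model."""
    return pd.DataFrame.from_dict(
        _SEPD, orient="index", columns=["N01", "N02", "S01", "S02"])


def swedish_2016_msep() -> pd.DataFrame:
    """MSEP model comparison: one row per model with its MSEP and rank."""
    df = pd.DataFrame(_MSEP, columns=["model", "msep"])
    df["rank"] = df["msep"].rank(method="min").astype(int)
    return df
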