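"""Synthetic zoned MET generator with recorded truth.

Emulates the structure of the Swedish official cultivar-testing series:
locations stratified into agro-ecological zones, alpha-design trials
(complete replicates partitioned into incomplete blocks), zone-specific
location and genotype x location variances, and a genotype response to a
location-specific soil covariate that may be fixed (population slope plus
zone-specific slope) and/or random (genotype- and genotype x zone-specific
random intercept/linear/quadratic coefficients with an unstructured 3x3
covariance).

Yields are generated as

    y = alpha + zeta_m + beta*x + gamma*x^2 + lambda_m*x      (fixed part)
        + g_i  (or a_i + b_i x + c_i x^2)                     (genotype)
        + (gz)_im  (or d_im + h_im x + p_im x^2)              (genotype x zone)
        + l_jm + (gl)_ijm + r_jkm + b_jklm + e_ijklm

with x the *scaled* response covariate of location j.  All random draws
come from named, seed-derived substreams (covariates, location effects,
genotype, genotype x zone, genotype x location, plot terms, then the new-
location substreams), so partial simulations are reproducible and
``simulate_met``/``simulate_new_locations`` can be called independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import CovariateTable, Dataset

__all__ = ["SimulationConfig", "TruthRecord", "simulate_met",
           "simulate_new_locations", "ConfigError"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# covariate sampling distributions: name -> (kind, par1, par2)
_DEFAULT_COVARIATES = {
    "clay": ("uniform", 10.0, 70.0),      # clay content, % of fine soil
    "ph": ("normal", 6.5, 0.5),           # topsoil pH
    "humus": ("lognormal", 0.9, 0.35),    # humus content, %
}


@dataclass
class SimulationConfig:
    """Generative truth for one simulated MET.

    Scalar variances are in (g/m^2)^2.  ``sigma2_location`` and
    ``sigma2_gl`` may be a single float (homogeneous) or a zone -> float
    mapping (zone-heterogeneous).  Supplying ``G_genotype`` (a PSD 3x3
    matrix over intercept/linear/quadratic coefficients) replaces the
    scalar genotype main effect by a random-coefficient polynomial in the
    scaled covariate; ``G_gz`` does the same for the genotype x zone term.
    """

    seed: int = 0
    zones: dict = field(default_factory=lambda: {"North": 6, "Middle": 6, "South": 6})
    n_new: dict = field(default_factory=lambda: {"North": 2, "South": 2})
    n_genotypes: int = 25
    n_replicates: int = 2
    block_size: int = 5
    covariates: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    response_covariate: str = "clay"
    response_shift: float = 40.0
    response_scale: float = 10.0
    intercept: float = 800.0
    zone_effects: dict = field(default_factory=lambda: {"North": -80.0, "Middle": 0.0,
                                                        "South": 60.0})
    beta: float = 15.0           # population linear slope on the scaled covariate
    gamma: float = -10.0         # population quadratic slope
    lambda_zone: dict = field(default_factory=lambda: {"North": -5.0, "Middle": 0.0,
                                                       "South": 5.0})
    sigma2_location: dict | float = field(
        default_factory=lambda: {"North": 25000.0, "Middle": 30000.0, "South": 16000.0})
    sigma2_genotype: float = 600.0
    sigma2_gz: float = 65.0
    sigma2_gl: dict | float = field(
        default_factory=lambda: {"North": 580.0, "Middle": 1150.0, "South": 1050.0})
    sigma2_rep: float = 400.0
    sigma2_block: float = 300.0
    sigma2_plot: float = 2500.0
    G_genotype: np.ndarray | None = None
    G_gz: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigError("need at least 2 genotypes")
        if self.block_size > self.n_genotypes:
            raise ConfigError("block_size cannot exceed the number of genotypes")
        if self.n_replicates < 1:
            raise ConfigError("need at least 1 replicate")
        for name in ("sigma2_genotype", "sigma2_gz", "sigma2_rep",
                     "sigma2_block", "sigma2_plot"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for name in ("sigma2_location", "sigma2_gl"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ConfigError(f"{name} must be nonnegative")
            if isinstance(v, dict):
                missing = sorted(set(self.zones) - set(v))
                if missing:
                    raise ConfigError(
                        f"{name} missing zone(s) {missing}; supply every "
                        "zone or a single homogeneous value")
        for name in ("G_genotype", "G_gz"):
            A = getattr(self, name)
            if A is not None:
                A = np.asarray(A, float)
                if A.shape != (3, 3) or not np.allclose(A, A.T):
                    raise ConfigError(f"{name} must be a symmetric 3x3 matrix")
                if np.linalg.eigvalsh(A).min() < -1e-8:
                    raise ConfigError(f"{name} must be positive semidefinite")
                setattr(self, name, A)
        if self.response_covariate not in self.covariates:
            raise ConfigError(
                f"response covariate {self.response_covariate!r} not in covariates")

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("G_genotype", "G_gz"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for k in ("G_genotype", "G_gz"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], float)
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TruthRecord:
    """Realised random effects and per-cell true genotype values.

    ``true_values`` holds, per (genotype, location), the conditional
    expectation of a plot given all location- and genotype-level effects,
    i.e. fixed part + genotype + genotype x zone + location + genotype x
    location (replicate, block and plot error excluded).
    """

    location_effects: dict
    genotype_effects: dict
    gz_effects: dict
    gl_effects: dict
    rc_genotype: pd.DataFrame | None
    rc_gz: pd.DataFrame | None
    true_values: pd.DataFrame
    fixed_part: dict

    def true_value(self, genotype: str, location: str) -> float:
        tv = self.true_values
        row = tv[(tv["genotype"] == genotype) & (tv["location"] == location)]
        return float(row["true_value"].iloc[0])

    def to_json(self, path) -> None:
        import json
        payload = {
            "location_effects": self.location_effects,
            "genotype_effects": self.genotype_effects,
            "gz_effects": {"|".join(k): v for k, v in self.gz_effects.items()},
            "gl_effects": {"|".join(k): v for k, v in self.gl_effects.items()},
            "true_values": self.true_values.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _zone_value(v, zone: str) -> float:
    return float(v[zone]) if isinstance(v, dict) else float(v)


def _location_ids(config: SimulationConfig, new: bool = False) -> list[tuple[str, str]]:
    """(location-id, zone) pairs; ids are zone-prefixed and unique."""
    counts = config.n_new if new else config.zones
    prefixes = {}
    for z in sorted(config.zones):
        p = z[:1].upper()
        prefixes[z] = p if p not in prefixes.values() else z
    out = []
    for z in sorted(counts):
        if z not in config.zones and not new:
            raise ConfigError(f"unknown zone {z!r}")
        tag = "X" if new else ""
        for i in range(1, int(counts[z]) + 1):
            out.append((f"{prefixes.get(z, z)}{tag}{i:02d}", z))
    return out


def _sample_covariates(config, rng, locations) -> pd.DataFrame:
    rows = {}
    for name, (kind, a, b) in config.covariates.items():
        if kind == "uniform":
            v = rng.uniform(a, b, len(locations))
        elif kind == "normal":
            v = rng.normal(a, b, len(locations))
        elif kind == "lognormal":
            v = rng.lognormal(a, b, len(locations))
        else:
            raise ConfigError(f"unknown covariate distribution {kind!r}")
        rows[name] = v
    df = pd.DataFrame(rows, index=[loc for loc, _ in locations])
    df.index.name = "location"
    df.insert(0, "zone", [z for _, z in locations])
    return df


def _scaled_x(config, cov_df, location) -> float:
    raw = float(cov_df.loc[location, config.response_covariate])
    return (raw - config.response_shift) / config.response_scale


def _genotype_labels(config) -> list[str]:
    width = max(2, len(str(config.n_genotypes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genotypes + 1)]


def _draw_genotype_terms(config) -> tuple[dict, pd.DataFrame | None]:
    genos = _genotype_labels(config)
    rng = _rng(config, 3)
    if config.G_genotype is not None:
        coef = rng.multivariate_normal(np.zeros(3), config.G_genotype, len(genos))
        df = pd.DataFrame(coef, index=genos, columns=["a", "b", "c"])
        return {}, df
    eff = rng.normal(0, np.sqrt(config.sigma2_genotype), len(genos))
    return dict(zip(genos, eff)), None


def _draw_gz_terms(config) -> tuple[dict, pd.DataFrame | None]:
    genos = _genotype_labels(config)
    zones = sorted(config.zones)
    rng = _rng(config, 4)
    keys = [(g, z) for g in genos for z in zones]
    if config.G_gz is not None:
        coef = rng.multivariate_normal(np.zeros(3), config.G_gz, len(keys))
        df = pd.DataFrame(coef, index=pd.MultiIndex.from_tuples(keys),
                          columns=["d", "h", "p"])
        return {}, df
    eff = rng.normal(0, np.sqrt(config.sigma2_gz), len(keys))
    return dict(zip(keys, eff)), None


def _genotype_value(config, g, zone, x, g_eff, rc_g, gz_eff, rc_gz) -> float:
    """Genotype + genotype x zone contribution at scaled covariate x."""
    val = 0.0
    if rc_g is not None:
        a, b, c = rc_g.loc[g]
        val += a + b * x + c * x * x
    else:
        val += g_eff[g]
    if rc_gz is not None:
        d, h, p = rc_gz.loc[(g, zone)]
        val += d + h * x + p * x * x
    else:
        val += gz_eff[(g, zone)]
    return float(val)


def _fixed_part(config, zone, x) -> float:
    return (config.intercept + float(config.zone_effects.get(zone, 0.0))
            + config.beta * x + config.gamma * x * x
            + float(config.lambda_zone.get(zone, 0.0)) * x)


def simulate_met(config: SimulationConfig) -> tuple[Dataset, CovariateTable, TruthRecord]:
    """Simulate the tested locations of a zoned MET.

    Returns the plot-level :class:`~zonemet.data.Dataset`, the covariate
    table of the tested locations, and the :class:`TruthRecord` of realised
    effects.  Identical configs (including the seed) give byte-identical
    CSV exports.
    """
    locations = _location_ids(config)
    cov_df = _sample_covariates(config, _rng(config, 1), locations)
    loc_rng = _rng(config, 2)
    loc_eff = {loc: loc_rng.normal(0, np.sqrt(_zone_value(config.sigma2_location, z)))
               for loc, z in locations}
    g_eff, rc_g = _draw_genotype_terms(config)
    gz_eff, rc_gz = _draw_gz_terms(config)
    genos = _genotype_labels(config)
    gl_rng = _rng(config, 5)
    gl_eff = {(g, loc): gl_rng.normal(0, np.sqrt(_zone_value(config.sigma2_gl, z)))
              for loc, z in locations for g in genos}
    plot_rng = _rng(config, 6)

    records, truth_rows = [], []
    cell_value: dict[tuple[str, str], float] = {}
    for loc, zone in locations:
        x = _scaled_x(config, cov_df, loc)
        fixed = _fixed_part(config, zone, x)
        for g in genos:
            tv = (fixed + _genotype_value(config, g, zone, x, g_eff, rc_g,
                                          gz_eff, rc_gz)
                  + loc_eff[loc] + gl_eff[(g, loc)])
            cell_value[(g, loc)] = tv
            truth_rows.append({"genotype": g, "location": loc, "zone": zone,
                               "true_value": tv})
        for k in range(1, config.n_replicates + 1):
            rep_eff = plot_rng.normal(0, np.sqrt(config.sigma2_rep))
            order = list(plot_rng.permutation(genos))
            n_blocks = int(np.ceil(len(order) / config.block_size))
            for bi in range(n_blocks):
                members = order[bi * config.block_size:(bi + 1) * config.block_size]
                blk_eff = plot_rng.normal(0, np.sqrt(config.sigma2_block))
                for g in members:
                    e = plot_rng.normal(0, np.sqrt(config.sigma2_plot))
                    records.append({
                        "location": loc, "zone": zone, "replicate": f"R{k}",
                        "block": f"B{bi + 1}", "genotype": g,
                        "yield": cell_value[(g, loc)] + rep_eff + blk_eff + e})
    dataset = Dataset(pd.DataFrame(records))
    cov_table = CovariateTable(cov_df.assign(is_new=False).reset_index())
    truth = TruthRecord(
        location_effects=loc_eff, genotype_effects=g_eff, gz_effects=gz_eff,
        gl_effects=gl_eff, rc_genotype=rc_g, rc_gz=rc_gz,
        true_values=pd.DataFrame(truth_rows),
        fixed_part={loc: _fixed_part(config, z, _scaled_x(config, cov_df, loc))
                    for loc, z in locations})
    return dataset, cov_table, truth


def simulate_new_locations(config: SimulationConfig) -> tuple[CovariateTable, TruthRecord]:
    """Simulate the *new* (untested) locations of the same simulated world.

    New locations receive covariate values plus realised -- but unobserved
    -- location and genotype x location effects, so empirical coverage of
    prediction intervals can be checked against the returned truth.  The
    genotype-level effects are shared with :func:`simulate_met` for the
    same config (same seed-derived substreams).
    """
    new_locs = _location_ids(config, new=True)
    if not new_locs:
        empty = pd.DataFrame(columns=["location", "zone", "is_new"]).set_index("location")
        return CovariateTable(empty.assign(zone=pd.Series(dtype=str))), TruthRecord(
            {}, {}, {}, {}, None, None,
            pd.DataFrame(columns=["genotype", "location", "zone", "true_value"]), {})
    cov_df = _sample_covariates(config, _rng(config, 7), new_locs)
    loc_rng = _rng(config, 8)
    loc_eff = {loc: loc_rng.normal(0, np.sqrt(_zone_value(config.sigma2_location, z)))
               for loc, z in new_locs}
    g_eff, rc_g = _draw_genotype_terms(config)
    gz_eff, rc_gz = _draw_gz_terms(config)
    genos = _genotype_labels(config)
    gl_rng = _rng(config, 9)
    gl_eff = {(g, loc): gl_rng.normal(0, np.sqrt(_zone_value(config.sigma2_gl, z)))
              for loc, z in new_locs for g in genos}
    truth_rows = []
    for loc, zone in new_locs:
        x = _scaled_x(config, cov_df, loc)
        fixed = _fixed_part(config, zone, x)
        for g in genos:
            truth_rows.append({
                "genotype": g, "location": loc, "zone": zone,
                "true_value": fixed + _genotype_value(
                    config, g, zone, x, g_eff, rc_g, gz_eff, rc_gz)
                + loc_eff[loc] + gl_eff[(g, loc)]})
    table = CovariateTable(cov_df.assign(is_new=True).reset_index())
    truth = TruthRecord(
        location_effects=loc_eff, genotype_effects=g_eff, gz_effects=gz_eff,
        gl_effects=gl_eff, rc_genotype=rc_g, rc_gz=rc_gz,
        true_values=pd.DataFrame(truth_rows),
        fixed_part={loc: _fixed_part(config, z, _scaled_x(config, cov_df, loc))
                    for loc, z in new_locs})
    return table, truth


def merged_covariates(tested: CovariateTable, new: CovariateTable) -> CovariateTable:
    """Concatenate tested and new covariate rows into one table."""
    if new.table.empty:
        return tested
    return CovariateTable(pd.concat([tested.table, new.table]).reset_index())
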