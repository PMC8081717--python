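"""Design-matrix construction for stage-II models (adjusted means with a
forwarded R matrix), the covariate-screening model, and the equivalent
single-stage plot-level model.

Fixed-effect columns use full indicator (over-parameterised) coding; the
engine works with generalised inverses and only estimable functions are
ever reported, so no identifiability constraints are needed.  Columns are
labelled with structured tuples, e.g. ``("zone", m)``, ``("gxz", i, m)``,
``("rc_gxz", i, m, r)`` with ``r`` in {0, 1, 2} the polynomial degree, and
the prediction module assembles K/M coefficient vectors by label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import CovariateSpec, ModelSpec
from .engine import MixedModel, RandomTerm

__all__ = ["build_stage2_design", "build_plot_design", "build_selection_design"]


def _indicator(values: pd.Series, levels: list) -> np.ndarray:
    codes = pd.Categorical(values, categories=levels).codes
    out = np.zeros((len(values), len(levels)))
    out[np.arange(len(values)), codes] = 1.0
    return out


def _fixed_columns(df: pd.DataFrame, x: np.ndarray | None, spec_fixed,
                   genotypes, zones):
    cols, labels = [], []
    gi = _indicator(df["genotype"], genotypes)
    zi = _indicator(df["zone"], zones)
    for term in spec_fixed:
        if term == "intercept":
            cols.append(np.ones((len(df), 1))); labels.append([("intercept",)])
        elif term == "zone":
            cols.append(zi); labels.append([("zone", m) for m in zones])
        elif term == "cov_lin":
            cols.append(x[:, None]); labels.append([("cov_lin",)])
        elif term == "cov_quad":
            cols.append((x ** 2)[:, None]); labels.append([("cov_quad",)])
        elif term == "zone_cov_lin":
            cols.append(zi * x[:, None])
            labels.append([("zone_cov_lin", m) for m in zones])
        elif term == "genotype":
            cols.append(gi); labels.append([("genotype", g) for g in genotypes])
        elif term in ("geno_cov_lin", "geno_cov_quad"):
            deg = 1 if term.endswith("lin") else 2
            cols.append(gi * (x ** deg)[:, None])
            labels.append([(term, g) for g in genotypes])
        elif term == "gxz":
            blocks, labs = [], []
            for m in zones:
                blocks.append(gi * zi[:, [zones.index(m)]])
                labs.extend(("gxz", g, m) for g in genotypes)
            cols.append(np.hstack(blocks)); labels.append(labs)
        elif term in ("gxz_cov_lin", "gxz_cov_quad"):
            deg = 1 if term.endswith("lin") else 2
            blocks, labs = [], []
            for m in zones:
                blocks.append(gi * zi[:, [zones.index(m)]] * (x ** deg)[:, None])
                labs.extend((term, g, m) for g in genotypes)
            cols.append(np.hstack(blocks)); labels.append(labs)
        else:
            raise KeyError(f"unknown fixed term {term!r}")
    X = np.hstack(cols)
    flat = [lab for ls in labels for lab in ls]
    return X, flat


def _random_terms(df: pd.DataFrame, x: np.ndarray | None, spec_random,
                  genotypes, zones, locations, loc_zone: dict):
    gi = _indicator(df["genotype"], genotypes)
    li = _indicator(df["location"], locations)
    zi = _indicator(df["zone"], zones)
    terms = []
    for ts in spec_random:
        if ts.name == "location":
            Z, labels = li, [(l,) for l in locations]
            groups = [loc_zone[l] for l in locations]
        elif ts.name == "genotype":
            Z, labels, groups = gi, [(g,) for g in genotypes], None
        elif ts.name == "gxz":
            blocks, labels = [], []
            for m in zones:
                blocks.append(gi * zi[:, [zones.index(m)]])
                labels.extend((g, m) for g in genotypes)
            Z, groups = np.hstack(blocks), None
        elif ts.name == "gxl":
            blocks, labels, groups = [], [], []
            for l in locations:
                blocks.append(gi * li[:, [locations.index(l)]])
                labels.extend((g, l) for g in genotypes)
                groups.extend(loc_zone[l] for g in genotypes)
            Z = np.hstack(blocks)
        elif ts.name == "rc_genotype":
            blocks, labels = [], []
            for g in genotypes:
                ind = gi[:, [genotypes.index(g)]]
                blocks.append(np.hstack([ind, ind * x[:, None],
                                         ind * (x ** 2)[:, None]]))
                labels.extend((g, r) for r in range(3))
            Z, groups = np.hstack(blocks), None
        elif ts.name == "rc_gxz":
            blocks, labels = [], []
            for g in genotypes:
                for m in zones:
                    ind = gi[:, [genotypes.index(g)]] * zi[:, [zones.index(m)]]
                    blocks.append(np.hstack([ind, ind * x[:, None],
                                             ind * (x ** 2)[:, None]]))
                    labels.extend((g, m, r) for r in range(3))
            Z, groups = np.hstack(blocks), None
        else:
            raise KeyError(f"unknown random term {ts.name!r}")
        structure = {"scalar": "scalar", "zone_het": "groups",
                     "us3": "us3", "diag3": "diag3"}[ts.structure]
        terms.append(RandomTerm(
            name=ts.name, Z=Z, labels=labels, structure=structure,
            col_group=np.asarray(groups) if structure == "groups" else None,
            group_names=sorted(set(groups)) if structure == "groups" else []))
    return terms


def _scaled_x(spec: ModelSpec, df: pd.DataFrame, covariates, tested_locations):
    """Per-row scaled covariate; scaling statistics frozen from the tested
    locations.  Returns (x, frozen CovariateSpec)."""
    if spec.covariate is None:
        return None, None
    cs = spec.covariate
    if cs.name not in covariates.covariate_names:
        raise KeyError(f"covariate {cs.name!r} missing from covariate table")
    tested_vals = [covariates.value(l, cs.name) for l in tested_locations]
    frozen = cs.freeze(tested_vals)
    raw = np.array([covariates.value(l, cs.name) for l in df["location"]])
    return frozen.transform(raw), frozen


def build_stage2_design(spec: ModelSpec, stage2, covariates=None) -> MixedModel:
    """Build the stage-II mixed model for one catalogued model.

    ``stage2`` is a :class:`~zonemet.stage1.Stage2Data`; its forwarded
    block-diagonal R is treated as known.  The returned
    :class:`~zonemet.engine.MixedModel` carries ``spec``, the frozen
    covariate spec, and the level rosters needed for prediction.
    """
    df = stage2.df
    genotypes, zones = stage2.genotypes, stage2.zone_list
    locations, loc_zone = stage2.locations, stage2.zones
    if spec.uses_covariate and covariates is None:
        raise ValueError(f"model {spec.model_id} requires a covariate table")
    x, frozen = _scaled_x(spec, df, covariates, locations)
    X, fixed_labels = _fixed_columns(df, x, spec.fixed, genotypes, zones)
    terms = _random_terms(df, x, spec.random, genotypes, zones, locations, loc_zone)
    model = MixedModel(df["mean"].to_numpy(), X, terms, R=stage2.R,
                       fixed_labels=fixed_labels)
    model.spec = spec
    model.covariate = frozen
    model.genotypes, model.zone_list = genotypes, zones
    model.locations = locations
    return model


def build_plot_design(spec: ModelSpec, dataset, covariates=None) -> MixedModel:
    """Single-stage analogue: the stage-II model fitted directly to plot
    data, with random replicate and incomplete-block effects added and the
    plot residual variance estimated.  Used to verify the fully-efficient
    two-stage scheme."""
    df = dataset.plots.rename(columns={"yield": "mean"})
    genotypes = sorted(df["genotype"].unique())
    zones = sorted(df["zone"].unique())
    locations = sorted(df["location"].unique())
    loc_zone = dataset.zones
    x, frozen = _scaled_x(spec, df, covariates, locations)
    X, fixed_labels = _fixed_columns(df, x, spec.fixed, genotypes, zones)
    terms = _random_terms(df, x, spec.random, genotypes, zones, locations, loc_zone)

    rep_key = df["location"] + "/" + df["replicate"]
    rep_levels = sorted(rep_key.unique())
    terms.append(RandomTerm("replicate", _indicator(rep_key, rep_levels),
                            [(r,) for r in rep_levels], "scalar"))
    blk_key = rep_key + "/" + df["block"]
    blk_levels = sorted(blk_key.unique())
    terms.append(RandomTerm("block", _indicator(blk_key, blk_levels),
                            [(b,) for b in blk_levels], "scalar"))

    model = MixedModel(df["mean"].to_numpy(), X, terms, R=None,
                       fixed_labels=fixed_labels)
    model.spec = spec
    model.covariate = frozen
    model.genotypes, model.zone_list = genotypes, zones
    model.locations = locations
    return model


def build_selection_design(stage2, covariates, candidate_specs,
                           quads: list[str]):
    """Extended fixed-genotype baseline for covariate screening: the FG1
    fixed part plus a scaled linear term for every candidate and a
    quadratic term for the candidates in ``quads``.

    Returns ``(MixedModel, meta)`` where ``meta['containment_ddf']`` is
    J minus the rank of the location-level fixed design.
    """
    df = stage2.df
    genotypes, zones = stage2.genotypes, stage2.zone_list
    locations, loc_zone = stage2.locations, stage2.zones
    X, fixed_labels = _fixed_columns(df, None, ("intercept", "zone", "genotype",
                                                "gxz"), genotypes, zones)
    extra_cols, extra_labels = [], []
    for cs in candidate_specs:
        raw = np.array([covariates.value(l, cs.name) for l in df["location"]])
        xs = cs.transform(raw)
        extra_cols.append(xs[:, None])
        extra_labels.append(("sel_lin", cs.name))
        if cs.name in quads:
            extra_cols.append((xs ** 2)[:, None])
            extra_labels.append(("sel_quad", cs.name))
    if extra_cols:
        X = np.hstack([X] + extra_cols)
        fixed_labels = fixed_labels + extra_labels
    # baseline random structure: zone-heterogeneous location and g x location
    from .catalog import RandomTermSpec
    terms = _random_terms(df, None,
                          (RandomTermSpec("location", "zone_het"),
                           RandomTermSpec("gxl", "zone_het")),
                          genotypes, zones, locations, loc_zone)
    model = MixedModel(df["mean"].to_numpy(), X, terms, R=stage2.R,
                       fixed_labels=fixed_labels)
    # containment-style denominator df: location-level design rank
    loc_level = [i for i, lab in enumerate(fixed_labels)
                 if lab[0] in ("intercept", "zone", "sel_lin", "sel_quad")]
    per_loc = pd.DataFrame(X[:, loc_level]).groupby(
        df["location"].to_numpy()).first().to_numpy()
    ddf = len(locations) - int(np.linalg.matrix_rank(per_loc))
    return model, {"containment_ddf": max(ddf, 0)}
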