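"""Catalog of the fourteen stage-II models, covariate scaling, and the
F-test covariate screening procedure.

Seven fixed-genotype (FG) and seven random-genotype (RG/RC) models are
available.  All share a random location effect nested in zone and a random
genotype x location effect; they differ in whether genotype and genotype x
zone enter as fixed or random, whether a location covariate enters the
fixed part (linear, or linear + quadratic with a zone-specific linear
slope), whether genotype-specific covariate responses are fixed
regressions (FGI models) or random coefficients (RC models), and whether
location-level variances are zone-heterogeneous or homogeneous.

====== ===========================================================
FG1    baseline, zone-heterogeneous location and g x location variances
FG2    as FG1 with homogeneous variances
FGC    + fixed linear covariate trend (population and zone slopes)
FGCQ   + fixed quadratic covariate term (no zone-specific quadratic)
FGI1   + fixed genotype- and genotype x zone-specific covariate slopes
FGI2   FGI1 without the genotype-specific slopes
FGI3   FGI1 without the genotype x zone-specific slopes
RG1    baseline random-genotype model
RG2    as RG1 with homogeneous location-level variances
RGC    + fixed linear covariate trend
RGCQ   + fixed quadratic covariate term
RC1    random intercept/linear/quadratic coefficients for genotype AND
       genotype x zone, each with an unstructured 3x3 covariance
RC2    RC1 with the genotype-main-effect coefficients dropped (scalar g)
RC3    RC1 with the genotype x zone coefficients dropped (scalar g x zone)
====== ===========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import fit_reml, EstimabilityError

__all__ = ["MODEL_IDS", "CovariateSpec", "RandomTermSpec", "ModelSpec",
           "make_model", "scale_covariate", "select_covariates",
           "SelectionResult", "dump_catalog"]

MODEL_IDS = ["FG1", "FG2", "FGC", "FGCQ", "FGI1", "FGI2", "FGI3",
             "RG1", "RG2", "RGC", "RGCQ", "RC1", "RC2", "RC3"]

_NO_COVARIATE = {"FG1", "FG2", "RG1", "RG2"}


@dataclass
class CovariateSpec:
    """A named location covariate with a frozen scaling.

    ``shift_scale`` maps x -> (x - shift)/scale with fixed constants (the
    conventional clay scaling is (clay - 40)/10); ``standardise`` centres
    and scales by the mean/sd of the *tested* locations, frozen at first
    use so new locations are transformed with the tested-location
    statistics; ``none`` leaves values untouched.
    """

    name: str
    scaling: str = "shift_scale"
    shift: float | None = 40.0
    scale: float | None = 10.0

    def __post_init__(self) -> None:
        if self.scaling not in ("shift_scale", "standardise", "none"):
            raise ValueError(f"unknown scaling {self.scaling!r}")

    def freeze(self, tested_values) -> "CovariateSpec":
        """Return a spec with scaling statistics frozen from tested values."""
        v = np.asarray(tested_values, float)
        if self.scaling == "standardise":
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            if sd == 0.0:
                raise ValueError(
                    f"covariate {self.name!r} is constant across tested locations")
            return replace(self, shift=float(v.mean()), scale=sd)
        return self

    @property
    def frozen(self) -> bool:
        return self.scaling == "none" or (self.shift is not None and
                                          self.scale is not None)

    def transform(self, values):
        if self.scaling == "none":
            return np.asarray(values, float)
        if not self.frozen:
            raise ValueError("scaling statistics not frozen; call freeze() first")
        return (np.asarray(values, float) - self.shift) / self.scale


def scale_covariate(values, spec: CovariateSpec, tested_values=None):
    """Scale covariate values, freezing standardisation statistics from
    ``tested_values`` (defaults to ``values``)."""
    frozen = spec.freeze(values if tested_values is None else tested_values)
    return frozen.transform(values)


@dataclass(frozen=True)
class RandomTermSpec:
    name: str        # location | genotype | gxz | gxl | rc_genotype | rc_gxz
    structure: str   # scalar | zone_het | us3 | diag3


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one stage-II model."""

    model_id: str
    fixed: tuple[str, ...]
    random: tuple[RandomTermSpec, ...]
    covariate: CovariateSpec | None = None

    @property
    def genotype_fixed(self) -> bool:
        return "genotype" in self.fixed or "gxz" in self.fixed

    @property
    def uses_covariate(self) -> bool:
        return any("cov" in t for t in self.fixed) or any(
            t.name.startswith("rc_") for t in self.random)

    def random_term(self, name: str) -> RandomTermSpec:
        for t in self.random:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def gl_term(self) -> RandomTermSpec:
        return self.random_term("gxl")


_FG_BASE = ("intercept", "zone", "genotype", "gxz")
_COV_LIN = ("cov_lin", "zone_cov_lin")

_LOC_HET = RandomTermSpec("location", "zone_het")
_LOC_HOM = RandomTermSpec("location", "scalar")
_GL_HET = RandomTermSpec("gxl", "zone_het")
_GL_HOM = RandomTermSpec("gxl", "scalar")
_G = RandomTermSpec("genotype", "scalar")
_GZ = RandomTermSpec("gxz", "scalar")


def _catalog(rc_structure: str = "us3") -> dict[str, tuple]:
    rc_g = RandomTermSpec("rc_genotype", rc_structure)
    rc_gz = RandomTermSpec("rc_gxz", rc_structure)
    return {
        "FG1": (_FG_BASE, (_LOC_HET, _GL_HET)),
        "FG2": (_FG_BASE, (_LOC_HOM, _GL_HOM)),
        "FGC": (("intercept", "cov_lin", "zone", "zone_cov_lin",
                 "genotype", "gxz"), (_LOC_HET, _GL_HET)),
        "FGCQ": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin",
                  "genotype", "gxz"), (_LOC_HET, _GL_HET)),
        "FGI1": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin",
                  "genotype", "geno_cov_lin", "geno_cov_quad",
                  "gxz", "gxz_cov_lin", "gxz_cov_quad"), (_LOC_HET, _GL_HET)),
        "FGI2": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin",
                  "genotype",
                  "gxz", "gxz_cov_lin", "gxz_cov_quad"), (_LOC_HET, _GL_HET)),
        "FGI3": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin",
                  "genotype", "geno_cov_lin", "geno_cov_quad",
                  "gxz"), (_LOC_HET, _GL_HET)),
        "RG1": (("intercept", "zone"), (_LOC_HET, _G, _GZ, _GL_HET)),
        "RG2": (("intercept", "zone"), (_LOC_HOM, _G, _GZ, _GL_HOM)),
        "RGC": (("intercept", "cov_lin", "zone", "zone_cov_lin"),
                (_LOC_HET, _G, _GZ, _GL_HET)),
        "RGCQ": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin"),
                 (_LOC_HET, _G, _GZ, _GL_HET)),
        "RC1": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin"),
                (_LOC_HET, rc_g, rc_gz, _GL_HET)),
        "RC2": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin"),
                (_LOC_HET, _G, rc_gz, _GL_HET)),
        "RC3": (("intercept", "cov_lin", "cov_quad", "zone", "zone_cov_lin"),
                (_LOC_HET, rc_g, _GZ, _GL_HET)),
    }


def make_model(model_id: str, covariate: CovariateSpec | None = None,
               rc_structure: str = "us3") -> ModelSpec:
    """Instantiate one of the fourteen catalogued models.

    ``rc_structure`` may be set to ``"diag3"`` to restrict random-
    coefficient covariances to a diagonal matrix -- useful only to
    demonstrate that the diagonal restriction loses invariance under
    covariate translation.
    """
    if model_id not in MODEL_IDS:
        raise KeyError(f"unknown model id {model_id!r}; choose from {MODEL_IDS}")
    if model_id not in _NO_COVARIATE and covariate is None:
        raise ValueError(f"model {model_id} requires a covariate")
    fixed, random = _catalog(rc_structure)[model_id]
    return ModelSpec(model_id=model_id, fixed=fixed, random=tuple(random),
                     covariate=None if model_id in _NO_COVARIATE else covariate)


def dump_catalog(rc_structure: str = "us3") -> dict:
    """Machine-readable catalog (model id -> fixed terms and random
    terms with covariance structures), e.g. for audit as JSON."""
    return {mid: {"fixed": list(fixed),
                  "random": [{"term": t.name, "structure": t.structure}
                             for t in random]}
            for mid, (fixed, random) in _catalog(rc_structure).items()}


@dataclass
class SelectionResult:
    """Log of the covariate-screening tests.

    ``tests`` has one row per (covariate, degree, stage) with the Wald
    statistic, numerator/denominator df, p-value and the kept/dropped
    decision; ``kept`` maps covariate name to 'quadratic', 'linear' or
    None; ``aliased`` lists covariates dropped for degeneracy or aliasing.
    """

    tests: pd.DataFrame
    kept: dict[str, str | None]
    aliased: list[str] = field(default_factory=list)
    ddf_method: str = "containment"

    @property
    def kept_covariates(self) -> list[str]:
        return [c for c, deg in self.kept.items() if deg]


def _wald_test(fit, label: tuple, ddf: float | None):
    """Marginal Wald test of a single fixed-effect coefficient."""
    k = fit.fixed_index(label)
    est = fit.beta[k]
    var = fit.C11[k, k]
    if var <= 0:
        return np.nan, np.nan
    F = est * est / var
    if ddf is not None and ddf >= 1:
        p = float(stats.f.sf(F, 1, ddf))
    else:
        p = float(stats.chi2.sf(F, 1))
    return float(F), p


def select_covariates(stage2, covariates, candidates, alpha: float = 0.05,
                      ddf_method: str = "containment") -> SelectionResult:
    """Screen candidate covariates by Wald F tests in an extended
    fixed-genotype baseline model.

    Each candidate contributes scaled linear and quadratic fixed terms to
    the baseline fixed-genotype model (zone-heterogeneous location and
    genotype x location variances).  Quadratic terms are tested first; a
    retained quadratic keeps its linear term (polynomial hierarchy);
    linear terms are tested, after refitting, only for candidates whose
    quadratic was dropped.  The denominator df default is a
    containment-style approximation, J minus the rank of the
    location-level fixed design; ``ddf_method="chisq"`` uses large-sample
    Wald chi-square tests instead.
    """
    from .design import build_selection_design

    tested = stage2.locations
    frozen, aliased = {}, []
    for c in candidates:
        vals = np.array([covariates.value(l, c.name) for l in tested])
        if np.isclose(vals.std(), 0.0):
            aliased.append(c.name)
            continue
        frozen[c.name] = c.freeze(vals)

    rows, kept = [], {c.name: None for c in candidates}
    for name in aliased:
        rows.append({"covariate": name, "degree": "linear", "stage": "prescreen",
                     "statistic": np.nan, "ndf": np.nan, "ddf": np.nan,
                     "p_value": np.nan, "kept": False, "note": "aliased/constant"})

    def _fit_with(quads: list[str]):
        model, meta = build_selection_design(stage2, covariates,
                                             list(frozen.values()), quads)
        return fit_reml(model), meta

    names = list(frozen)
    if not names:
        return SelectionResult(pd.DataFrame(rows), kept, aliased, ddf_method)

    fit, meta = _fit_with(quads=names)
    ddf = meta["containment_ddf"] if ddf_method == "containment" else None

    kept_quad = []
    for name in names:
        try:
            F, p = _wald_test(fit, ("sel_quad", name), ddf)
            note = ""
        except EstimabilityError:
            F, p, note = np.nan, np.nan, "non-estimable"
        keep = bool(p < alpha) if np.isfinite(p) else False
        rows.append({"covariate": name, "degree": "quadratic", "stage": "joint",
                     "statistic": F, "ndf": 1, "ddf": ddf if ddf else np.nan,
                     "p_value": p, "kept": keep, "note": note})
        if keep:
            kept_quad.append(name)
            kept[name] = "quadratic"

    # refit without the dropped quadratics, then test the linear terms of
    # candidates whose quadratic was dropped
    fit2, meta2 = _fit_with(quads=kept_quad)
    ddf2 = meta2["containment_ddf"] if ddf_method == "containment" else None
    for name in names:
        if name in kept_quad:
            continue
        F, p = _wald_test(fit2, ("sel_lin", name), ddf2)
        keep = bool(p < alpha) if np.isfinite(p) else False
        rows.append({"covariate": name, "degree": "linear", "stage": "after-drop",
                     "statistic": F, "ndf": 1, "ddf": ddf2 if ddf2 else np.nan,
                     "p_value": p, "kept": keep, "note": ""})
        if keep:
            kept[name] = "linear"

    return SelectionResult(pd.DataFrame(rows), kept, aliased, ddf_method)
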