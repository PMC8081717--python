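"""Zone-based prediction of genotype performance in new locations.

A new location is characterised only by its zone and covariate values.
The target of prediction is

    w = K'beta + M'u + M0'u0,

where K selects the target zone's fixed effects (with the new location's
scaled covariate values where the model has covariate terms), M selects
the estimable genotype-level random effects for that zone (genotype main
effect, genotype x zone, and for random-coefficient terms the triplet
weights 1, x, x^2), and u0 holds the two *unobservable* new-location
effects -- the location main effect and the genotype x location
interaction -- with covariance G0 = diag(sigma2_l, sigma2_gl) taken from
the target zone's estimates.  The BLUP of M0'u0 is zero, so the point
prediction is eta_hat = K'beta_hat + M'u_hat, and since u0 is independent
of the data,

    SEPV = sqrt( var(eta_hat) + M0' G0 M0 ),

with var(eta_hat) the prediction-error variance from the inverse MME
coefficient matrix.  For a pairwise genotype difference the location main
effect cancels and two independent genotype x location effects remain:

    SEPD = sqrt( VDIFF(eta_hat) + 2 * sigma2_gl ).

Prediction intervals use standard-normal quantiles: eta_hat +- z * SEPV
(and DIFF +- z * SEPD for differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .engine import FitResult, pev

__all__ = ["PredictableFunction", "NewLocationPrediction", "PairwiseTable",
           "build_predictable_function", "predict_new_location",
           "pairwise_differences", "prediction_interval"]


@dataclass
class PredictableFunction:
    """Coefficients of one genotype's predictable function in a new
    location: K over fixed effects, M over estimable random effects, M0
    over the unobservable new-location effects with covariance G0."""

    K: np.ndarray
    M: np.ndarray
    M0: np.ndarray
    G0: np.ndarray
    genotype: str
    zone: str
    x: float | None


@dataclass
class NewLocationPrediction:
    """Per-genotype predictions for one new location."""

    table: pd.DataFrame       # genotype, eta, sepv, lower, upper
    model_id: str
    location: str
    zone: str
    alpha: float
    covariate_value: float | None


@dataclass
class PairwiseTable:
    """Predicted pairwise genotype differences for one new location."""

    table: pd.DataFrame       # genotype_i, genotype_j, diff, sepd, lower, upper
    model_id: str
    location: str
    zone: str
    alpha: float

    @property
    def genotypes(self) -> list[str]:
        return sorted(set(self.table["genotype_i"]) | set(self.table["genotype_j"]))


def prediction_interval(center: float, se: float, alpha: float):
    """Normal-quantile interval ``center +- z_{1-alpha/2} * se``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if se < 0.0:
        raise ValueError("standard error must be nonnegative")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return center - z * se, center + z * se


def _location_info(fit: FitResult, covariates, location: str):
    """Zone and scaled covariate value of a (new) location."""
    spec = fit.model.spec
    zone = covariates.zone_of(location)
    if zone not in fit.model.zone_list:
        raise ValueError(
            f"zone {zone!r} of location {location!r} absent from training data")
    x = None
    if spec.covariate is not None:
        frozen = fit.model.covariate
        x = float(frozen.transform([covariates.value(location, frozen.name)])[0])
    elif any(t.name.startswith("rc_") for t in spec.random):
        raise ValueError("random-coefficient model without a covariate spec")
    return zone, x


def _g0(fit: FitResult, zone: str) -> np.ndarray:
    spec = fit.model.spec
    loc_ts = spec.random_term("location")
    gl_ts = spec.gl_term
    s2_l = fit.variance("location", zone if loc_ts.structure == "zone_het" else None)
    s2_gl = fit.variance("gxl", zone if gl_ts.structure == "zone_het" else None)
    return np.diag([s2_l, s2_gl])


def build_predictable_function(fit: FitResult, genotype: str, zone: str,
                               x: float | None) -> PredictableFunction:
    """K/M/M0 coefficient vectors for one genotype in a new location of
    the given zone with scaled covariate value ``x``."""
    spec = fit.model.spec
    K_entries: dict[tuple, float] = {}
    for term in spec.fixed:
        if term == "intercept":
            K_entries[("intercept",)] = 1.0
        elif term == "zone":
            K_entries[("zone", zone)] = 1.0
        elif term == "cov_lin":
            K_entries[("cov_lin",)] = x
        elif term == "cov_quad":
            K_entries[("cov_quad",)] = x * x
        elif term == "zone_cov_lin":
            K_entries[("zone_cov_lin", zone)] = x
        elif term == "genotype":
            K_entries[("genotype", genotype)] = 1.0
        elif term == "gxz":
            K_entries[("gxz", genotype, zone)] = 1.0
        elif term == "geno_cov_lin":
            K_entries[("geno_cov_lin", genotype)] = x
        elif term == "geno_cov_quad":
            K_entries[("geno_cov_quad", genotype)] = x * x
        elif term == "gxz_cov_lin":
            K_entries[("gxz_cov_lin", genotype, zone)] = x
        elif term == "gxz_cov_quad":
            K_entries[("gxz_cov_quad", genotype, zone)] = x * x
    M_entries: dict[tuple, float] = {}
    for ts in spec.random:
        if ts.name == "genotype":
            M_entries[("genotype", genotype)] = 1.0
        elif ts.name == "gxz":
            M_entries[("gxz", genotype, zone)] = 1.0
        elif ts.name == "rc_genotype":
            for r in range(3):
                M_entries[("rc_genotype", genotype, r)] = x ** r
        elif ts.name == "rc_gxz":
            for r in range(3):
                M_entries[("rc_gxz", genotype, zone, r)] = x ** r
        # location and gxl effects of a *new* location are not estimable
    return PredictableFunction(
        K=fit.K_vector(K_entries), M=fit.M_vector(M_entries),
        M0=np.array([1.0, 1.0]), G0=_g0(fit, zone),
        genotype=genotype, zone=zone, x=x)


def predict_new_location(fit: FitResult, covariates, location: str,
                         alpha: float = 0.05) -> NewLocationPrediction:
    """Predict every genotype's performance in a new location.

    ``covariates`` must contain the location's zone and covariate values;
    the covariate is transformed with the scaling frozen from the tested
    locations at fit time.
    """
    zone, x = _location_info(fit, covariates, location)
    rows = []
    for g in fit.model.genotypes:
        pf = build_predictable_function(fit, g, zone, x)
        eta = float(pf.K @ fit.beta + pf.M @ fit.u)
        var_eta = pev(fit, pf.K, pf.M)
        sepv = float(np.sqrt(var_eta + pf.M0 @ pf.G0 @ pf.M0))
        lo, hi = prediction_interval(eta, sepv, alpha)
        rows.append({"genotype": g, "eta": eta, "sepv": sepv,
                     "lower": lo, "upper": hi})
    return NewLocationPrediction(pd.DataFrame(rows), fit.model.spec.model_id,
                                 location, zone, alpha, x)


def pairwise_differences(fit: FitResult, covariates, location: str,
                         alpha: float = 0.05) -> PairwiseTable:
    """Predicted pairwise genotype differences with SEPD and intervals.

    The difference contrast uses coefficients 1 and -1 in K and M; the
    location main effect cancels, leaving twice the target zone's genotype
    x location variance in the unobservable part.
    """
    genotypes = fit.model.genotypes
    if len(genotypes) < 2:
        raise ValueError("pairwise differences need at least 2 genotypes")
    zone, x = _location_info(fit, covariates, location)
    spec = fit.model.spec
    s2_gl = fit.variance(
        "gxl", zone if spec.gl_term.structure == "zone_het" else None)
    pfs = {g: build_predictable_function(fit, g, zone, x) for g in genotypes}
    rows = []
    for gi, gj in combinations(genotypes, 2):
        K = pfs[gi].K - pfs[gj].K
        M = pfs[gi].M - pfs[gj].M
        diff = float(K @ fit.beta + M @ fit.u)
        vdiff = pev(fit, K, M)
        sepd = float(np.sqrt(vdiff + 2.0 * s2_gl))
        lo, hi = prediction_interval(diff, sepd, alpha)
        rows.append({"genotype_i": gi, "genotype_j": gj, "diff": diff,
                     "sepd": sepd, "lower": lo, "upper": hi})
    return PairwiseTable(pd.DataFrame(rows), spec.model_id, location, zone, alpha)
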