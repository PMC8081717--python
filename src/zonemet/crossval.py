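"""Leave-one-location-out cross-validation and MSEP model comparison.

One location at a time is held out; the model is refitted on the
remaining locations and the held-out location is predicted as if it were
new (its covariates ARE used, its yields are not).  The observed values
are the held-out trial's stage-I adjusted means -- genotype comparisons at
the location level are what cultivar trials are for -- and accuracy is the
mean squared error of prediction (MSEP) of *pairwise genotype
differences*, accumulated over ordered pairs and folds:

    MSEP = sum_j sum_{i != i'} [ (y_ij - y_i'j) - (z_ij - z_i'j) ]^2
           / (J * I * (I - 1)).

The model with the smallest MSEP predicts the yield differences in the
validation sets most accurately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CovariateSpec, make_model
from .data import Dataset
from .design import build_stage2_design
from .engine import ConvergenceError, EstimabilityError, fit_reml
from .predict import predict_new_location
from .stage1 import Stage2Data, assemble_stage2, run_stage1

__all__ = ["Fold", "FoldResult", "MSEPResult", "loo_folds", "msep",
           "run_model_comparison"]


@dataclass
class Fold:
    training: list[str]
    validation: str
    flagged: bool = False
    note: str = ""


@dataclass
class FoldResult:
    """Observed (stage-I adjusted means) and predicted genotype values for
    one held-out location.  Predictions never touch the held-out yields;
    the held-out covariates are used."""

    location: str
    observed: pd.Series
    predicted: pd.Series


@dataclass
class MSEPResult:
    table: pd.DataFrame                 # model, msep, rank, n_folds
    dropped_folds: list[str] = field(default_factory=list)
    non_comparable: list[str] = field(default_factory=list)

    def msep_of(self, model_id: str) -> float:
        return float(self.table.set_index("model").loc[model_id, "msep"])


def loo_folds(dataset: Dataset) -> list[Fold]:
    """One fold per location.  A fold is flagged (and later skipped) when
    the training set would retain fewer than 2 locations in the held-out
    location's zone, leaving that zone's variances inestimable."""
    if dataset.J < 3:
        raise ValueError("leave-one-location-out needs at least 3 locations")
    folds = []
    for loc in dataset.locations:
        training = [l for l in dataset.locations if l != loc]
        zone = dataset.zones[loc]
        n_same_zone = sum(1 for l in training if dataset.zones[l] == zone)
        flagged = n_same_zone < 2
        folds.append(Fold(training, loc, flagged,
                          "" if not flagged else
                          f"zone {zone!r} retains {n_same_zone} training "
                          "location(s); zone variance inestimable"))
    return folds


def msep(folds: list[FoldResult]) -> float:
    """MSEP of pairwise genotype differences over ordered pairs and folds.

    Genotypes missing from either the observed or predicted side of a fold
    are dropped pairwise and the denominator counts only the terms
    actually summed (it equals J*I*(I-1) for complete data)."""
    total, count = 0.0, 0
    for fr in folds:
        common = fr.observed.index.intersection(fr.predicted.index)
        y = fr.observed[common].to_numpy()
        z = fr.predicted[common].to_numpy()
        d = y - z
        # ordered-pair sum of (d_i - d_i')^2 without forming the I^2 table
        k = d.size
        if k < 2:
            continue
        total += 2.0 * (k * np.sum(d * d) - np.sum(d) ** 2)
        count += k * (k - 1)
    if count == 0:
        raise ValueError("no valid genotype pairs across folds")
    return total / count


def _predict_fold(fit, covariates, location: str) -> pd.Series:
    pred = predict_new_location(fit, covariates, location)
    return pred.table.set_index("genotype")["eta"]


def run_model_comparison(dataset: Dataset, covariates, model_ids: list[str],
                         covariate_spec: CovariateSpec | None = None,
                         stage1_fits=None, rc_structure: str = "us3",
                         fail_fraction: float = 0.2) -> MSEPResult:
    """Leave-one-location-out MSEP for several models on one dataset.

    Stage-I fits are computed once per location and shared by every fold
    and model (each trial's analysis uses only that trial's own data, so
    no information leaks across folds).  Folds where any model fails to
    converge are dropped for ALL models to keep MSEP comparable; a model
    failing on more than ``fail_fraction`` of folds is marked
    non-comparable.
    """
    if covariates is None:
        # covariate-free models still need each held-out location's zone
        from .data import CovariateTable
        covariates = CovariateTable(pd.DataFrame(
            [{"location": l, "zone": z, "is_new": False}
             for l, z in dataset.zones.items()]))
    fits1 = run_stage1(dataset) if stage1_fits is None else stage1_fits
    stage2_all = assemble_stage2(fits1)
    by_loc = {f.location: f for f in fits1}
    folds = [f for f in loo_folds(dataset) if not f.flagged]

    specs = {mid: make_model(mid, covariate_spec, rc_structure)
             for mid in model_ids}
    # warm starts from the full-data fits
    warm = {}
    for mid, spec in specs.items():
        try:
            full = fit_reml(build_stage2_design(spec, stage2_all, covariates))
            warm[mid] = full.theta
        except ConvergenceError:
            warm[mid] = None

    results: dict[str, list[FoldResult]] = {mid: [] for mid in model_ids}
    failures: dict[str, int] = {mid: 0 for mid in model_ids}
    dropped = []
    for fold in folds:
        stage2 = stage2_all.subset_locations(fold.training)
        fold_preds = {}
        ok = True
        for mid, spec in specs.items():
            try:
                model = build_stage2_design(spec, stage2, covariates)
                fit = fit_reml(model, x0=warm[mid])
                fold_preds[mid] = _predict_fold(fit, covariates, fold.validation)
            except (ConvergenceError, EstimabilityError,
                    np.linalg.LinAlgError):
                failures[mid] += 1
                ok = False
                break
        if not ok:
            dropped.append(fold.validation)
            continue
        observed = by_loc[fold.validation].means
        for mid in model_ids:
            results[mid].append(FoldResult(fold.validation, observed,
                                           fold_preds[mid]))

    non_comparable = [mid for mid in model_ids
                      if failures[mid] > fail_fraction * max(len(folds), 1)]
    rows = []
    for mid in model_ids:
        value = msep(results[mid]) if results[mid] else np.nan
        rows.append({"model": mid, "msep": value, "n_folds": len(results[mid])})
    table = pd.DataFrame(rows)
    table["rank"] = table["msep"].rank(method="min").astype("Int64")
    table = table.sort_values("rank").reset_index(drop=True)
    return MSEPResult(table, dropped, non_comparable)
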