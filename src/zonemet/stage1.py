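"""Stage I of the fully-efficient two-stage analysis: each trial
(location) is analysed with its own linear mixed model, and the genotype
adjusted means are forwarded together with their *full* variance-
covariance matrix.

Per trial the model has fixed genotype effects in cell-means
parameterisation (so the adjusted means are directly the estimable
genotype expected values), random complete-replicate and incomplete-block
(within replicate) effects, and a homogeneous plot residual, all estimated
by REML.  The forwarded matrix ``R_j = var(mu_hat_j)`` comes from the
generalised inverse of the trial's mixed-model equations; stacking the
means location-major and the ``R_j`` block-diagonally yields the stage-II
input, in which R is treated as known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .data import Dataset
from .engine import MixedModel, RandomTerm, fit_reml

__all__ = ["TrialFit", "Stage2Data", "fit_trial", "run_stage1",
           "assemble_stage2", "TrialFitError"]


class TrialFitError(ValueError):
    """A trial cannot be analysed (too few observations or replicates)."""


@dataclass
class TrialFit:
    """Per-trial REML results: adjusted means and their covariance."""

    location: str
    zone: str
    genotypes: list[str]
    means: pd.Series          # adjusted means, g/m^2, indexed by genotype
    R_j: np.ndarray           # variance-covariance of the adjusted means
    sigma2_rep: float
    sigma2_block: float
    sigma2_e: float
    converged: bool
    boundary: list[str]


@dataclass
class Stage2Data:
    """Stacked adjusted means with block-diagonal forwarded R.

    Rows of ``df`` are ordered location-major (canonical location sort,
    genotype sort within location) and ``R`` rows/columns match.
    """

    df: pd.DataFrame          # columns: location, zone, genotype, mean
    R: np.ndarray
    zones: dict               # location -> zone

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    @property
    def locations(self) -> list[str]:
        return sorted(self.df["location"].unique())

    @property
    def zone_list(self) -> list[str]:
        return sorted(set(self.zones.values()))

    def subset_locations(self, keep) -> "Stage2Data":
        keep = set(keep)
        mask = self.df["location"].isin(keep).to_numpy()
        return Stage2Data(self.df[mask].reset_index(drop=True),
                          self.R[np.ix_(mask, mask)],
                          {l: z for l, z in self.zones.items() if l in keep})


def fit_trial(trial_df: pd.DataFrame, drop_block: bool = False) -> TrialFit:
    """REML analysis of a single trial's plot data.

    ``trial_df`` holds one location's rows of a plot table.  Genotype is
    fixed (cell means), replicate and block-within-replicate random,
    residual homogeneous.  ``drop_block`` omits the incomplete-block term
    (e.g. for an RCBD).
    """
    df = trial_df.reset_index(drop=True)
    locs = df["location"].unique()
    if len(locs) != 1:
        raise TrialFitError(f"fit_trial expects a single location, got {list(locs)}")
    if len(df) < 2:
        raise TrialFitError(f"trial {locs[0]!r}: fewer than 2 observations")
    n_rep = df["replicate"].nunique()
    if n_rep < 2:
        raise TrialFitError(
            f"trial {locs[0]!r}: replicate variance inestimable with "
            f"{n_rep} replicate")
    genotypes = sorted(df["genotype"].unique())
    gi = pd.Categorical(df["genotype"], categories=genotypes).codes
    X = np.zeros((len(df), len(genotypes)))
    X[np.arange(len(df)), gi] = 1.0

    rep_levels = sorted(df["replicate"].unique())
    ri = pd.Categorical(df["replicate"], categories=rep_levels).codes
    Zr = np.zeros((len(df), len(rep_levels)))
    Zr[np.arange(len(df)), ri] = 1.0
    terms = [RandomTerm("replicate", Zr, [(r,) for r in rep_levels], "scalar")]

    if not drop_block:
        blk_key = (df["replicate"].astype(str) + "/" + df["block"].astype(str))
        blk_levels = sorted(blk_key.unique())
        bi = pd.Categorical(blk_key, categories=blk_levels).codes
        Zb = np.zeros((len(df), len(blk_levels)))
        Zb[np.arange(len(df)), bi] = 1.0
        terms.append(RandomTerm("block", Zb, [(b,) for b in blk_levels], "scalar"))

    model = MixedModel(df["yield"].to_numpy(), X, terms, R=None,
                       fixed_labels=[("genotype", g) for g in genotypes])
    fit = fit_reml(model)
    comps = fit.term_params()
    return TrialFit(
        location=str(locs[0]), zone=str(df["zone"].iloc[0]),
        genotypes=genotypes,
        means=pd.Series(fit.beta, index=genotypes, name="mean"),
        R_j=0.5 * (fit.C11 + fit.C11.T),
        sigma2_rep=float(comps["replicate"][0]),
        sigma2_block=float(comps["block"][0]) if not drop_block else 0.0,
        sigma2_e=float(comps["residual"][0]),
        converged=fit.converged, boundary=fit.boundary)


def run_stage1(dataset: Dataset, drop_block: bool = False) -> list[TrialFit]:
    """Fit every location of a dataset; returns fits in location order."""
    return [fit_trial(df, drop_block=drop_block)
            for _, df in dataset.plots.groupby("location", sort=True)]


def assemble_stage2(fits: list[TrialFit]) -> Stage2Data:
    """Stack per-trial adjusted means and assemble the block-diagonal R.

    Fits are sorted canonically by location id, so input order is
    irrelevant; off-diagonal cross-location blocks are exactly zero (the
    trials are statistically independent)."""
    if len(fits) < 2:
        raise ValueError("stage II needs at least 2 trials")
    seen = [f.location for f in fits]
    if len(set(seen)) != len(seen):
        dup = sorted({l for l in seen if seen.count(l) > 1})
        raise ValueError(f"duplicated location(s) in stage-1 fits: {dup}")
    fits = sorted(fits, key=lambda f: f.location)
    rows = []
    for f in fits:
        for g in f.genotypes:
            rows.append({"location": f.location, "zone": f.zone,
                         "genotype": g, "mean": float(f.means[g])})
    R = sla.block_diag(*[f.R_j for f in fits])
    zones = {f.location: f.zone for f in fits}
    return Stage2Data(pd.DataFrame(rows), R, zones)


def write_stage1(fits: list[TrialFit], out_dir) -> None:
    """Export per-trial means (CSV) and R blocks (plain-text matrix file:
    one '# location <id>' header per block followed by its dense rows)."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in sorted(fits, key=lambda f: f.location):
        se = np.sqrt(np.diag(f.R_j))
        for g, s in zip(f.genotypes, se):
            rows.append({"location": f.location, "zone": f.zone, "genotype": g,
                         "mean": float(f.means[g]), "se": float(s)})
    pd.DataFrame(rows).to_csv(out / "adjusted_means.csv", index=False)
    with open(out / "r_blocks.txt", "w") as fh:
        for f in sorted(fits, key=lambda f: f.location):
            fh.write(f"# location {f.location} ({len(f.genotypes)} genotypes)\n")
            for row in f.R_j:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
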