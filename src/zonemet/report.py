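"""Pairwise significance reporting for new-location predictions:
z-tests with Bonferroni adjustment, a p-value heatmap, a compact letter
display built with the insert-and-absorb algorithm, and CSV/plot export.

Each predicted pairwise difference is divided by its SEPD to give a z
score and a two-sided p-value; the Bonferroni adjustment multiplies p by
the number of pairs I(I-1)/2 (capped at 1).  The letter display encodes
the adjusted significance pattern exactly: two genotypes share at least
one letter if and only if their difference is non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from string import ascii_lowercase

import numpy as np
import pandas as pd
from scipy import stats

from .predict import NewLocationPrediction, PairwiseTable

__all__ = ["PValueMatrix", "LetterDisplay", "n_pairs", "pairwise_pvalues",
           "letter_display", "export_report"]


def n_pairs(n_genotypes: int) -> int:
    """Number of unordered genotype pairs, I(I-1)/2."""
    return n_genotypes * (n_genotypes - 1) // 2


@dataclass
class PValueMatrix:
    """Symmetric matrices of raw and Bonferroni-adjusted two-sided
    p-values from z-tests of pairwise differences (diagonal = 1)."""

    p: pd.DataFrame
    p_adj: pd.DataFrame
    alpha: float
    n_pairs: int

    def significant(self, i: str, j: str, adjusted: bool = True) -> bool:
        mat = self.p_adj if adjusted else self.p
        return bool(mat.loc[i, j] < self.alpha)


@dataclass
class LetterDisplay:
    """Mean-sorted compact letter display.  Genotypes not sharing any
    letter differ significantly (at the basis alpha/adjustment)."""

    table: pd.DataFrame       # genotype, mean, letters; sorted by mean desc
    alpha: float
    adjusted: bool

    def letters_of(self, genotype: str) -> str:
        return str(self.table.set_index("genotype").loc[genotype, "letters"])


def pairwise_pvalues(pairwise: PairwiseTable, alpha: float = 0.05,
                     adjust: bool = True) -> PValueMatrix:
    """z-test every predicted pairwise difference: z = DIFF/SEPD,
    p = 2(1 - Phi(|z|)); Bonferroni multiplies by I(I-1)/2."""
    genos = pairwise.genotypes
    m = n_pairs(len(genos))
    p = pd.DataFrame(1.0, index=genos, columns=genos)
    for _, row in pairwise.table.iterrows():
        if row["sepd"] > 0:
            z = row["diff"] / row["sepd"]
            pv = 2.0 * stats.norm.sf(abs(z))
        else:
            pv = 0.0 if row["diff"] != 0 else 1.0
        p.loc[row["genotype_i"], row["genotype_j"]] = pv
        p.loc[row["genotype_j"], row["genotype_i"]] = pv
    p_adj = (p * m).clip(upper=1.0) if adjust else p.copy()
    np.fill_diagonal(p_adj.values, 1.0)
    return PValueMatrix(p, p_adj, alpha, m)


def letter_display(pmatrix: PValueMatrix, means: pd.Series,
                   alpha: float | None = None,
                   adjusted: bool = True) -> LetterDisplay:
    """Compact letter display via insert-and-absorb.

    Start from a single letter covering all genotypes; for every
    significant pair split each covering set into two sets, one excluding
    each member; absorb sets contained in others.  The result encodes the
    significance pattern exactly and is verified against all pairs before
    returning.
    """
    alpha = pmatrix.alpha if alpha is None else alpha
    order = means.sort_values(ascending=False).index.tolist()
    pmat = pmatrix.p_adj if adjusted else pmatrix.p
    sig = [(i, j) for i, j in combinations(order, 2) if pmat.loc[i, j] < alpha]

    sets: list[frozenset] = [frozenset(order)]
    for i, j in sig:
        new_sets = []
        for s in sets:
            if i in s and j in s:
                new_sets += [s - {i}, s - {j}]
            else:
                new_sets.append(s)
        # absorb: drop any set contained in another
        sets = [s for s in new_sets if s and
                not any(s < t for t in new_sets)]
        sets = list(dict.fromkeys(sets))
    if len(sets) > len(ascii_lowercase):
        raise ValueError(
            f"{len(sets)} letters needed, exceeding the alphabet; "
            "use the p-value heatmap instead")

    # order letters by the best (highest-mean) genotype they contain
    rank = {g: k for k, g in enumerate(order)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    letters = {g: "".join(ascii_lowercase[k] for k, s in enumerate(sets) if g in s)
               for g in order}

    for i, j in combinations(order, 2):
        shares = bool(set(letters[i]) & set(letters[j]))
        if shares == ((i, j) in sig or (j, i) in sig):
            raise AssertionError(  # pragma: no cover - defensive
                f"letter display failed to encode pair ({i}, {j})")
    table = pd.DataFrame({"genotype": order,
                          "mean": [float(means[g]) for g in order],
                          "letters": [letters[g] for g in order]})
    return LetterDisplay(table, alpha, adjusted)


def export_report(predictions: NewLocationPrediction, pairwise: PairwiseTable,
                  pmatrix: PValueMatrix, letters: LetterDisplay,
                  out_dir, heatmap: bool = True) -> dict[str, Path]:
    """Write plot-ready CSVs (predictions with intervals, pairwise table,
    p-value heatmap matrix, letter table) plus a rendered heatmap image."""
    if predictions.table.empty:
        raise ValueError("no genotypes to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["predictions"] = out / "predictions.csv"
    predictions.table.to_csv(paths["predictions"], index=False)
    paths["pairwise"] = out / "pairwise.csv"
    pairwise.table.to_csv(paths["pairwise"], index=False)
    paths["heatmap_csv"] = out / "pvalues.csv"
    pmatrix.p_adj.rename_axis("genotype").to_csv(paths["heatmap_csv"])
    paths["letters"] = out / "letters.csv"
    letters.table.to_csv(paths["letters"], index=False)
    if heatmap:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        genos = pmatrix.p_adj.index.tolist()
        fig, ax = plt.subplots(figsize=(0.3 * len(genos) + 2,) * 2)
        im = ax.imshow(pmatrix.p_adj.to_numpy(), vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(genos)), genos, rotation=90, fontsize=6)
        ax.set_yticks(range(len(genos)), genos, fontsize=6)
        fig.colorbar(im, ax=ax, label="adjusted p-value")
        ax.set_title(f"{pairwise.model_id}: pairwise differences at "
                     f"{pairwise.location}")
        paths["heatmap_png"] = out / "pvalues_heatmap.png"
        fig.savefig(paths["heatmap_png"], dpi=150, bbox_inches="tight")
        plt.close(fig)
    return paths
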