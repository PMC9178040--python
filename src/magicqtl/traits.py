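"""Trait correlation structure, Ward trait groups and PCA pseudo-traits.

Workflow: pairwise Pearson correlations between trait adjusted means, the
sign-blind dissimilarity d = 2(1 - |r|), Ward agglomerative clustering
(the "on-distances" ward.D2 convention) cut into k groups, and a per-group
principal component analysis of the scaled traits whose component scores
become pseudo-traits for multi-trait QTL mapping.  A method-of-moments
one-way variance-components estimator provides broad-sense heritability
from replicated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .simulate import PhenotypeTable


@dataclass
class TraitCorrelationMatrix:
    corr: pd.DataFrame  # trait x trait Pearson r, NaN when < min pairs
    n_pairs: pd.DataFrame  # complete pairs per trait pair


@dataclass
class TraitGrouping:
    groups: pd.Series  # trait -> group label (1..k)
    k: int


@dataclass
class PCTraitSet:
    """Per-group PCA: weightings, per-line scores, % variance explained."""

    weightings: dict[int, pd.DataFrame]  # group -> trait x PC loadings
    scores: pd.DataFrame  # line x pseudo-trait ("G<g>_PC<k>")
    pct_variance: dict[int, np.ndarray]  # group -> % variance per PC


@dataclass
class HeritabilityEstimate:
    trait: str
    year: int | str
    H2: float
    Vg: float
    Vr: float
    mean_replication: float


def correlation_matrix(
    pheno: PhenotypeTable | pd.DataFrame, year: int | str | None = None
) -> TraitCorrelationMatrix:
    """Pairwise-complete Pearson correlations between trait means.

    ``year=None`` pools every (trait, year) combination as its own
    variable, mirroring a single clustering over all per-year trait means.
    Entries with fewer than 3 complete pairs are flagged missing (NaN).
    """
    wide = pheno.wide(year) if isinstance(pheno, PhenotypeTable) else pheno
    corr = wide.corr(method="pearson", min_periods=3)
    present = wide.notna().astype(int)
    n_pairs = present.T @ present
    return TraitCorrelationMatrix(corr, n_pairs)


def trait_distance(corr: TraitCorrelationMatrix | pd.DataFrame) -> pd.DataFrame:
    """Sign-blind trait dissimilarity d = 2(1 - |r|), in [0, 2]."""
    r = corr.corr if isinstance(corr, TraitCorrelationMatrix) else corr
    d = 2.0 * (1.0 - r.abs())
    np.fill_diagonal(d.values, 0.0)
    return d


def ward_cluster(dist: pd.DataFrame, k: int = 8) -> TraitGrouping:
    """Ward agglomerative clustering of a precomputed dissimilarity, cut at k.

    Uses the Lance-Williams Ward update applied directly to the supplied
    dissimilarities (the hclust ``ward.D2`` convention, which scipy's
    ``ward`` linkage implements on a condensed distance input).
    """
    if dist.shape[0] != dist.shape[1] or not np.allclose(
        dist.values, dist.values.T, atol=1e-10
    ):
        raise ValueError("distance matrix must be square and symmetric")
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must be between 1 and the number of traits")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        Z = linkage(squareform(dist.values, checks=False), method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    return TraitGrouping(pd.Series(labels, index=dist.index, name="group"), k)


def group_pca(
    pheno: PhenotypeTable | pd.DataFrame,
    grouping: TraitGrouping,
    year: int | str | None = None,
) -> PCTraitSet:
    """Per-group PCA of scaled, centred trait data; scores as pseudo-traits.

    Within each trait group the correlation matrix of the member traits is
    eigendecomposed (traits standardised to mean 0, variance 1).  Lines
    with a missing value in any member trait are dropped when estimating
    weightings; scores are emitted for all lines with complete group data.
    Component signs are fixed so the largest-magnitude weighting in each
    component is positive.  Constant traits are excluded with a warning.
    """
    wide = pheno.wide(year) if isinstance(pheno, PhenotypeTable) else pheno
    weightings: dict[int, pd.DataFrame] = {}
    pct: dict[int, np.ndarray] = {}
    score_cols: dict[str, pd.Series] = {}
    for g in sorted(grouping.groups.unique()):
        traits = grouping.groups.index[grouping.groups == g].tolist()
        traits = [t for t in traits if t in wide.columns]
        sub = wide[traits]
        keep = [t for t in traits if sub[t].std(skipna=True) > 0]
        dropped = set(traits) - set(keep)
        if dropped:
            warnings.warn(f"group {g}: constant traits excluded: {sorted(dropped)}")
        if not keep:
            continue
        complete = sub[keep].dropna()
        X = (complete - complete.mean()) / complete.std(ddof=1)
        C = np.corrcoef(X.to_numpy(), rowvar=False)
        C = np.atleast_2d(C)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
        # deterministic sign: largest-|weighting| entry positive
        for j in range(evecs.shape[1]):
            if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
                evecs[:, j] *= -1
        pc_names = [f"G{g}_PC{j + 1}" for j in range(evecs.shape[1])]
        weightings[g] = pd.DataFrame(evecs, index=keep, columns=pc_names)
        pct[g] = 100.0 * evals / evals.sum()
        scores = X.to_numpy() @ evecs
        for j, name in enumerate(pc_names):
            score_cols[name] = pd.Series(scores[:, j], index=complete.index)
    score_df = pd.DataFrame(score_cols)
    score_df.index.name = "line_id"
    return PCTraitSet(weightings, score_df, pct)


def pc_phenotypes(pcs: PCTraitSet, year: int | str = "PC") -> PhenotypeTable:
    """Repackage PC scores in the long phenotype schema for QTL scanning."""
    long = (
        pcs.scores.reset_index()
        .melt(id_vars="line_id", var_name="trait", value_name="value")
        .dropna(subset=["value"])
    )
    long["year"] = year
    long["rep"] = 1
    return PhenotypeTable(long[["line_id", "trait", "year", "rep", "value"]])


def estimate_heritability(
    pheno: PhenotypeTable, trait: str, year: int | str | None = None
) -> HeritabilityEstimate:
    """Broad-sense heritability from one-way variance components.

    Method-of-moments ANOVA on replicated line values: Vr = MS_within,
    Vg = (MS_between - MS_within) / n0 (truncated at zero), with n0 the
    effective replication for unbalanced designs; H2 = Vg / (Vg + Vr/r)
    at r = mean replication, i.e. the heritability of line means.
    """
    d = pheno.data[pheno.data["trait"] == trait]
    if year is not None:
        d = d[d["year"] == year]
    d = d.dropna(subset=["value"])
    counts = d.groupby("line_id", observed=True)["value"].count()
    counts = counts[counts >= 1]
    if (counts >= 2).sum() < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 replicates on >= 2 lines")
    N, a = counts.sum(), len(counts)
    grand = d["value"].mean()
    means = d.groupby("line_id", observed=True)["value"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(
        ((d["value"] - means.reindex(d["line_id"]).to_numpy()) ** 2).sum()
    )
    ms_between = ss_between / (a - 1)
    dfw = N - a
    ms_within = ss_within / dfw if dfw > 0 else 0.0
    n0 = (N - (counts**2).sum() / N) / (a - 1)
    vg = max((ms_between - ms_within) / n0, 0.0)
    vr = ms_within
    rbar = N / a
    denom = vg + vr / rbar
    h2 = float(vg / denom) if denom > 0 else 0.0
    return HeritabilityEstimate(trait, year if year is not None else "all", h2, vg, vr, float(rbar))
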