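"""Alpha/beta diversity, ordination and longitudinal dissimilarity.

Counts are converted to relative abundances before Bray-Curtis; Shannon
uses the natural log.  PCoA is the classical double-centred
eigendecomposition with negative eigenvalues dropped from the variance
denominator.  PERMANOVA follows the adonis sum-of-squares decomposition
with a permutation p value.  The longitudinal analysis computes, per
animal, the Bray-Curtis dissimilarity of each later timepoint to its own
baseline and classifies which timepoint drifted further.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis, pdist, squareform


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min(x,y)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("vectors must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(braycurtis(x, y))


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise proportions of a groups x samples count table."""
    sums = table.sum(axis=0)
    if (sums == 0).any():
        warnings.warn("samples with zero total counts")
        sums = sums.replace(0, 1)
    return table.div(sums, axis=1)


def beta_diversity_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples, computed on
    relative abundances."""
    rel = relative_abundance(table)
    mat = squareform(pdist(rel.T.values, metric="braycurtis"))
    return pd.DataFrame(mat, index=table.columns, columns=table.columns)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    variance_explained: np.ndarray  # percent per axis, non-increasing
    eigenvalues: np.ndarray


def pcoa(dissimilarity: pd.DataFrame, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinate analysis of a symmetric zero-diagonal
    dissimilarity matrix.  Negative eigenvalues are dropped — from both the
    retained axes and the variance-explained denominator."""
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    centre = np.eye(n) - np.ones((n, n)) / n
    b = centre @ a @ centre
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-12
    positive = evals > tol
    pos_vals = evals[positive]
    coords = evecs[:, positive] * np.sqrt(pos_vals)
    # deterministic sign: largest-magnitude loading positive per axis
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    var = 100.0 * pos_vals / pos_vals.sum()
    if n_axes is not None:
        coords, var, pos_vals = coords[:, :n_axes], var[:n_axes], pos_vals[:n_axes]
    index = dissimilarity.index if isinstance(dissimilarity, pd.DataFrame) else range(n)
    frame = pd.DataFrame(coords, index=index,
                         columns=[f"PCo{j + 1}" for j in range(coords.shape[1])])
    return PcoaResult(frame, var, evals)


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(R^2, pseudo-F) from squared dissimilarities via the adonis
    sum-of-squares decomposition."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    a = groups.size
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return ss_between / ss_total, f


def permanova(
    dissimilarity: pd.DataFrame,
    grouping,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutational multivariate ANOVA (one factor).

    Returns R^2 (variance explained), pseudo-F, and the permutation p value
    computed as the fraction of permuted statistics at least as large as
    the observed one, the observed included.
    """
    d = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(grouping)
    if d.shape[0] != labels.size:
        raise ValueError("grouping length must match the matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    d2 = d**2
    r2, f_obs = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    geq = 1  # the observed ordering counts as one permutation
    for _ in range(n_perm):
        _, f_perm = _permanova_stats(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            geq += 1
    return {
        "r2": float(r2),
        "pseudo_f": float(f_obs),
        "p_value": geq / (n_perm + 1),
        "n_permutations": n_perm,
    }


@dataclass
class DissimilarityRecord:
    animal_id: str
    bc_base_t1: float
    bc_base_t5: float
    bc_t1_t5: float
    direction: str  # T1_more_dissimilar | T5_more_dissimilar | tie


def longitudinal_dissimilarity(
    table: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-animal Bray-Curtis drift from baseline.

    For every animal with a Base sample and both later timepoints, computes
    Base-vs-T1, Base-vs-T5 and T1-vs-T5 dissimilarities (on relative
    abundances) and classifies whether the virome was more dissimilar from
    baseline at T1 or at T5.  Returns (per-animal records, per-treatment
    averages, per-cage averages).
    """
    rel = relative_abundance(table)
    meta = metadata.set_index("sample_id")
    records = []
    for animal, grp in metadata.groupby("animal_id", sort=True):
        by_tp = dict(zip(grp["timepoint"], grp["sample_id"]))
        if "Base" not in by_tp or not {"T1", "T5"} <= set(by_tp):
            warnings.warn(f"animal {animal}: incomplete timepoints; skipped")
            continue
        missing = [s for s in by_tp.values() if s not in rel.columns]
        if missing:
            warnings.warn(f"animal {animal}: samples missing from table; skipped")
            continue
        base, t1, t5 = (rel[by_tp[tp]].values for tp in ("Base", "T1", "T5"))
        b1, b5, b15 = bray_curtis(base, t1), bray_curtis(base, t5), bray_curtis(t1, t5)
        if b5 > b1:
            direction = "T5_more_dissimilar"
        elif b1 > b5:
            direction = "T1_more_dissimilar"
        else:
            direction = "tie"
        records.append(
            (animal, meta.loc[by_tp["Base"], "treatment"],
             meta.loc[by_tp["Base"], "cage_id"], b1, b5, b15, direction)
        )
    per_animal = pd.DataFrame(
        records,
        columns=["animal_id", "treatment", "cage_id",
                 "bc_base_t1", "bc_base_t5", "bc_t1_t5", "direction"],
    )
    value_cols = ["bc_base_t1", "bc_base_t5", "bc_t1_t5"]
    by_treatment = per_animal.groupby("treatment", sort=True)[value_cols].mean()
    by_cage = per_animal.groupby("cage_id", sort=True)[value_cols].mean()
    return per_animal, by_treatment, by_cage


def group_compare(
    values,
    grouping,
    test: str = "wilcoxon",
    n_comparisons: int = 1,
) -> dict:
    """Rank-based group comparison with Bonferroni correction.

    ``wilcoxon`` runs the two-sample Wilcoxon rank-sum test; ``kruskal``
    the Kruskal-Wallis test for three or more groups.  The p value is
    multiplied by ``n_comparisons`` and capped at 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(grouping)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    if test == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon compares exactly two groups")
        stat, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif test == "kruskal":
        stat, p = stats.kruskal(*groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "p_adjusted": min(1.0, float(p) * n_comparisons),
        "n_comparisons": n_comparisons,
    }


def pairwise_group_compare(values, grouping, n_comparisons: int | None = None) -> pd.DataFrame:
    """All pairwise two-group rank-sum tests, Bonferroni-adjusted over the
    number of pairs (or an explicit comparison count)."""
    labels = np.asarray(grouping)
    uniq = list(np.unique(labels))
    pairs = list(combinations(uniq, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    rows = []
    values = np.asarray(values, dtype=float)
    for a, b in pairs:
        res = group_compare(
            np.concatenate([values[labels == a], values[labels == b]]),
            np.concatenate([np.repeat(a, (labels == a).sum()),
                            np.repeat(b, (labels == b).sum())]),
            test="wilcoxon",
            n_comparisons=m,
        )
        rows.append((a, b, res["statistic"], res["p_value"], res["p_adjusted"]))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "p_adj"])
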