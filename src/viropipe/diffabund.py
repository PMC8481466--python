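"""Negative-binomial differential abundance and cross-treatment concordance.

Counts are normalized by median-of-ratios size factors; each viral group is
tested per treatment for Base-vs-T1 and Base-vs-T5 changes with a Wald test
on the log2 fold change under a negative-binomial error model
(var = mu + alpha * mu^2, alpha by method of moments with a pseudocount
floor).  P values are Bonferroni-adjusted within a treatment over all
groups x contrasts; significance is called at a strict adjusted threshold
(1e-5 by default).  The concordance analysis classifies significant groups
by how many treatments and timepoints they are altered in.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

#: Bonferroni-adjusted significance threshold for differential abundance
ALPHA = 1e-5

CONTRASTS = (("Base", "T1"), ("Base", "T5"))


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors.

    Per sample, the median ratio of its counts to the per-group geometric
    means, over groups with no zero count anywhere.  If no group is
    all-nonzero, the geometric means are computed over positive counts only
    (with a warning).
    """
    counts = table.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        log_counts = np.log(counts[all_positive])
        log_geomeans = log_counts.mean(axis=1, keepdims=True)
        factors = np.median(np.exp(log_counts - log_geomeans), axis=0)
    else:
        warnings.warn("no group with all-positive counts; "
                      "falling back to positive-count geometric means")
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(counts, where=counts > 0), np.nan)
        log_geomeans = np.nanmean(logs, axis=1, keepdims=True)
        factors = np.nanmedian(np.exp(logs - log_geomeans), axis=0)
    return pd.Series(factors, index=table.columns, name="size_factor")


def _moment_dispersion(norm: np.ndarray) -> np.ndarray:
    """Per-group method-of-moments NB dispersion from normalized counts
    (columns = samples of one condition), floored at a small positive."""
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mu) / np.maximum(mu, 1e-8) ** 2
    return np.clip(np.nan_to_num(alpha), 1e-8, None)


def nb_wald_test(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    contrasts: tuple = CONTRASTS,
    alpha: float = ALPHA,
    pseudocount: float = 0.5,
    dispersion_mode: str = "pooled",
) -> pd.DataFrame:
    """Per-treatment NB Wald tests of each viral group against baseline.

    For every treatment and contrast (Base vs T1, Base vs T5), the log2
    fold change of size-factor-normalized means is tested with
    z = log2FC / SE, where the delta-method SE uses the NB variance with a
    method-of-moments dispersion.  The default ``dispersion_mode``
    ``"pooled"`` shares the median per-group estimate across all groups of
    a contrast (a common-dispersion model: with few replicates, per-group
    moment estimates are too unstable for a strict significance threshold);
    ``"per_group"`` keeps the larger of the two condition estimates for
    each group.  Bonferroni adjustment is
    applied within each treatment over all tested groups x contrasts.
    Groups with zero counts in every sample of a treatment are excluded.
    """
    sf = size_factors(table)
    norm = table.div(sf, axis=1)
    meta = metadata.set_index("sample_id")
    results = []
    for treatment in sorted(meta["treatment"].unique()):
        trt_samples = meta.index[meta["treatment"] == treatment]
        trt_norm = norm[[s for s in table.columns if s in set(trt_samples)]]
        trt_meta = meta.loc[trt_norm.columns]
        nonzero = trt_norm.sum(axis=1) > 0
        if (~nonzero).any():
            warnings.warn(
                f"{treatment}: {int((~nonzero).sum())} all-zero groups excluded"
            )
        sub = trt_norm.loc[nonzero]
        rows = []
        for ref_tp, alt_tp in contrasts:
            ref = sub[trt_meta.index[trt_meta["timepoint"] == ref_tp]].to_numpy(float)
            alt = sub[trt_meta.index[trt_meta["timepoint"] == alt_tp]].to_numpy(float)
            if ref.shape[1] < 2 or alt.shape[1] < 2:
                raise ValueError(
                    f"{treatment} {ref_tp} vs {alt_tp}: need >=2 samples per condition"
                )
            mu_ref = ref.mean(axis=1) + pseudocount
            mu_alt = alt.mean(axis=1) + pseudocount
            disp_ref = _moment_dispersion(ref)
            disp_alt = _moment_dispersion(alt)
            if dispersion_mode == "pooled":
                pooled = np.median(np.maximum(disp_ref, disp_alt))
                disp_ref = disp_alt = np.full_like(disp_ref, pooled)
            elif dispersion_mode != "per_group":
                raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
            disp = np.maximum(disp_ref, disp_alt)
            lfc = np.log2(mu_alt / mu_ref)
            var_log_ref = 1.0 / (ref.shape[1] * mu_ref) + disp / ref.shape[1]
            var_log_alt = 1.0 / (alt.shape[1] * mu_alt) + disp / alt.shape[1]
            se = np.sqrt(var_log_ref + var_log_alt) / np.log(2)
            z = lfc / se
            p = 2.0 * stats.norm.sf(np.abs(z))
            for gid, l2, pv, bm in zip(sub.index, lfc, p, (mu_ref + mu_alt) / 2):
                rows.append((gid, treatment, f"{ref_tp}_vs_{alt_tp}", bm, l2, pv))
        m = len(rows)
        for gid, treatment_, contrast, bm, l2, pv in rows:
            p_adj = min(1.0, pv * m)
            results.append(
                (gid, treatment_, contrast, bm, l2, pv, p_adj, p_adj < alpha, m)
            )
    out = pd.DataFrame(
        results,
        columns=["group_id", "treatment", "contrast", "base_mean",
                 "log2fc", "p", "p_adj", "significant", "n_tests"],
    )
    return out


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """log2FC vs -log10 adjusted p, ready for volcano plotting (the +-2
    log2FC and adjusted-p reference lines are plotting annotations, not
    filters)."""
    out = results[["group_id", "treatment", "contrast", "log2fc"]].copy()
    out["neg_log10_p_adj"] = -np.log10(results["p_adj"].clip(lower=1e-300))
    return out


def concordance(results: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Classify significant groups by treatment/timepoint concordance.

    For each group significant in at least one (treatment, contrast) cell:
    which treatments and timepoints it is altered in, the direction per
    cell, whether it is single- or multi-treatment, and whether any single
    treatment altered it at both T1 and T5 (persistent).  The summary also
    counts, per treatment pair, the groups significant in both.
    """
    sig = results.loc[results["significant"].astype(bool)]
    records = []
    for gid, grp in sig.groupby("group_id", sort=True):
        treatments = sorted(grp["treatment"].unique())
        timepoints = sorted(grp["contrast"].str.split("_vs_").str[1].unique())
        directions = {
            (r.treatment, r.contrast): ("up" if r.log2fc > 0 else "down")
            for r in grp.itertuples()
        }
        persistent = any(
            grp[grp["treatment"] == t]["contrast"].nunique() == 2 for t in treatments
        )
        category = "single_treatment" if len(treatments) == 1 else "multi_treatment"
        records.append((gid, treatments, timepoints, directions, category, persistent))
    frame = pd.DataFrame(
        records,
        columns=["group_id", "treatments_altered", "timepoints_altered",
                 "direction", "category", "persistent_both_timepoints"],
    )
    pair_overlap = {}
    if not frame.empty:
        all_treatments = sorted(sig["treatment"].unique())
        for a, b in combinations(all_treatments, 2):
            n = sum(
                {a, b} <= set(ts) for ts in frame["treatments_altered"]
            )
            pair_overlap[f"{a}|{b}"] = n
    summary = summarize_concordance(
        total=len(frame),
        single_treatment=int((frame["category"] == "single_treatment").sum()) if len(frame) else 0,
        persistent_both_timepoints=int(frame["persistent_both_timepoints"].sum()) if len(frame) else 0,
    )
    summary["pair_overlap"] = pair_overlap
    return frame, summary


def summarize_concordance(
    total: int | None = None,
    single_treatment: int = 0,
    persistent_both_timepoints: int = 0,
    component_counts: dict[str, int] | None = None,
) -> dict:
    """Concordance summary arithmetic.

    ``component_counts`` lets the total be assembled from per-kind tallies
    (e.g. {"viral_contigs": 36, "viral_clusters": 42} -> total 78); the
    single-treatment percentage is reported to one decimal on the total.
    """
    if component_counts is not None:
        total = sum(component_counts.values())
    if total is None:
        raise ValueError("either total or component_counts is required")
    pct = round(100.0 * single_treatment / total, 1) if total else 0.0
    out = {
        "total": int(total),
        "single_treatment": int(single_treatment),
        "multi_treatment": int(total - single_treatment),
        "single_treatment_pct": pct,
        "persistent_both_timepoints": int(persistent_both_timepoints),
    }
    if component_counts is not None:
        out["components"] = dict(component_counts)
    return out
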