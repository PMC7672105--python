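"""Differential accessibility, cell-type-specific peak calling and
six-state (normal / unaffected / affected) peak classification.

Differential testing is a two-sided Welch t-test on peak intensities with
Benjamini-Hochberg correction; the effect size is the difference of mean
log2 intensities between groups. Cell-type-specific peaks additionally
require low coefficients of variation inside the focal cell type (inCov)
and across all remaining samples (outCov), both computed on the normalized
(linear-scale) counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import STATES, AccessibilityMatrix

SIX_STATE_CLUSTERS = {
    "C1": frozenset({"normal"}),
    "C2": frozenset({"normal", "unaffected"}),
    "C3": frozenset({"unaffected"}),
    "C4": frozenset({"unaffected", "affected"}),
    "C5": frozenset({"affected"}),
    "C6": frozenset({"normal", "affected"}),
}
# smallest subset wins, then cluster label order
_CLUSTER_PRECEDENCE = ("C1", "C3", "C5", "C2", "C4", "C6")


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (delegates to statsmodels)."""
    pvals = np.asarray(pvals, dtype=float)
    out = np.full(pvals.shape, np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        out[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return out


def welch_ttest(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values with zero-variance limits.

    When both groups are constant the p-value is 1 if the means agree and 0
    otherwise (limit convention for degenerate replicates).
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        means_equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate] = np.where(means_equal[degenerate], 1.0, 0.0)
    return p


def differential_peaks(
    matrix: AccessibilityMatrix,
    group_a: list[str],
    group_b: list[str],
    p_thr: float = 0.05,
    lfc_thr: float = 2.0,
    mode: str = "ttest",
) -> pd.DataFrame:
    """Pairwise differential accessibility between two sample groups.

    Returns a frame indexed by peak_id with columns log2fc (mean intensity
    of A minus B), p, fdr and significant. ``mode="fc_only"`` skips the
    test (single-replicate groups) and calls on |log2fc| alone.
    """
    if matrix.intensity is None:
        raise ValueError("intensity layer required")
    A = matrix.intensity[group_a].to_numpy()
    B = matrix.intensity[group_b].to_numpy()
    lfc = A.mean(axis=1) - B.mean(axis=1)
    if mode == "ttest":
        if A.shape[1] < 2 or B.shape[1] < 2:
            raise ValueError(
                "t-test needs >= 2 samples per group; use mode='fc_only' "
                "for singleton groups"
            )
        p = welch_ttest(A, B)
        fdr = benjamini_hochberg(p)
        significant = (p < p_thr) & (np.abs(lfc) > lfc_thr)
    elif mode == "fc_only":
        p = np.full(len(lfc), np.nan)
        fdr = np.full(len(lfc), np.nan)
        significant = np.abs(lfc) > lfc_thr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "fdr": fdr, "significant": significant},
        index=matrix.intensity.index,
    )


def _cv(values: np.ndarray) -> np.ndarray:
    """Row-wise coefficient of variation sd/mean; +inf when the mean is 0."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    bad = mean == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} peak(s) with zero mean; CV set to +inf")
        cv[bad] = np.inf
    return cv


def cell_type_specific_peaks(
    matrix: AccessibilityMatrix,
    meta: pd.DataFrame,
    p_thr: float = 0.005,
    lfc_thr: float = 2.0,
    in_cov: float = 0.5,
    out_cov: float = 0.5,
) -> pd.DataFrame:
    """One-vs-rest cell-type-specific peak calling.

    A peak is specific to a cell type when, against all other samples,
    p < p_thr, log2fc > lfc_thr (focal higher), inCov < in_cov and
    outCov < out_cov. Returns a per-peak frame with the winning cell_type
    (or "none") and, per cell type, the full statistics in ``.attrs``.
    """
    if matrix.intensity is None or matrix.normalized is None:
        raise ValueError("normalized and intensity layers required")
    meta = meta.loc[matrix.sample_ids]
    call = pd.DataFrame(
        {
            "cell_type": "none",
            "log2fc": np.nan,
            "p": np.nan,
            "in_cov": np.nan,
            "out_cov": np.nan,
        },
        index=matrix.intensity.index,
    )
    best_lfc = np.full(len(call), -np.inf)
    per_type: dict[str, pd.DataFrame] = {}
    for ct in meta["cell_type"].unique():
        focal = meta.index[meta["cell_type"] == ct].tolist()
        rest = meta.index[meta["cell_type"] != ct].tolist()
        if len(focal) < 2 or len(rest) < 2:
            raise ValueError(f"cell type {ct}: need >= 2 samples in focal and rest")
        diff = differential_peaks(matrix, focal, rest, p_thr, lfc_thr, mode="ttest")
        icv = _cv(matrix.normalized[focal].to_numpy())
        ocv = _cv(matrix.normalized[rest].to_numpy())
        passed = (
            (diff["p"].to_numpy() < p_thr)
            & (diff["log2fc"].to_numpy() > lfc_thr)
            & (icv < in_cov)
            & (ocv < out_cov)
        )
        stats_ct = diff.assign(in_cov=icv, out_cov=ocv, specific=passed)
        per_type[ct] = stats_ct
        # one-vs-rest calls are mutually exclusive in practice; at boundaries
        # the larger fold change wins
        take = passed & (diff["log2fc"].to_numpy() > best_lfc)
        call.loc[take, "cell_type"] = ct
        call.loc[take, ["log2fc", "p", "in_cov", "out_cov"]] = stats_ct.loc[
            take, ["log2fc", "p", "in_cov", "out_cov"]
        ].to_numpy()
        best_lfc = np.where(take, diff["log2fc"].to_numpy(), best_lfc)
    call.attrs["per_type"] = per_type
    return call


@dataclass
class SixStateResult:
    labels: pd.Series          # per candidate peak: C1..C6 or "unassigned"
    counts: pd.Series          # peaks per cluster
    ratios: pd.Series          # counts / total candidate peaks
    candidates: pd.Index


def classify_six_states(
    matrix: AccessibilityMatrix,
    meta_one_celltype: pd.DataFrame,
    p_thr: float = 0.01,
    lfc_thr: float = 2.0,
    sep: float = 0.8,
    range_max: float = 1.5,
) -> SixStateResult:
    """Classify one cell type's differential peaks over clinical states.

    Stage 1 collects candidate peaks as the union of significant peaks from
    the three pairwise state comparisons (p < p_thr, |log2fc| > lfc_thr;
    fold-change-only when a group has a single sample). Stage 2 assigns a
    candidate to the state subset S (one of the six singleton/pair patterns)
    in which every in-S group mean exceeds every out-of-S group mean by more
    than ``sep`` while every group's within-group intensity range stays
    below ``range_max``; peaks matching no pattern are "unassigned".
    """
    if matrix.intensity is None:
        raise ValueError("intensity layer required")
    meta = meta_one_celltype
    if meta["cell_type"].nunique() != 1:
        raise ValueError("six-state classification expects samples of one cell type")
    groups = {s: meta.index[meta["state"] == s].tolist() for s in STATES}
    missing = [s for s, ids in groups.items() if not ids]
    if missing:
        raise ValueError(f"missing clinical state group(s): {missing}")

    candidates: set[str] = set()
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = groups[STATES[i]], groups[STATES[j]]
            mode = "ttest" if len(a) >= 2 and len(b) >= 2 else "fc_only"
            diff = differential_peaks(matrix, a, b, p_thr, lfc_thr, mode=mode)
            candidates |= set(diff.index[diff["significant"]])
    cand_index = matrix.intensity.index[matrix.intensity.index.isin(candidates)]
    if len(cand_index) == 0:
        warnings.warn("no candidate peaks under the given thresholds")

    sub = matrix.intensity.loc[cand_index]
    means = {s: sub[ids].mean(axis=1).to_numpy() for s, ids in groups.items()}
    ranges = {
        s: (sub[ids].max(axis=1) - sub[ids].min(axis=1)).to_numpy()
        for s, ids in groups.items()
    }
    ranges_ok = np.all([r < range_max for r in ranges.values()], axis=0)

    labels = np.full(len(cand_index), "unassigned", dtype=object)
    for name in _CLUSTER_PRECEDENCE:
        subset = SIX_STATE_CLUSTERS[name]
        in_states = sorted(subset)
        out_states = sorted(set(STATES) - subset)
        in_min = np.min([means[s] for s in in_states], axis=0)
        out_max = np.max([means[s] for s in out_states], axis=0)
        match = (labels == "unassigned") & ranges_ok & (in_min - out_max > sep)
        labels[match] = name
    label_s = pd.Series(labels, index=cand_index, name="cluster")
    counts = label_s.value_counts().reindex(
        list(SIX_STATE_CLUSTERS) + ["unassigned"], fill_value=0
    )
    total = max(len(cand_index), 1)
    return SixStateResult(label_s, counts, counts / total, cand_index)
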