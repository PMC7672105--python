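"""Cell-type signature scores from expression data and their relation to
clinical skin fibrosis severity (mRSS).

Signature genes are the nearest genes of each cell type's specific peaks.
A signature score for an expression array is the mean normalized expression
of the signature genes, after removing treatment-response genes so that the
drug effect does not masquerade as a cell-type trend. Scores are related
to mRSS by Pearson correlation and, within patients, by a paired t-test
between each patient's lowest- and highest-mRSS timepoints.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import welch_ttest


def read_expression(path) -> pd.DataFrame:
    """Genes x arrays normalized expression TSV."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.columns.duplicated().any():
        raise ValueError("duplicate array ids")
    if not np.isfinite(expr.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    return expr


def read_clinical(path) -> pd.DataFrame:
    """Clinical table TSV: array_id, patient_id, timepoint, mrss, phase."""
    clin = pd.read_csv(path, sep="\t", dtype={"array_id": str, "patient_id": str})
    required = {"array_id", "patient_id", "timepoint", "mrss", "phase"}
    if not required <= set(clin.columns):
        raise ValueError(f"clinical table needs columns {sorted(required)}")
    if clin.duplicated(["patient_id", "timepoint"]).any():
        raise ValueError("(patient_id, timepoint) must be unique")
    if (clin["mrss"] < 0).any():
        raise ValueError("mrss must be >= 0")
    return clin.set_index("array_id", drop=False)


def signature_genes(
    specificity_calls: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, set[str]]:
    """Per cell type, the deduplicated nearest genes of its specific peaks."""
    out: dict[str, set[str]] = {}
    called = specificity_calls[specificity_calls["cell_type"] != "none"]
    if called.empty:
        warnings.warn("no specific peaks; signature gene sets are empty")
    for ct, grp in called.groupby("cell_type"):
        genes = set(annotation.loc[grp.index, "gene_id"]) - {"NA"}
        out[str(ct)] = genes
    return out


def treatment_response_genes(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    lfc_thr: float = 2.0,
    p_thr: float = 0.005,
) -> list[str]:
    """Genes responding to treatment: differential between treated and
    baseline arrays at |log2fc| > lfc_thr and p < p_thr (Welch t-test)."""
    treated = clinical.index[clinical["phase"] == "treated"]
    baseline = clinical.index[clinical["phase"] == "baseline"]
    if len(treated) < 2 or len(baseline) < 2:
        raise ValueError("need >= 2 arrays per treatment phase")
    A = expr[list(treated)].to_numpy()
    B = expr[list(baseline)].to_numpy()
    lfc = A.mean(axis=1) - B.mean(axis=1)
    p = welch_ttest(A, B)
    hit = (np.abs(lfc) > lfc_thr) & (p < p_thr)
    return list(expr.index[hit])


def signature_scores(
    expr: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    exclude: set[str] | list[str] = (),
) -> pd.DataFrame:
    """Cell-type x array signature scores: mean expression of each set
    (minus excluded genes) restricted to measured genes."""
    exclude = set(exclude)
    measured = set(expr.index)
    rows = {}
    for ct, genes in gene_sets.items():
        usable = sorted((genes - exclude) & measured)
        if not usable:
            warnings.warn(f"signature for {ct} empty after exclusion; scores NaN")
            rows[ct] = pd.Series(np.nan, index=expr.columns)
        else:
            rows[ct] = expr.loc[usable].mean(axis=0)
    return pd.DataFrame(rows).T


def correlate_mrss(scores: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Pearson R of each cell type's signature score against mRSS with a
    two-tailed t-statistic P-value (t = R sqrt((n-2)/(1-R^2)), n-2 df)."""
    arrays = [a for a in scores.columns if a in clinical.index]
    mrss = clinical.loc[arrays, "mrss"].to_numpy(dtype=float)
    rows = []
    for ct in scores.index:
        x = scores.loc[ct, arrays].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(mrss)
        n = int(ok.sum())
        if n < 3 or np.std(x[ok]) == 0 or np.std(mrss[ok]) == 0:
            warnings.warn(f"{ct}: degenerate data for correlation")
            rows.append({"cell_type": ct, "r": np.nan, "p": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x[ok], mrss[ok])
        rows.append({"cell_type": ct, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows).set_index("cell_type")


def paired_low_high(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    min_delta: float = 5.0,
) -> pd.DataFrame:
    """Paired test of signature scores between each patient's lowest- and
    highest-mRSS timepoints.

    Patients qualify when max(mRSS) - min(mRSS) > min_delta (strict); mRSS
    ties within a patient resolve to the earliest timepoint. Returns per
    cell type the paired two-tailed t P-value, mean High-Low difference and
    the number of patients included.
    """
    pairs = []  # (low_array, high_array)
    for _, grp in clinical.groupby("patient_id"):
        grp = grp.sort_values("timepoint", kind="stable")
        lo = grp.iloc[int(np.argmin(grp["mrss"].to_numpy()))]
        hi = grp.iloc[int(np.argmax(grp["mrss"].to_numpy()))]
        if hi["mrss"] - lo["mrss"] > min_delta:
            pairs.append((lo["array_id"], hi["array_id"]))
    if len(pairs) < 2:
        raise ValueError("fewer than 2 patients pass the mRSS range filter")
    low_ids = [p[0] for p in pairs]
    high_ids = [p[1] for p in pairs]
    rows = []
    for ct in scores.index:
        low = scores.loc[ct, low_ids].to_numpy(dtype=float)
        high = scores.loc[ct, high_ids].to_numpy(dtype=float)
        diff = high - low
        if np.allclose(diff, 0):
            warnings.warn(f"{ct}: all paired differences zero; P set to 1")
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(high, low)
        rows.append(
            {"cell_type": ct, "t": t, "p": p, "mean_diff": diff.mean(), "n": len(pairs)}
        )
    return pd.DataFrame(rows).set_index("cell_type")
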