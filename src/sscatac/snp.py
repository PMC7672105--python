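"""GWAS-SNP enrichment in accessible chromatin via deviation scores.

Trait-associated SNPs (GRASP-style catalog) are filtered at an association
P-value threshold, overlapped with the ATAC-seq peak universe to form a
trait-by-peak membership matrix, and each trait's accessibility deviation
is computed per sample: the relative excess of observed reads in the
trait's peaks over the expectation from the peak set's average
accessibility. A background z-score compares the raw deviation with
deviations of random peak sets matched on mean accessibility.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import AccessibilityMatrix, PeakSet

DEFAULT_THRESHOLDS = (0.05, 1e-3, 1e-5, 1e-6, 1e-8)


def read_snp_catalog(path) -> pd.DataFrame:
    """Read a trait-SNP catalog TSV (trait, chrom, pos 1-based, p).

    Positions are converted to 0-based on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"trait": str, "chrom": str})
    required = {"trait", "chrom", "pos", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"catalog needs columns {sorted(required)}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ValueError("association p-values must lie in (0, 1]")
    df = df.copy()
    df["pos0"] = df["pos"].astype(int) - 1
    return df


def filter_catalog(
    catalog: pd.DataFrame, p_threshold: float, min_snps: int = 20
) -> dict[str, pd.DataFrame]:
    """Retain SNPs with association p below threshold; drop sparse traits.

    Traits retaining fewer than ``min_snps`` SNPs are discarded (small SNP
    sets make the deviation statistically unstable).
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    if catalog.empty:
        warnings.warn("empty SNP catalog")
        return {}
    kept = catalog[catalog["p"] < p_threshold] if p_threshold < 1 else catalog
    out = {}
    for trait, grp in kept.groupby("trait"):
        if len(grp) >= min_snps:
            out[str(trait)] = grp.reset_index(drop=True)
    return out


def overlap_traits_peaks(
    trait_sets: dict[str, pd.DataFrame], peaks: PeakSet
) -> pd.DataFrame:
    """Trait-by-peak binary membership: 1 iff >=1 trait SNP falls in the peak.

    A SNP at 0-based position p is inside peak [s, e) iff s <= p < e.
    """
    members = np.zeros((len(trait_sets), len(peaks)), dtype=np.int8)
    chroms = np.array([p.interval.chrom for p in peaks], dtype=object)
    starts = np.array([p.interval.start for p in peaks])
    ends = np.array([p.interval.end for p in peaks])
    for t, (_, snps) in enumerate(trait_sets.items()):
        pos_by_chrom = {
            str(c): np.sort(grp["pos0"].to_numpy())
            for c, grp in snps.groupby("chrom")
        }
        for chrom, pos in pos_by_chrom.items():
            rows = np.flatnonzero(chroms == chrom)
            # peak contains a SNP iff some sorted position falls in [start, end)
            lo = np.searchsorted(pos, starts[rows], side="left")
            hi = np.searchsorted(pos, ends[rows], side="left")
            members[t, rows[hi > lo]] = 1
    return pd.DataFrame(members, index=list(trait_sets), columns=peaks.ids)


def deviation_scores(
    membership: pd.DataFrame,
    matrix: AccessibilityMatrix,
    n_background: int = 50,
    n_bins: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw deviations and background-corrected z-scores per trait and sample.

    Raw deviation y_tj = (O_tj - E_tj) / E_tj with O the observed reads in
    the trait's member peaks and E = f_t * T_j, where f_t is the member
    peaks' share of total mean accessibility and T_j the sample total.
    The z-score standardizes y against ``n_background`` random peak sets
    drawn to match the member set's mean-accessibility bin profile.
    """
    D = matrix.raw.reindex(membership.columns).to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("membership peak universe does not match matrix")
    M = membership.to_numpy(dtype=float)
    xbar = D.mean(axis=1)
    total_xbar = xbar.sum()
    T = D.sum(axis=0)

    def _raw_dev(member_matrix: np.ndarray) -> np.ndarray:
        O = member_matrix @ D
        f = (member_matrix @ xbar) / total_xbar
        E = np.outer(f, T)
        with np.errstate(invalid="ignore", divide="ignore"):
            y = (O - E) / E
        bad = E == 0
        if bad.any():
            warnings.warn("zero expected counts; deviations set to NaN")
            y[bad] = np.nan
        return y

    y = _raw_dev(M)

    # mean-accessibility bins for bias-matched background sets
    rng = np.random.default_rng(seed)
    bin_edges = np.quantile(xbar, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(bin_edges, xbar, side="right") - 1, 0, n_bins - 1)
    bin_members = [np.flatnonzero(bins == b) for b in range(n_bins)]

    z = np.full_like(y, np.nan)
    for t in range(M.shape[0]):
        profile = np.bincount(bins[M[t] > 0], minlength=n_bins)
        bg = np.zeros((n_background, D.shape[0]))
        for r in range(n_background):
            for b, need in enumerate(profile):
                if need == 0:
                    continue
                pool = bin_members[b]
                take = rng.choice(pool, size=min(need, len(pool)), replace=False)
                bg[r, take] = 1
        y_bg = _raw_dev(bg)
        mu = np.nanmean(y_bg, axis=0)
        sd = np.nanstd(y_bg, axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            zt = (y[t] - mu) / sd
        zt[sd == 0] = np.nan
        z[t] = zt

    idx, cols = membership.index, matrix.sample_ids
    return (
        pd.DataFrame(y, index=idx, columns=cols),
        pd.DataFrame(z, index=idx, columns=cols),
    )


def enrichment_by_cell_type(deviations: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean deviation per trait and cell type (columns ordered by first
    appearance in the metadata)."""
    meta = meta.loc[[s for s in deviations.columns if s in meta.index]]
    out = {}
    for ct in meta["cell_type"].unique():
        samples = meta.index[meta["cell_type"] == ct]
        out[ct] = deviations[list(samples)].mean(axis=1)
    return pd.DataFrame(out)


def deviation_sweep(
    catalog: pd.DataFrame,
    peaks: PeakSet,
    matrix: AccessibilityMatrix,
    meta: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    min_snps: int = 20,
    n_background: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the deviation analysis across association-P thresholds.

    Returns a long-format frame (threshold, trait, cell_type,
    mean_raw_dev, mean_z).
    """
    rows = []
    for thr in thresholds:
        trait_sets = filter_catalog(catalog, thr, min_snps=min_snps)
        if not trait_sets:
            continue
        membership = overlap_traits_peaks(trait_sets, peaks)
        raw, z = deviation_scores(
            membership, matrix, n_background=n_background, seed=seed
        )
        mean_raw = enrichment_by_cell_type(raw, meta)
        mean_z = enrichment_by_cell_type(z, meta)
        for trait in mean_raw.index:
            for ct in mean_raw.columns:
                rows.append(
                    {
                        "threshold": thr,
                        "trait": trait,
                        "cell_type": ct,
                        "mean_raw_dev": mean_raw.loc[trait, ct],
                        "mean_z": mean_z.loc[trait, ct],
                    }
                )
    return pd.DataFrame(rows)
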