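"""Motif occupancy and module-map-style motif enrichment.

Motif hits scanned over the genome are reduced to a binary peak-by-motif
occupancy matrix; enrichment of each motif in each peak set (e.g. a cell
type's specific peaks) against the peak universe is a hypergeometric test
in both directions, BH-corrected over all (motif, set) pairs, reported as
a signed -log10 adjusted p (positive = enriched, negative = depleted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import PeakSet
from .differential import benjamini_hochberg


def read_motif_hits_bed(path) -> pd.DataFrame:
    """Motif hits from BED with the name column carrying the motif id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "motif_id"],
        dtype={"chrom": str, "motif_id": str},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("motif hits must have end > start")
    return df


def occupancy_matrix(peaks: PeakSet, motif_hits: pd.DataFrame) -> pd.DataFrame:
    """Binary peak-by-motif matrix: 1 iff >=1 hit overlaps the peak
    (half-open interval overlap)."""
    motifs = list(pd.unique(motif_hits["motif_id"]))
    occ = np.zeros((len(peaks), len(motifs)), dtype=np.int8)
    chroms = np.array([p.interval.chrom for p in peaks], dtype=object)
    starts = np.array([p.interval.start for p in peaks])
    ends = np.array([p.interval.end for p in peaks])
    for m, motif in enumerate(motifs):
        hits = motif_hits[motif_hits["motif_id"] == motif]
        for chrom, grp in hits.groupby("chrom"):
            rows = np.flatnonzero(chroms == str(chrom))
            if len(rows) == 0:
                continue
            hs = grp["start"].to_numpy()
            he = grp["end"].to_numpy()
            # overlap iff hit.start < peak.end and hit.end > peak.start
            hit = (hs[None, :] < ends[rows, None]) & (he[None, :] > starts[rows, None])
            occ[rows[hit.any(axis=1)], m] = 1
    return pd.DataFrame(occ, index=peaks.ids, columns=motifs)


def module_map(
    occupancy: pd.DataFrame,
    peak_sets: dict[str, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric motif enrichment of peak sets against the universe.

    For each (motif, set): with N universe peaks, K motif-bearing, n in the
    set and k motif-bearing in the set, the enriched tail is P(X >= k) and
    the depleted tail P(X <= k). The smaller tail fixes the direction; BH
    runs across all pairs. Output is long format with signed_score =
    sign * -log10(adj_p) and a pass flag at ``alpha``.
    """
    universe = list(occupancy.index)
    N = len(universe)
    rows = []
    for set_name, members in peak_sets.items():
        members = list(members)
        if not set(members) <= set(universe):
            raise ValueError(f"peak set {set_name} not within the occupancy universe")
        n = len(members)
        for motif in occupancy.columns:
            col = occupancy[motif]
            K = int(col.sum())
            if n == 0:
                rows.append(
                    {"motif": motif, "set": set_name, "k": np.nan, "n": 0,
                     "K": K, "N": N, "p": np.nan, "direction": "none"}
                )
                continue
            k = int(col.loc[members].sum())
            p_enr = float(hypergeom.sf(k - 1, N, K, n))
            p_dep = float(hypergeom.cdf(k, N, K, n))
            if p_enr <= p_dep:
                p, direction = p_enr, "enriched"
            else:
                p, direction = p_dep, "depleted"
            rows.append(
                {"motif": motif, "set": set_name, "k": k, "n": n, "K": K,
                 "N": N, "p": min(p, 1.0), "direction": direction}
            )
    out = pd.DataFrame(rows)
    out["adj_p"] = benjamini_hochberg(out["p"].to_numpy())
    sign = np.where(out["direction"] == "enriched", 1.0, -1.0)
    with np.errstate(divide="ignore"):
        out["signed_score"] = sign * -np.log10(out["adj_p"])
    out.loc[out["adj_p"] >= 1.0, "signed_score"] = 0.0
    out["pass"] = out["adj_p"] < alpha
    return out
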