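"""TF footprinting from Tn5 insertion positions.

Mapped read ends are shifted (+4 on the plus strand, -5 on the minus
strand) so each record marks a single Tn5 cleavage position. Groups of
samples are depth-equalized by seeded downsampling, and insertions are
aggregated around aligned motif sites into an average per-offset profile;
a dip at the motif center relative to the flanks is the footprint left by
a bound factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class InsertionSet:
    """Tn5 insertion points with a provenance guard against double-shifting."""

    chroms: np.ndarray            # object array of chromosome names
    positions: np.ndarray         # int array, 0-based
    group: str = ""
    shifted: bool = True

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.positions):
            raise ValueError("chroms and positions must align")
        if len(self.positions) and self.positions.min() < 0:
            raise ValueError("insertion positions must be >= 0")

    def __len__(self) -> int:
        return len(self.positions)


def read_reads_bed(path) -> pd.DataFrame:
    """Read mapped reads from BED6 (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "strand": str},
    )
    if not set(df["strand"]) <= {"+", "-"}:
        raise ValueError("read strand must be + or -")
    if (df["end"] <= df["start"]).any():
        raise ValueError("reads must have end > start")
    return df


def read_motif_sites_bed(path) -> pd.DataFrame:
    """Motif occupancy sites from BED6; name column holds the motif id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "motif_id", "score", "strand"],
        dtype={"chrom": str, "motif_id": str, "strand": str},
    )
    lengths = (df["end"] - df["start"]).unique()
    if len(lengths) > 1:
        raise ValueError("all sites of a motif set must share one length")
    return df


def tn5_shift(reads: pd.DataFrame, group: str = "") -> InsertionSet:
    """Convert mapped reads to Tn5 cleavage positions.

    Plus-strand reads insert at start + 4; minus-strand reads at their 5'
    base (end - 1) shifted by -5. Records that would land below position 0
    are dropped (and counted in the log). The shift is not idempotent, so a
    provenance flag on the frame guards against applying it twice.
    """
    if reads.attrs.get("tn5_shifted"):
        raise ValueError("reads already Tn5-shifted; refusing to shift twice")
    reads.attrs["tn5_shifted"] = True
    plus = reads["strand"].to_numpy() == "+"
    pos = np.where(
        plus,
        reads["start"].to_numpy() + 4,
        reads["end"].to_numpy() - 1 - 5,
    )
    keep = pos >= 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("tn5_shift: dropped %d read(s) shifted below position 0", dropped)
    return InsertionSet(
        chroms=reads["chrom"].to_numpy(dtype=object)[keep],
        positions=pos[keep].astype(np.int64),
        group=group,
        shifted=True,
    )


def write_insertions_bed(ins: InsertionSet, path) -> None:
    pd.DataFrame(
        {"chrom": ins.chroms, "start": ins.positions, "end": ins.positions + 1}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_insertions_bed(path, group: str = "") -> InsertionSet:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end"], dtype={"chrom": str}
    )
    return InsertionSet(
        chroms=df["chrom"].to_numpy(dtype=object),
        positions=df["start"].to_numpy(dtype=np.int64),
        group=group,
    )


def downsample(
    insertions_by_group: dict[str, InsertionSet], n: int | str = "min", seed: int = 0
) -> dict[str, InsertionSet]:
    """Equalize group depths by uniform sampling without replacement.

    ``n="min"`` (default) uses the smallest group's depth — the analog of
    drawing an equal number of reads from every clinical category.
    """
    sizes = {g: len(ins) for g, ins in insertions_by_group.items()}
    if n == "min":
        target = min(sizes.values())
    else:
        target = int(n)
        small = [g for g, s in sizes.items() if s < target]
        if small:
            raise ValueError(
                f"group(s) {small} have fewer than n={target} insertions; "
                'use n="min"'
            )
    rng = np.random.default_rng(seed)
    out = {}
    for g in insertions_by_group:
        ins = insertions_by_group[g]
        idx = np.sort(rng.choice(len(ins), size=target, replace=False))
        out[g] = InsertionSet(ins.chroms[idx], ins.positions[idx], group=g)
    return out


@dataclass
class FootprintProfile:
    offsets: np.ndarray           # -halfwidth .. +halfwidth
    mean_insertions: np.ndarray   # per-site mean insertion count per offset
    n_sites: int
    group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean_insertions, "group": self.group}
        )


def aggregate_footprint(
    insertions: InsertionSet, motif_sites: pd.DataFrame, halfwidth: int = 50
) -> FootprintProfile:
    """Average insertion profile around aligned motif site centers.

    Each site contributes its insertion counts at offsets -halfwidth..
    +halfwidth from its center; minus-strand sites are mirrored so motif
    orientation aligns. The profile is the per-offset mean over sites.
    """
    if len(motif_sites) == 0:
        raise ValueError("no motif sites")
    motif_len = int((motif_sites["end"] - motif_sites["start"]).iloc[0])
    if halfwidth < motif_len / 2:
        raise ValueError("halfwidth must cover at least half the motif")
    width = 2 * halfwidth + 1
    total = np.zeros(width)
    pos_by_chrom = {
        str(c): np.sort(insertions.positions[insertions.chroms == c])
        for c in pd.unique(insertions.chroms)
    }
    for _, site in motif_sites.iterrows():
        pos = pos_by_chrom.get(str(site["chrom"]))
        if pos is None:
            continue
        center = (int(site["start"]) + int(site["end"])) // 2
        lo = np.searchsorted(pos, center - halfwidth, side="left")
        hi = np.searchsorted(pos, center + halfwidth, side="right")
        offs = pos[lo:hi] - center
        if site.get("strand", "+") == "-":
            offs = -offs
        total += np.bincount(offs + halfwidth, minlength=width)[:width]
    mean = total / len(motif_sites)
    return FootprintProfile(
        offsets=np.arange(-halfwidth, halfwidth + 1),
        mean_insertions=mean,
        n_sites=len(motif_sites),
        group=insertions.group,
    )
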