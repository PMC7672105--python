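"""Receptor-ligand communication alteration between cell types.

Gene-level accessibility (summed peak intensities) stands in for
expression. For each gene in each cell type an Alteration Score (AS) is
the log2 fold change of mean accessibility in affected versus normal
samples. For an ordered cell-type pair, the Strength of Interaction
Alteration of a receptor (in the receiver) and ligand (in the sender) is

    SIA = 0                        if |AS_receptor| < 1 or |AS_ligand| < 1
        = AS_receptor + AS_ligand  otherwise,

optionally zeroed when the two scores disagree in sign (an interaction
is only called coherently up- or down-regulated). Interactions with
|SIA| above a threshold (default 7) are retained and labelled by sign.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def read_lr_pairs(path) -> pd.DataFrame:
    """Ligand-receptor pair TSV with columns ligand, receptor[, source]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("LR table needs columns ligand, receptor")
    if "source" not in df.columns:
        df["source"] = "user"
    if df["ligand"].isna().any() or df["receptor"].isna().any():
        raise ValueError("empty gene names in LR table")
    if df.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate ligand/receptor pair")
    return df


def alteration_scores(
    gene_acc_affected: pd.DataFrame,
    gene_acc_normal: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per (cell_type, gene) alteration score.

    Inputs are gene x sample accessibility tables already restricted to one
    cell type's affected / normal samples, or dicts of such tables keyed by
    cell type (see :func:`alteration_scores_by_cell_type`). AS =
    log2((mean_affected + c) / (mean_normal + c)); a gene present in only
    one condition gets NaN.
    """
    genes = gene_acc_affected.index.union(gene_acc_normal.index)
    mean_aff = gene_acc_affected.mean(axis=1).reindex(genes)
    mean_norm = gene_acc_normal.mean(axis=1).reindex(genes)
    as_ = np.log2((mean_aff + pseudocount) / (mean_norm + pseudocount))
    return pd.DataFrame({"AS": as_}, index=genes)


def alteration_scores_by_cell_type(
    gene_acc: pd.DataFrame, meta: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Cell-type x gene AS table from a full gene accessibility matrix and
    sample metadata (states 'affected' vs 'normal')."""
    rows = {}
    for ct in meta["cell_type"].unique():
        aff = meta.index[(meta["cell_type"] == ct) & (meta["state"] == "affected")]
        nor = meta.index[(meta["cell_type"] == ct) & (meta["state"] == "normal")]
        if len(aff) == 0 or len(nor) == 0:
            logger.warning("cell type %s lacks affected or normal samples; skipped", ct)
            continue
        rows[ct] = alteration_scores(
            gene_acc[list(aff)], gene_acc[list(nor)], pseudocount
        )["AS"]
    return pd.DataFrame(rows).T


def sia(
    as_receptor: float, as_ligand: float, concordance_required: bool = True
) -> float:
    """Strength of Interaction Alteration for one receptor/ligand pair."""
    if math.isnan(as_receptor) or math.isnan(as_ligand):
        return float("nan")
    if abs(as_receptor) < 1 or abs(as_ligand) < 1:
        return 0.0
    if concordance_required and (as_receptor > 0) != (as_ligand > 0):
        return 0.0
    return as_receptor + as_ligand


@dataclass(frozen=True)
class InteractionAlteration:
    sender: str
    receiver: str
    ligand: str
    receptor: str
    as_ligand: float
    as_receptor: float
    sia: float
    direction: str  # up / down


def altered_interactions(
    as_table: pd.DataFrame,
    lr_pairs: pd.DataFrame,
    cell_types: list[str] | None = None,
    threshold: float = 7.0,
    concordance_required: bool = True,
) -> pd.DataFrame:
    """Scan every ordered (sender, receiver) cell-type pair and LR pair.

    ``as_table`` is cell_type x gene. Retains interactions with
    |SIA| > threshold (strict); direction is the SIA sign. Pairs with a
    missing AS on either side are skipped (logged).
    """
    if cell_types is None:
        cell_types = list(as_table.index)
    rows = []
    skipped = 0
    for sender in cell_types:
        for receiver in cell_types:
            for _, pair in lr_pairs.iterrows():
                lig, rec = pair["ligand"], pair["receptor"]
                if lig not in as_table.columns or rec not in as_table.columns:
                    skipped += 1
                    continue
                as_l = float(as_table.loc[sender, lig])
                as_r = float(as_table.loc[receiver, rec])
                if math.isnan(as_l) or math.isnan(as_r):
                    skipped += 1
                    continue
                s = sia(as_r, as_l, concordance_required)
                if abs(s) > threshold:
                    rows.append(
                        {
                            "sender": sender,
                            "receiver": receiver,
                            "ligand": lig,
                            "receptor": rec,
                            "AS_ligand": as_l,
                            "AS_receptor": as_r,
                            "SIA": s,
                            "direction": "up" if s > 0 else "down",
                        }
                    )
    if skipped:
        logger.info("altered_interactions: skipped %d pair evaluations missing AS", skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "sender", "receiver", "ligand", "receptor",
            "AS_ligand", "AS_receptor", "SIA", "direction",
        ],
    )


def interaction_summary(interactions: pd.DataFrame) -> pd.DataFrame:
    """Per cell type, the number of retained up / down interactions it
    participates in (as sender or receiver; counted once per cell type)."""
    counts: dict[str, dict[str, int]] = {}
    for _, row in interactions.iterrows():
        involved = {row["sender"], row["receiver"]}
        for ct in involved:
            entry = counts.setdefault(ct, {"n_up": 0, "n_down": 0})
            entry["n_up" if row["direction"] == "up" else "n_down"] += 1
    out = pd.DataFrame(counts).T
    if out.empty:
        out = pd.DataFrame(columns=["n_up", "n_down"])
    out.index.name = "cell_type"
    return out.astype(int).sort_values("n_up", ascending=False)
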