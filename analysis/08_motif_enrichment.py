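"""Module-map motif enrichment over cell-type-specific peak sets.

Builds the binary peak-by-motif occupancy matrix from scanned hit
locations and scores each motif in each cell type's specific peaks
against the full peak universe (hypergeometric, BH-corrected, signed).
"""

from pathlib import Path

import pandas as pd

from sscatac import core, motifs, simulate

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    peaks = core.read_peaks_bed(BASE / "sim" / "peaks.bed")
    hits = motifs.read_motif_hits_bed(BASE / "sim" / "motif_hits.bed")
    calls = pd.read_csv(BASE / "specific_peaks.tsv", sep="\t", index_col=0)
    truth = simulate.GroundTruth.from_json(BASE / "sim" / "ground_truth.json")

    occ = motifs.occupancy_matrix(peaks, hits)
    peak_sets = {
        ct: list(grp.index)
        for ct, grp in calls[calls["cell_type"] != "none"].groupby("cell_type")
    }
    res = motifs.module_map(occ, peak_sets)
    res.to_csv(BASE / "motif_enrichment.tsv", sep="\t", index=False)

    top = res.loc[res["signed_score"].idxmax()]
    print(f"{occ.shape[1]} motifs x {len(peak_sets)} peak sets "
          f"over a universe of {occ.shape[0]} peaks")
    print(f"top enrichment: {top['motif']} in {top['set']} "
          f"(signed score {top['signed_score']:.1f}); the planted motif was "
          f"concentrated in CD4-specific peaks")


if __name__ == "__main__":
    main()
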