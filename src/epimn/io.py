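"""On-disk formats for the multiome matrices.

A matrix bundle is the conventional trio — Matrix-Market counts plus
features.tsv and barcodes.tsv — together with cell_meta.tsv carrying the
per-cell condition/cell_type/sample annotations. ATAC feature tables carry
peak coordinates and can be exported as BED.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .multiome import CellFeatureMatrix

__all__ = ["save_matrix_bundle", "load_matrix_bundle", "write_peaks_bed"]


def save_matrix_bundle(matrix: CellFeatureMatrix, out_dir) -> None:
    """Write counts.mtx, features.tsv, barcodes.tsv, cell_meta.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "counts.mtx", matrix.counts)
    matrix.feature_meta.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.Series(
        [f"cell{i}" for i in range(matrix.n_cells)], name="barcode"
    ).to_csv(out / "barcodes.tsv", sep="\t", index=False)
    matrix.cell_meta.to_csv(out / "cell_meta.tsv", sep="\t", index=False)
    (out / "modality.txt").write_text(matrix.modality + "\n")


def load_matrix_bundle(in_dir) -> CellFeatureMatrix:
    src = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(src / "counts.mtx"))
    feature_meta = pd.read_csv(src / "features.tsv", sep="\t")
    cell_meta = pd.read_csv(src / "cell_meta.tsv", sep="\t")
    modality = (src / "modality.txt").read_text().strip()
    return CellFeatureMatrix(counts, modality, cell_meta, feature_meta)


def write_peaks_bed(matrix: CellFeatureMatrix, path) -> None:
    """BED of ATAC peak coordinates in feature order."""
    if matrix.modality != "ATAC":
        raise ValueError("peak BED export needs an ATAC matrix")
    with open(path, "w") as fh:
        for r in matrix.feature_meta.itertuples(index=False):
            fh.write(f"{r.chrom}\t{int(r.start)}\t{int(r.end)}\t{r.feature_id}\n")
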