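"""Reading and writing peak-by-cell count matrices and result tables.

Count matrices use the 10x-style trio: a MatrixMarket coordinate file of
integer counts (peaks as rows, cells as columns), a BED file of peak
coordinates (0-based half-open) and a TSV of cell barcodes with an optional
group column. Results are written as a TSV with missing values as "NA".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["CountMatrix", "read_counts", "read_counts_csv", "write_counts",
           "write_results", "read_results"]

RESULT_COLUMNS = ["peak_id", "chrom", "start", "end", "lambda_lr", "df",
                  "pvalue", "fdr", "log2fc_mu", "log2fc_p", "log2fc_phi",
                  "status"]


@dataclass
class CountMatrix:
    """Peaks-by-cells integer count matrix with peak coordinates, cell
    barcodes and an optional two-level group label per cell.

    ``counts`` is kept sparse (CSR); row access never densifies the full
    matrix.
    """

    counts: sparse.csr_matrix
    peaks: pd.DataFrame            # columns chrom, start, end, peak_id
    barcodes: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self):
        n_peaks, n_cells = self.counts.shape
        if len(self.peaks) != n_peaks:
            raise ValueError(
                f"peak table has {len(self.peaks)} rows but the matrix has "
                f"{n_peaks} peaks")
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"{len(self.barcodes)} barcodes but the matrix has "
                f"{n_cells} cells")
        if self.groups is not None and len(self.groups) != n_cells:
            raise ValueError("group labels must match the number of cells")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def peak_counts(self, i: int) -> np.ndarray:
        """Dense count vector of one peak across all cells."""
        return np.asarray(self.counts.getrow(i).todense()).ravel()

    def require_two_groups(self) -> np.ndarray:
        if self.groups is None:
            raise ValueError("no group labels attached to this matrix")
        levels = np.unique(self.groups)
        if levels.size != 2:
            raise ValueError(
                f"exactly two group labels required, found {levels.size}")
        return self.groups


def _validate_integer_matrix(mat: sparse.coo_matrix) -> sparse.csr_matrix:
    data = mat.data
    bad = np.flatnonzero((data != np.floor(data)) | (data < 0))
    if bad.size:
        i = bad[0]
        raise ValueError(
            f"non-integer or negative count {data[i]} at peak "
            f"{mat.row[i] + 1}, cell {mat.col[i] + 1} (1-based)")
    out = mat.tocsr()
    out.data = out.data.astype(np.int64)
    return out


def _read_bed(path) -> pd.DataFrame:
    try:
        bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:
        raise ValueError(f"malformed BED file {path}: {exc}") from exc
    if bed.shape[1] < 3:
        raise ValueError(f"BED file {path} needs at least 3 columns, "
                         f"found {bed.shape[1]}")
    peaks = bed.iloc[:, :3].copy()
    peaks.columns = ["chrom", "start", "end"]
    if not (np.issubdtype(peaks["start"].dtype, np.integer)
            and np.issubdtype(peaks["end"].dtype, np.integer)):
        raise ValueError(f"BED file {path} has non-integer coordinates")
    if bed.shape[1] >= 4:
        peaks["peak_id"] = bed.iloc[:, 3].astype(str)
    else:
        peaks["peak_id"] = (peaks["chrom"].astype(str) + ":"
                            + peaks["start"].astype(str) + "-"
                            + peaks["end"].astype(str))
    return peaks


def read_counts(path_mtx, path_peaks_bed, path_barcodes_tsv) -> CountMatrix:
    """Load a MatrixMarket + BED + barcodes trio into a CountMatrix.

    The barcodes TSV has one barcode per line with an optional second
    column holding the group label.
    """
    mat = spio.mmread(str(path_mtx))
    counts = _validate_integer_matrix(sparse.coo_matrix(mat))
    peaks = _read_bed(path_peaks_bed)
    bc = pd.read_csv(path_barcodes_tsv, sep="\t", header=None)
    barcodes = bc.iloc[:, 0].astype(str).to_numpy()
    groups = (bc.iloc[:, 1].astype(str).to_numpy()
              if bc.shape[1] >= 2 else None)
    if counts.shape[0] != len(peaks):
        raise ValueError(
            f"matrix has {counts.shape[0]} peaks but BED lists {len(peaks)}")
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[1]} cells but barcodes file lists "
            f"{len(barcodes)}")
    return CountMatrix(counts=counts, peaks=peaks, barcodes=barcodes,
                       groups=groups)


def read_counts_csv(path, groups=None) -> CountMatrix:
    """Dense CSV fallback for tiny teaching examples: rows are peaks
    (index = peak id), columns are cell barcodes."""
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    if np.any(vals < 0) or np.any(vals != np.floor(vals)):
        raise ValueError(f"CSV {path} contains non-integer or negative counts")
    peaks = pd.DataFrame({
        "chrom": "synthetic",
        "start": np.arange(len(df)) * 1000,
        "end": np.arange(len(df)) * 1000 + 500,
        "peak_id": df.index.astype(str),
    })
    return CountMatrix(counts=sparse.csr_matrix(vals.astype(np.int64)),
                       peaks=peaks,
                       barcodes=df.columns.to_numpy(dtype=str),
                       groups=None if groups is None else np.asarray(groups))


def write_counts(cm: CountMatrix, out_dir) -> None:
    """Write the MTX/BED/barcodes trio into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), cm.counts.tocoo(), field="integer")
    cm.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        out / "peaks.bed", sep="\t", header=False, index=False)
    bc = pd.DataFrame({"barcode": cm.barcodes})
    if cm.groups is not None:
        bc["group"] = cm.groups
    bc.to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-peak result table as TSV, missing values as "NA".

    Columns not present in ``results`` (e.g. coordinates when the input was
    a bare matrix) are filled with NA; column order is stable.
    """
    out = results.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA",
               float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
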