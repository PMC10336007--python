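"""Contact probability maps: I/O, validation, prominent contacts, P(s) curves.

A contact map is a symmetric matrix ``P_ij`` of pairwise contact probabilities
at fixed genomic resolution (e.g. 200 bp Micro-C bins).  It is both the input
that constrains ensemble construction and the quantity recomputed from an
ensemble for validation.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import h5py
import numpy as np

logger = logging.getLogger(__name__)

MAX_BINS = 5000  # dense storage only; desk-scale limit

__all__ = [
    "ContactMap",
    "ProminentContactSet",
    "read_contact_map",
    "write_contact_map",
    "find_prominent_contacts",
    "contact_probability_curve",
]


@dataclass
class ContactMap:
    """A validated symmetric contact probability matrix with genomic metadata.

    Attributes
    ----------
    matrix : (n, n) ndarray
        Symmetric, entries in [0, 1], unit diagonal.
    resolution_bp : int
        Genomic span of one bin (200 for nucleosome-linker beads).
    chrom : str
        Chromosome label.
    start_bp : int
        0-based genomic start; bin ``b`` covers
        ``[start_bp + b*res, start_bp + (b+1)*res)``.
    """

    matrix: np.ndarray
    resolution_bp: int = 200
    chrom: str = "chrN"
    start_bp: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        validate_matrix(self.matrix)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_interval(self, b: int) -> tuple[int, int]:
        """Half-open genomic interval covered by bin ``b``."""
        lo = self.start_bp + b * self.resolution_bp
        return lo, lo + self.resolution_bp


@dataclass
class ProminentContactSet:
    """Pairs (i, j, P_ij), i < j, exceeding their separation stratum's mean + SD."""

    pairs: list[tuple[int, int, float]]
    source_map_id: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.pairs:
            return (np.empty(0, int), np.empty(0, int), np.empty(0, float))
        i, j, p = zip(*self.pairs)
        return np.asarray(i, int), np.asarray(j, int), np.asarray(p, float)


def validate_matrix(m: np.ndarray) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"contact matrix must be square, got shape {m.shape}")
    if m.shape[0] == 0:
        raise ValueError("contact matrix is empty")
    if m.shape[0] > MAX_BINS:
        raise ValueError(f"map exceeds the {MAX_BINS}-bin dense-storage limit")
    if not np.all(np.isfinite(m)):
        raise ValueError("contact matrix contains non-finite entries")
    if m.min() < -1e-9 or m.max() > 1 + 1e-9:
        raise ValueError(
            f"contact probabilities outside [0, 1]: range "
            f"[{m.min():.3g}, {m.max():.3g}]"
        )
    if not np.allclose(m, m.T, atol=1e-8, rtol=0):
        raise ValueError("contact matrix is not symmetric (asymmetry > 1e-8)")
    if not np.allclose(np.diag(m), 1.0, atol=1e-8):
        raise ValueError("contact matrix diagonal deviates from 1")


def _sanitize(m: np.ndarray) -> np.ndarray:
    """Symmetrize, clip round-off, force unit diagonal; warn on repairs."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"contact matrix must be square, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("contact matrix contains non-finite entries")
    if m.min() < -1e-9 or m.max() > 1 + 1e-9:
        raise ValueError(
            f"contact probabilities outside [0, 1]: range "
            f"[{m.min():.3g}, {m.max():.3g}]"
        )
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > 1e-8:
        logger.warning("symmetrizing contact matrix (max asymmetry %.3g)", asym)
    m = 0.5 * (m + m.T)
    m = np.clip(m, 0.0, 1.0)
    d = np.abs(np.diag(m) - 1.0).max() if m.size else 0.0
    if d > 1e-8:
        logger.warning("forcing unit diagonal (max deviation %.3g)", d)
    np.fill_diagonal(m, 1.0)
    return m


def read_contact_map(path: str | os.PathLike, format: str | None = None) -> ContactMap:
    """Read a contact map from dense TSV or HDF5.

    TSV: whitespace-delimited square matrix, optional first header line
    ``#chrom start resolution_bp``.  HDF5: dataset ``/matrix`` with attributes
    ``chrom``, ``start_bp``, ``resolution_bp``.

    The matrix is symmetrized as ``(M + M^T)/2`` (warning if asymmetry exceeds
    1e-8) and the diagonal forced to 1 (warning if it deviates).
    """
    path = os.fspath(path)
    if format is None:
        format = "hdf5" if path.endswith((".h5", ".hdf5")) else "dense-tsv"
    meta = {"chrom": "chrN", "start_bp": 0, "resolution_bp": 200}
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            m = f["matrix"][...]
            for k in meta:
                if k in f["matrix"].attrs:
                    v = f["matrix"].attrs[k]
                    meta[k] = v.decode() if isinstance(v, bytes) else v
    elif format == "dense-tsv":
        with open(path) as f:
            first = f.readline()
            rows = []
            if first.startswith("#"):
                parts = first[1:].split()
                if len(parts) >= 3:
                    meta = {
                        "chrom": parts[0],
                        "start_bp": int(parts[1]),
                        "resolution_bp": int(parts[2]),
                    }
            else:
                rows.append(first.split())
            for line in f:
                if line.strip():
                    rows.append(line.split())
        try:
            m = np.asarray(rows, dtype=float)
        except ValueError as e:
            raise ValueError(f"malformed dense TSV matrix in {path}: {e}") from e
    else:
        raise ValueError(f"unknown format {format!r}")
    return ContactMap(
        _sanitize(m),
        resolution_bp=int(meta["resolution_bp"]),
        chrom=str(meta["chrom"]),
        start_bp=int(meta["start_bp"]),
    )


def write_contact_map(
    cmap: ContactMap, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a contact map; ``read(write(m))`` round-trips (1e-12 for HDF5,
    printed precision for TSV, which uses 6 decimals)."""
    path = os.fspath(path)
    if format is None:
        format = "hdf5" if path.endswith((".h5", ".hdf5")) else "dense-tsv"
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("matrix", data=cmap.matrix)
            d.attrs["chrom"] = cmap.chrom
            d.attrs["start_bp"] = cmap.start_bp
            d.attrs["resolution_bp"] = cmap.resolution_bp
    elif format == "dense-tsv":
        header = f"#{cmap.chrom} {cmap.start_bp} {cmap.resolution_bp}"
        np.savetxt(path, cmap.matrix, fmt="%.6f", delimiter="\t", header=header,
                   comments="")
    else:
        raise ValueError(f"unknown format {format!r}")


def stratum_stats(matrix: np.ndarray, s: int) -> tuple[float, float]:
    """Mean and population SD of all entries at genomic separation ``s``."""
    vals = np.diagonal(matrix, offset=s)
    return float(vals.mean()), float(vals.std())


def find_prominent_contacts(cmap: ContactMap) -> ProminentContactSet:
    """Extract the map's prominent (strong) contacts.

    For each genomic separation ``s = |i - j| >= 2`` the mean ``mu_s`` and
    population standard deviation ``sigma_s`` over all entries at that
    separation are computed; a pair is prominent when ``P_ij >= mu_s + sigma_s``.
    Separations 0 and 1 are excluded (chain bonds already connect neighbours).
    A zero-variance stratum yields no prominent contacts: all its entries are
    equal, so none stands out.
    """
    m = cmap.matrix
    n = cmap.n_bins
    if n < 4:
        raise ValueError("prominent contacts need at least 4 bins")
    pairs: list[tuple[int, int, float]] = []
    for s in range(2, n):
        vals = np.diagonal(m, offset=s)
        mu = vals.mean()
        sd = vals.std()
        if sd == 0.0:
            continue
        (idx,) = np.nonzero(vals >= mu + sd)
        for i in idx:
            pairs.append((int(i), int(i + s), float(vals[i])))
    pairs.sort()
    return ProminentContactSet(pairs, source_map_id=f"{cmap.chrom}:{cmap.start_bp}")


def contact_probability_curve(cmap: ContactMap) -> np.ndarray:
    """Mean contact probability versus genomic separation.

    Returns an (n_bins, 2) array of ``(s, mean P at separation s)``; P(0) = 1.
    """
    m = cmap.matrix
    n = cmap.n_bins
    out = np.empty((n, 2))
    for s in range(n):
        out[s, 0] = s
        out[s, 1] = np.diagonal(m, offset=s).mean()
    return out
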