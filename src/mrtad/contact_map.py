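"""Containers and plain-text I/O for binned intra-chromosomal Hi-C contact maps.

A contact map is a symmetric ``n x n`` matrix ``W`` whose entry ``W[i, j]``
counts (or, after matrix balancing, weights) the pair-end read contacts
between genomic bins ``i`` and ``j`` of a single chromosome.  The row sum
``c_i`` is the *coverage* of bin ``i`` and ``N = sum(c) / 2`` is the total
number of read pairs mapped to the chromosome.

Two exchange formats are supported:

* **dense** — whitespace-delimited ``n`` rows by ``n`` columns, no header;
* **coo** — three whitespace-delimited columns ``i j value`` with 0-based
  bin indices; the upper triangle alone is sufficient (it is mirrored), and
  if both triangles are present they must agree.

Bins are 0-based internally; BED output uses standard 0-based half-open
coordinates with ``start = bin_index * bin_size``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMap",
    "MapFormatError",
    "MapValidationError",
    "read_contact_map",
    "write_contact_map",
    "ice_balance",
    "write_tads_bed",
    "write_boundary_scores",
    "read_boundary_scores",
]

#: relative tolerance for the symmetry check of W
SYMMETRY_RTOL = 1e-8


class MapFormatError(ValueError):
    """A file does not conform to the declared contact-map format."""


class MapValidationError(ValueError):
    """A contact map violates a structural invariant (negativity, asymmetry, ...)."""


@dataclass
class ContactMap:
    """Symmetric bin-level contact matrix for one chromosome.

    Parameters
    ----------
    chrom:
        Chromosome name (used verbatim in BED/bedGraph output).
    bin_size:
        Bin width in base pairs.
    W:
        Symmetric ``(n, n)`` array of non-negative, finite contact weights.
        Weights may be non-integer (e.g. after ICE balancing).  A tiny
        float asymmetry up to :data:`SYMMETRY_RTOL` (relative to the
        largest entry) is tolerated and symmetrized away on construction.
    """

    chrom: str
    bin_size: int
    W: np.ndarray
    #: set by :func:`ice_balance` on its output; ``None`` otherwise
    ice_converged: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise MapFormatError(f"contact matrix must be square, got shape {W.shape}")
        if not np.isfinite(W).all():
            raise MapValidationError("contact matrix contains non-finite entries")
        if (W < 0).any():
            raise MapValidationError("contact matrix contains negative entries")
        scale = float(np.abs(W).max()) if W.size else 0.0
        if scale > 0 and np.abs(W - W.T).max() > SYMMETRY_RTOL * scale:
            raise MapValidationError(
                "contact matrix is not symmetric within relative tolerance "
                f"{SYMMETRY_RTOL:g}"
            )
        # remove float-level asymmetry so downstream row/column sums agree exactly
        self.W = (W + W.T) / 2.0
        if self.bin_size <= 0:
            raise MapValidationError("bin_size must be a positive integer")

    @property
    def n(self) -> int:
        """Number of bins."""
        return self.W.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        """Per-bin coverage ``c_i = sum_j W[i, j]`` (row sums)."""
        return self.W.sum(axis=1)

    @property
    def total_reads(self) -> float:
        """Total read pairs ``N = sum_i c_i / 2``."""
        return float(self.coverage.sum()) / 2.0


def read_contact_map(
    path,
    format: str = "dense",
    *,
    chrom: str,
    bin_size: int,
    n_bins: int | None = None,
) -> ContactMap:
    """Read a contact map from a dense or COO triplet text file.

    For ``format="coo"`` the matrix size is ``n_bins`` when given, otherwise
    inferred as ``max(index) + 1``.  COO input is symmetrized: an entry given
    only in one triangle is mirrored; conflicting duplicates raise
    :class:`MapValidationError`.
    """
    if format == "dense":
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[0] != arr.shape[1]:
            raise MapFormatError(
                f"dense matrix in {path!s} is {arr.shape[0]}x{arr.shape[1]}, not square"
            )
        return ContactMap(chrom=chrom, bin_size=bin_size, W=arr)
    if format == "coo":
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            if n_bins is None:
                raise MapFormatError("empty coo file and no n_bins given")
            return ContactMap(chrom=chrom, bin_size=bin_size, W=np.zeros((n_bins, n_bins)))
        if data.shape[1] != 3:
            raise MapFormatError(
                f"coo file {path!s} must have 3 columns, found {data.shape[1]}"
            )
        ii = data[:, 0].astype(int)
        jj = data[:, 1].astype(int)
        vv = data[:, 2]
        if (ii < 0).any() or (jj < 0).any():
            raise MapValidationError("negative bin index in coo file")
        n = int(max(ii.max(), jj.max())) + 1 if n_bins is None else int(n_bins)
        if ii.max() >= n or jj.max() >= n:
            raise MapValidationError("coo index exceeds n_bins")
        W = np.zeros((n, n))
        seen: dict[tuple[int, int], float] = {}
        for i, j, v in zip(ii, jj, vv):
            key = (min(i, j), max(i, j))
            if key in seen:
                if seen[key] != v:
                    raise MapValidationError(
                        f"conflicting duplicate coo entries for bins {key}: "
                        f"{seen[key]!r} vs {v!r}"
                    )
                continue
            seen[key] = v
            W[i, j] = v
            W[j, i] = v
        return ContactMap(chrom=chrom, bin_size=bin_size, W=W)
    raise MapFormatError(f"unknown contact-map format {format!r}")


def write_contact_map(cmap: ContactMap, path, format: str = "dense") -> None:
    """Write a contact map losslessly (``%.17g``) as dense or upper-triangle COO."""
    if format == "dense":
        np.savetxt(path, cmap.W, fmt="%.17g")
        return
    if format == "coo":
        iu, ju = np.triu_indices(cmap.n)
        mask = cmap.W[iu, ju] != 0
        with open(path, "w") as fh:
            for i, j in zip(iu[mask], ju[mask]):
                fh.write(f"{i} {j} {cmap.W[i, j]:.17g}\n")
        return
    raise MapFormatError(f"unknown contact-map format {format!r}")


def ice_balance(cmap: ContactMap, tol: float = 1e-6, max_iter: int = 200) -> ContactMap:
    """Iteratively correct a map so every non-empty bin has equal visibility.

    Classic iterative correction: row sums of bins with positive coverage are
    driven to a common value by repeated division by the normalized bias
    vector.  The output is rescaled so ``total_reads`` is preserved; all-zero
    rows remain exactly zero.  On non-convergence a warning is issued and the
    best iterate is returned with ``ice_converged=False``.
    """
    c = cmap.coverage
    nz = c > 0
    if not nz.any():
        raise MapValidationError("cannot balance a map with no positive-coverage bin")
    W = cmap.W.copy()
    converged = False
    for _ in range(max_iter):
        s = W.sum(axis=1)
        m = s[nz].mean()
        dev = np.abs(s[nz] / m - 1.0).max()
        if dev <= tol:
            converged = True
            break
        bias = np.where(nz, s / m, 1.0)
        W /= np.outer(bias, bias)
    if not converged:
        warnings.warn(
            f"ICE balancing did not converge below tol={tol:g} in {max_iter} "
            "iterations; returning best iterate",
            RuntimeWarning,
        )
    total = W.sum() / 2.0
    if total > 0:
        W *= cmap.total_reads / total
    out = ContactMap(chrom=cmap.chrom, bin_size=cmap.bin_size, W=W)
    out.ice_converged = converged
    return out


def write_tads_bed(tads, path) -> None:
    """Write a TAD set as BED3+ (chrom, start, end, domain id), 0-based half-open."""
    bs = tads.bin_size
    with open(path, "w") as fh:
        for k, (s, e) in enumerate(tads.intervals, start=1):
            fh.write(f"{tads.chrom}\t{s * bs}\t{e * bs}\tTAD_{k}\n")


def write_boundary_scores(track, path) -> None:
    """Write internal boundary scores as bedGraph.

    One record per internal border ``k`` (``1 <= k <= n-1``), on the 1-bp
    interval starting at the border coordinate ``k * bin_size``.  Chromosome
    ends (score 1 by construction) are not written.
    """
    if track.chrom is None or track.bin_size is None:
        raise ValueError("track must carry chrom and bin_size to be written")
    n = len(track.scores) - 1
    with open(path, "w") as fh:
        for k in range(1, n):
            coord = k * track.bin_size
            fh.write(f"{track.chrom}\t{coord}\t{coord + 1}\t{track.scores[k]:.6f}\n")


def read_boundary_scores(path) -> np.ndarray:
    """Parse a bedGraph written by :func:`write_boundary_scores`; returns the
    internal scores in border order."""
    scores = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                scores.append(float(parts[3]))
    return np.asarray(scores)
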