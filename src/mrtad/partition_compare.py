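"""Agreement between two TAD partitions via normalized mutual information.

Bin labels of the two partitions are treated as paired categorical
variables ``X`` and ``Y``; the score is

    NMI = 2 I(X; Y) / (H(X) + H(Y))

which is 1 for identical partitions and 0 for independent labelings.
Bins unassigned in *both* partitions are excluded from the comparison;
bins unassigned in exactly one partition are retained, with all of a
partition's unassigned bins forming one extra label class.  Natural
logarithms are used throughout (NMI is base-invariant).
"""

from __future__ import annotations

import numpy as np

from .tad_caller import UNASSIGNED, Partition, TADSet

__all__ = ["normalized_mutual_information", "read_tads_as_partition"]


def _labels(p) -> np.ndarray:
    return np.asarray(getattr(p, "labels", p), dtype=int)


def normalized_mutual_information(p1, p2) -> float:
    """NMI between two bin labelings (Partition objects or label arrays)."""
    x = _labels(p1)
    y = _labels(p2)
    if x.shape != y.shape:
        raise ValueError("partitions cover different numbers of bins")
    keep = ~((x == UNASSIGNED) & (y == UNASSIGNED))
    if not keep.any():
        raise ValueError("no bins are assigned in either partition")
    x = x[keep]
    y = y[keep]
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx = xi.max() + 1
    ky = yi.max() + 1
    cont = np.zeros((kx, ky))
    np.add.at(cont, (xi, yi), 1.0)
    m = cont.sum()
    pxy = cont / m
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nzx = px > 0
    nzy = py > 0
    hx = float(-(px[nzx] * np.log(px[nzx])).sum())
    hy = float(-(py[nzy] * np.log(py[nzy])).sum())
    if hx + hy == 0.0:
        # both labelings constant over the compared bins: identical trivial partitions
        return 1.0
    nz = pxy > 0
    hxy = float(-(pxy[nz] * np.log(pxy[nz])).sum())
    # I = H(X) + H(Y) - H(X,Y); exact (bitwise) for identical partitions,
    # where the joint entropy equals each marginal entropy
    mi = hx + hy - hxy
    return max(0.0, min(1.0, 2.0 * mi / (hx + hy)))


def read_tads_as_partition(bed_path, chrom: str, bin_size: int, n: int) -> Partition:
    """Convert a BED file of TAD intervals back into a bin labeling.

    Bins fully inside an interval receive that interval's label.  A bin
    partially overlapped is assigned by majority coverage — to the
    interval covering at least half of it, ties going to the earlier
    interval — and is otherwise unassigned.  Overlapping intervals raise
    ``ValueError``.
    """
    intervals: list[tuple[int, int]] = []
    with open(bed_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if parts[0] != chrom:
                continue
            intervals.append((int(parts[1]), int(parts[2])))
    intervals.sort()
    for (s1, e1), (s2, e2) in zip(intervals[:-1], intervals[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping intervals ({s1},{e1}) and ({s2},{e2})")
    labels = np.full(n, UNASSIGNED, dtype=int)
    for lab, (start, end) in enumerate(intervals):
        first_bin = start // bin_size
        last_bin = min((end - 1) // bin_size, n - 1)
        for b in range(first_bin, last_bin + 1):
            bin_lo = b * bin_size
            bin_hi = bin_lo + bin_size
            overlap = min(end, bin_hi) - max(start, bin_lo)
            if overlap <= 0:
                continue
            if 2 * overlap >= bin_size and labels[b] == UNASSIGNED:
                # >= keeps an exact half-covered bin with the earlier interval
                labels[b] = lab
    return Partition(labels)


def tads_to_partition(tads: TADSet, n: int) -> Partition:
    """Convenience alias for :meth:`TADSet.to_partition`."""
    return tads.to_partition(n)
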