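"""Sparse symmetric Hi-C contact matrices and distance-dependent summaries.

Counts are stored upper-triangular (i <= j) in CSR form over the global bin
index of a :class:`~hicarch.fragments.FragmentBinMap`.  Analysis operations
that need dense arithmetic densify one chromosome at a time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fragments import FragmentBinMap

PAIRS_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact counts over a bin map.

    ``counts`` holds the upper triangle (including diagonal).  ``mask`` marks
    bins filtered out of downstream analysis.  ``bias`` holds per-bin positive
    correction factors when ``corrected`` is True; the stored counts are then
    already divided by ``bias_i * bias_j``.
    """

    bins: FragmentBinMap
    counts: sp.csr_matrix
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    corrected: bool = False
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin map")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        coo = self.counts.tocoo()
        if np.any(coo.row > coo.col):
            raise ValueError("counts must be stored upper-triangular")

    # -------------------------------------------------------------- basics

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def dense(self, chrom: str | None = None) -> np.ndarray:
        """Dense symmetric matrix, whole genome or one chromosome block."""
        m = self.counts
        if chrom is not None:
            sl = self.bins.chrom_slice(chrom)
            m = m[sl, sl]
        d = np.asarray(m.todense(), dtype=float)
        return d + np.triu(d, 1).T

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.mask[self.bins.chrom_slice(chrom)]

    def with_counts(self, upper: sp.spmatrix, **kw) -> "ContactMatrix":
        out = replace(self, counts=sp.csr_matrix(sp.triu(upper)), **kw)
        out.mask = self.mask.copy()
        return out

    # ----------------------------------------------------------------- I/O

    def write_coo(self, path: str) -> None:
        """Text COO dialect: ``bin_i <TAB> bin_j <TAB> value`` (i <= j)."""
        coo = self.counts.tocoo()
        order = np.lexsort((coo.col, coo.row))
        with open(path, "w") as fh:
            fh.write("#bin_i\tbin_j\tcount\n")
            for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
                fh.write(f"{i}\t{j}\t{float(v)!r}\n")  # repr round-trips exactly

    @classmethod
    def read_coo(cls, path: str, bins: FragmentBinMap) -> "ContactMatrix":
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                i, j, v = line.split("\t")
                rows.append(int(i))
                cols.append(int(j))
                vals.append(float(v))
        n = bins.n_bins
        m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        return cls(bins, sp.csr_matrix(m))

    @classmethod
    def from_dense(cls, bins: FragmentBinMap, dense: np.ndarray,
                   **kw) -> "ContactMatrix":
        """Import shim for standard dense symmetric text matrices."""
        dense = np.asarray(dense, dtype=float)
        if not np.allclose(dense, dense.T):
            raise ValueError("dense matrix must be symmetric")
        return cls(bins, sp.csr_matrix(sp.triu(dense)), **kw)


# ------------------------------------------------------------------ ingest


def iter_pairs(path: str) -> Iterator[tuple[str, int, str, str, int, str]]:
    """Stream a 6-column pairs TSV (chrom1 pos1 strand1 chrom2 pos2 strand2),
    skipping '#' comment lines."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c1, p1, s1, c2, p2, s2 = line.rstrip("\n").split("\t")
            yield c1, int(p1), s1, c2, int(p2), s2


def ingest_pairs(
    pairs: Iterable[tuple[str, int, str, str, int, str]],
    bins: FragmentBinMap,
) -> tuple[ContactMatrix, dict[str, int]]:
    """Bin read pairs into a contact matrix with a QC summary.

    Each pair increments the unordered (bin(pos1), bin(pos2)) cell by one;
    same-bin pairs land on the diagonal.  Pairs on chromosomes absent from
    the bin map are skipped and counted as ``unmapped_pairs``.
    """
    n = bins.n_bins
    qc = {"total_pairs": 0, "intra_pairs": 0, "inter_pairs": 0,
          "same_bin_pairs": 0, "unmapped_pairs": 0}
    rows: list[int] = []
    cols: list[int] = []
    for c1, p1, _s1, c2, p2, _s2 in pairs:
        qc["total_pairs"] += 1
        if c1 not in bins.starts or c2 not in bins.starts:
            qc["unmapped_pairs"] += 1
            continue
        i = bins.bin_index(c1, p1)
        j = bins.bin_index(c2, p2)
        if i > j:
            i, j = j, i
        if c1 == c2:
            qc["intra_pairs"] += 1
            if i == j:
                qc["same_bin_pairs"] += 1
        else:
            qc["inter_pairs"] += 1
        rows.append(i)
        cols.append(j)
    m = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    return ContactMatrix(bins, sp.csr_matrix(m)), qc


def merge_replicates(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Element-wise sum of two replicate matrices on the same bin map."""
    _check_same_bins(a, b)
    return ContactMatrix(a.bins, sp.csr_matrix(a.counts + b.counts))


def downsample(m: ContactMatrix, target_total: int, seed: int) -> ContactMatrix:
    """Down-sample to exactly ``target_total`` contacts without replacement.

    Draws a multivariate hypergeometric sample over the nonzero cells, so
    the result is an exchangeable subset of the original contacts and the
    target is met exactly.  Deterministic for a fixed seed.
    """
    total = int(round(m.total))
    if not 0 <= target_total <= total:
        raise ValueError(f"target {target_total} outside [0, {total}]")
    coo = m.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))  # canonical order for determinism
    colors = coo.data[order].astype(np.int64)
    rng = np.random.default_rng(seed)
    sample = rng.multivariate_hypergeometric(colors, target_total,
                                             method="marginals")
    keep = sample > 0
    out = sp.coo_matrix(
        (sample[keep].astype(float),
         (coo.row[order][keep], coo.col[order][keep])),
        shape=m.counts.shape,
    )
    res = ContactMatrix(m.bins, sp.csr_matrix(out))
    res.mask = m.mask.copy()
    return res


# ------------------------------------------------------- distance summaries


def _midpoints(bins: FragmentBinMap, chrom: str) -> np.ndarray:
    return (bins.starts[chrom] + bins.ends[chrom]) / 2.0


def decay_curve(
    m: ContactMatrix, n_dist_bins: int = 50
) -> pd.DataFrame:
    """Mean contact frequency vs genomic distance, on log-spaced distance
    bins, normalized to sum to one over distance bins.

    Distances are measured between bin midpoints; only intra-chromosomal
    unmasked cells contribute.  The zero-distance diagonal is excluded.
    """
    dists, vals = [], []
    for chrom in m.bins.genome.names:
        sl = m.bins.chrom_slice(chrom)
        sub = m.counts[sl, sl].tocoo()
        mid = _midpoints(m.bins, chrom)
        cmask = m.chrom_mask(chrom)
        ok = (~cmask[sub.row]) & (~cmask[sub.col]) & (sub.row != sub.col)
        dists.append(np.abs(mid[sub.col[ok]] - mid[sub.row[ok]]))
        vals.append(sub.data[ok])
    d = np.concatenate(dists) if dists else np.array([])
    v = np.concatenate(vals) if vals else np.array([])
    if d.size == 0 or v.sum() == 0:
        raise ValueError("no intra-chromosomal contacts")
    edges = np.geomspace(d.min(), d.max() + 1, n_dist_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_dist_bins - 1)
    sums = np.bincount(idx, weights=v, minlength=n_dist_bins)
    ns = np.bincount(idx, minlength=n_dist_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    centers = np.sqrt(edges[:-1] * edges[1:])
    keep = ns > 0
    freq = mean[keep] / np.nansum(mean[keep])
    return pd.DataFrame({"distance": centers[keep], "frequency": freq})


def long_range_fraction(m: ContactMatrix, threshold_bp: float = 1e6) -> float:
    """Fraction of intra-chromosomal contacts spanning more than
    ``threshold_bp`` (midpoint distance)."""
    far = near = 0.0
    for chrom in m.bins.genome.names:
        sl = m.bins.chrom_slice(chrom)
        sub = m.counts[sl, sl].tocoo()
        mid = _midpoints(m.bins, chrom)
        d = np.abs(mid[sub.col] - mid[sub.row])
        far += sub.data[d > threshold_bp].sum()
        near += sub.data[d <= threshold_bp].sum()
    if far + near == 0:
        raise ValueError("no intra-chromosomal contacts")
    return far / (far + near)


def log2_ratio_map(
    a: ContactMatrix, b: ContactMatrix, pseudocount: float | None = None
) -> sp.csr_matrix:
    """log2 of normalized contact frequencies, a over b, cell by cell.

    Each cell is ``log2((a_ij/a.total + psi) / (b_ij/b.total + psi))``.  The
    default pseudocount is one contact in the smaller library.
    """
    _check_same_bins(a, b)
    ta, tb = a.total, b.total
    if ta <= 0 or tb <= 0:
        raise ValueError("both matrices must have contacts")
    psi = pseudocount if pseudocount is not None else 1.0 / min(ta, tb)
    union = ((a.counts != 0) + (b.counts != 0)).tocoo()
    av = np.asarray(a.counts[union.row, union.col]).ravel() / ta
    bv = np.asarray(b.counts[union.row, union.col]).ravel() / tb
    vals = np.log2((av + psi) / (bv + psi))
    return sp.csr_matrix(
        sp.coo_matrix((vals, (union.row, union.col)), shape=a.counts.shape)
    )


def observed_expected(m: ContactMatrix) -> dict[str, np.ndarray]:
    """Observed/expected transform, per chromosome.

    The expected value at distance ``d`` (in bins) is the mean of unmasked
    cells on diagonal ``d`` of that chromosome.  Returns a dense symmetric
    O/E array per chromosome with NaN where undefined (masked rows/columns
    or zero expected).
    """
    out = {}
    for chrom in m.bins.genome.names:
        dense = m.dense(chrom)
        cmask = m.chrom_mask(chrom)
        out[chrom] = oe_dense(dense, cmask)
    return out


def oe_dense(dense: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """O/E of one dense symmetric chromosome block; masked bins become NaN."""
    n = dense.shape[0]
    oe = np.full_like(dense, np.nan, dtype=float)
    valid = ~mask
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = valid[i] & valid[j]
        if not ok.any():
            continue
        vals = dense[i[ok], j[ok]]
        exp = vals.mean()
        if exp > 0:
            oe[i[ok], j[ok]] = vals / exp
            oe[j[ok], i[ok]] = oe[i[ok], j[ok]]
    return oe


def enriched_contacts(
    oe: Mapping[str, np.ndarray],
    m: ContactMatrix,
    z_threshold: float = 2.0,
    n_hist_bins: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells whose log O/E is unusually high for their genomic distance.

    Per chromosome and per diagonal (>= 3 defined cells), log O/E values are
    z-scored; cells with z >= ``z_threshold`` are reported together with a
    log-spaced histogram of anchor (midpoint) distances.
    """
    rows = []
    for chrom, block in oe.items():
        n = block.shape[0]
        off = m.bins.offsets[chrom]
        mid = _midpoints(m.bins, chrom)
        dense = m.dense(chrom)
        for d in range(1, n):
            i = np.arange(n - d)
            j = i + d
            vals = block[i, j]
            ok = np.isfinite(vals) & (vals > 0)
            if ok.sum() < 3:
                continue
            logv = np.log(vals[ok])
            sd = logv.std()
            if sd == 0:
                continue
            z = (logv - logv.mean()) / sd
            hit = z >= z_threshold
            for ii, jj, zz in zip(i[ok][hit], j[ok][hit], z[hit]):
                rows.append({
                    "chrom": chrom,
                    "bin_i": off + ii, "bin_j": off + jj,
                    "observed": dense[ii, jj],
                    "oe": block[ii, jj], "z": zz,
                    "distance": abs(mid[jj] - mid[ii]),
                })
    contacts = pd.DataFrame(
        rows, columns=["chrom", "bin_i", "bin_j", "observed", "oe", "z",
                       "distance"]
    )
    if len(contacts):
        edges = np.geomspace(max(contacts["distance"].min(), 1),
                             contacts["distance"].max() + 1, n_hist_bins + 1)
        counts, _ = np.histogram(contacts["distance"], bins=edges)
        hist = pd.DataFrame({
            "dist_low": edges[:-1], "dist_high": edges[1:], "count": counts,
        })
    else:
        hist = pd.DataFrame(columns=["dist_low", "dist_high", "count"])
    return contacts, hist


def _check_same_bins(a: ContactMatrix, b: ContactMatrix) -> None:
    if a.bins.n_bins != b.bins.n_bins:
        raise ValueError("bin maps differ")
    for chrom in a.bins.genome.names:
        if (chrom not in b.bins.starts
                or not np.array_equal(a.bins.starts[chrom], b.bins.starts[chrom])
                or not np.array_equal(a.bins.ends[chrom], b.bins.ends[chrom])):
            raise ValueError("bin maps differ")
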