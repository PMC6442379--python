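"""Chromatin-loop calling with a donut local-background filter.

A loop is a focal contact enrichment between two distal anchors.  Each
pixel of a balanced fixed-resolution matrix is tested against the mean of
the surrounding donut annulus (Chebyshev radius in (peak_half_width,
donut_half_width], excluding the row/column cross through the pixel).  The
donut expectation, rescaled to raw-count space through the balancing bias,
parameterizes a Poisson upper-tail test; Benjamini-Hochberg controls the
FDR across tested pixels and nearby significant pixels are merged into one
loop (the most enriched pixel represents the cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import scipy.sparse as sp

from .correction import BalanceResult
from .matrix import ContactMatrix
from .tads import Border, TadSet


@dataclass(frozen=True)
class LoopCallParams:
    resolution: int = 2000            # bp per bin
    fdr: float = 0.05
    peak_half_width: int = 5          # bins
    donut_half_width: int = 10        # bins
    merge_distance: int = 20_000      # bp
    min_diagonal_offset: int | None = None  # bins; default peak_half_width+1

    def __post_init__(self) -> None:
        if not self.peak_half_width < self.donut_half_width:
            raise ValueError("peak_half_width must be < donut_half_width")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0,1)")
        if self.min_diagonal_offset is None:
            object.__setattr__(self, "min_diagonal_offset",
                               self.peak_half_width + 1)


def _donut_kernel(peak: int, donut: int) -> np.ndarray:
    size = 2 * donut + 1
    yy, xx = np.mgrid[-donut:donut + 1, -donut:donut + 1]
    cheb = np.maximum(np.abs(yy), np.abs(xx))
    kern = (cheb > peak) & (cheb <= donut)
    kern &= (yy != 0) & (xx != 0)   # exclude the row/column cross
    return kern.astype(float)


def call_loops_donut(
    balanced: BalanceResult,
    raw: ContactMatrix,
    params: LoopCallParams = LoopCallParams(),
) -> pd.DataFrame:
    """Donut-filter loop calling on a balanced matrix.

    Returns a DataFrame (chrom, bin1, bin2, observed, expected, p, q,
    anchor1_start, anchor2_start) of merged significant pixels, sorted by
    q.  Pixels whose donut is entirely masked or zero are skipped.
    """
    m = balanced.matrix
    bias = balanced.bias
    rows_out = []
    kern = _donut_kernel(params.peak_half_width, params.donut_half_width)
    ksum = kern.sum()
    for chrom in m.bins.genome.names:
        dense_bal = m.dense(chrom)
        dense_raw = raw.dense(chrom)
        cmask = m.chrom_mask(chrom)
        sl = m.bins.chrom_slice(chrom)
        cbias = bias[sl]
        n = dense_bal.shape[0]
        if n == 0:
            continue
        ok2d = np.outer(~cmask, ~cmask).astype(float)
        vals = np.where(ok2d > 0, dense_bal, 0.0)
        num = ndimage.convolve(vals, kern, mode="constant", cval=0.0)
        den = ndimage.convolve(ok2d, kern, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            donut_mean = np.where(den >= 0.25 * ksum, num / den, np.nan)
        ii, jj = np.triu_indices(n, k=params.min_diagonal_offset)
        keep = (~cmask[ii]) & (~cmask[jj]) & np.isfinite(donut_mean[ii, jj])
        keep &= donut_mean[ii, jj] > 0
        ii, jj = ii[keep], jj[keep]
        exp_raw = donut_mean[ii, jj] * cbias[ii] * cbias[jj]
        obs_raw = dense_raw[ii, jj]
        p = stats.poisson.sf(obs_raw - 1, exp_raw)
        for i, j, o, e, pv in zip(ii, jj, obs_raw, exp_raw, p):
            rows_out.append((chrom, int(i), int(j), float(o), float(e),
                             float(pv)))
    if not rows_out:
        return _empty_loops()
    df = pd.DataFrame(rows_out, columns=["chrom", "bin1", "bin2",
                                         "observed", "expected", "p"])
    df["q"] = stats.false_discovery_control(df["p"].to_numpy())
    hits = df[df["q"] <= params.fdr].copy()
    if hits.empty:
        return _empty_loops()
    merged = _merge_pixels(hits, params)
    bins = m.bins
    merged["anchor1_start"] = [
        int(bins.starts[c][b]) for c, b in zip(merged["chrom"], merged["bin1"])]
    merged["anchor2_start"] = [
        int(bins.starts[c][b]) for c, b in zip(merged["chrom"], merged["bin2"])]
    return merged.sort_values("q").reset_index(drop=True)


def _empty_loops() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "bin1", "bin2", "observed",
                                 "expected", "p", "q", "anchor1_start",
                                 "anchor2_start"])


def _merge_pixels(hits: pd.DataFrame, params: LoopCallParams) -> pd.DataFrame:
    """Single-linkage clustering of significant pixels within merge_distance
    (Chebyshev, bp); the cluster's most enriched pixel (largest observed /
    expected) is kept."""
    radius = max(1, int(round(params.merge_distance / params.resolution)))
    out = []
    for chrom, sub in hits.groupby("chrom", sort=True):
        coords = sub[["bin1", "bin2"]].to_numpy()
        n = len(sub)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(n):
            for b in range(a + 1, n):
                if (abs(coords[a, 0] - coords[b, 0]) <= radius
                        and abs(coords[a, 1] - coords[b, 1]) <= radius):
                    parent[find(a)] = find(b)
        sub = sub.assign(_cluster=[find(k) for k in range(n)],
                         _enrich=sub["observed"] / sub["expected"])
        best = sub.sort_values("_enrich", ascending=False).groupby(
            "_cluster", sort=False).head(1)
        out.append(best.drop(columns=["_cluster", "_enrich"]))
    return pd.concat(out, ignore_index=True)


# ------------------------------------------------------------ classification


def classify_loops(
    loops: pd.DataFrame,
    tads: TadSet,
    borders: list[Border],
    resolution: int,
    tolerance_bins: int = 1,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Place each loop relative to the TAD map.

    at_border: either anchor within ``tolerance_bins`` bins of a border;
    within_tad: both anchors inside the same domain; otherwise between_tads.
    """
    tol_bp = tolerance_bins * resolution
    border_pos: dict[str, np.ndarray] = {}
    for b in borders:
        border_pos.setdefault(b.chrom, []).append(b.position)  # type: ignore
    border_pos = {c: np.sort(np.asarray(v)) for c, v in border_pos.items()}
    dom = tads.domains
    labels = []
    for _, row in loops.iterrows():
        chrom = row["chrom"]
        a1 = row["anchor1_start"] + resolution / 2
        a2 = row["anchor2_start"] + resolution / 2
        bp = border_pos.get(chrom, np.empty(0))
        near = False
        for a in (a1, a2):
            if len(bp):
                i = np.searchsorted(bp, a)
                cands = bp[max(0, i - 1):i + 1]
                if len(cands) and np.min(np.abs(cands - a)) <= tol_bp:
                    near = True
        if near:
            labels.append("at_border")
            continue
        sub = dom[dom["chrom"] == chrom]
        t1 = sub[(sub["start"] <= a1) & (a1 < sub["end"])].index
        t2 = sub[(sub["start"] <= a2) & (a2 < sub["end"])].index
        if len(t1) and len(t2) and t1[0] == t2[0]:
            labels.append("within_tad")
        else:
            labels.append("between_tads")
    out = loops.copy()
    out["classification"] = labels
    counts = {k: int(v) for k, v in
              pd.Series(labels).value_counts().items()}
    for k in ("at_border", "within_tad", "between_tads"):
        counts.setdefault(k, 0)
    return out, counts


def annotate_loop_anchors(
    loops: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    resolution: int,
) -> dict[str, float]:
    """Fraction of loops with >= 1 anchor overlapping each annotation set.

    Anchor interval = the anchor's bin interval; overlap = >= 1 bp
    intersection.  Annotation frames need columns chrom, start, end.
    """
    from intervaltree import IntervalTree

    out = {}
    for name, ann in annotations.items():
        trees: dict[str, IntervalTree] = {}
        for _, r in ann.iterrows():
            trees.setdefault(r["chrom"], IntervalTree()).addi(
                int(r["start"]), int(r["end"]))
        if loops.empty or ann.empty:
            out[name] = 0.0
            continue
        hit = 0
        for _, row in loops.iterrows():
            tree = trees.get(row["chrom"])
            if tree is None:
                continue
            s1 = int(row["anchor1_start"])
            s2 = int(row["anchor2_start"])
            if tree.overlap(s1, s1 + resolution) or \
                    tree.overlap(s2, s2 + resolution):
                hit += 1
        out[name] = hit / len(loops)
    return out


def write_bedpe(loops: pd.DataFrame, path: str, resolution: int) -> None:
    with open(path, "w") as fh:
        for k, (_, r) in enumerate(loops.iterrows()):
            cls = r.get("classification", ".")
            fh.write(
                f"{r['chrom']}\t{r['anchor1_start']}\t"
                f"{r['anchor1_start'] + resolution}\t{r['chrom']}\t"
                f"{r['anchor2_start']}\t{r['anchor2_start'] + resolution}\t"
                f"loop_{k}\t{r['q']:.3e}\t{cls}\n")
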