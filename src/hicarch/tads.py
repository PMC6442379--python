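"""TAD-separation scores, border calling, grading and cross-cell comparison.

The separation score at a bin edge is the mean, over diamond-shaped
sub-matrices of several window sizes, of per-diagonal z-normalized contact
values crossing that edge.  Local minima of the aggregate score are border
candidates; a candidate is kept if the score dip (delta) relative to its
flanks exceeds a threshold and a rank-sum test of the boundary diamond
against flanking diamonds survives multiple-testing correction.  Borders
are graded strong/weak on delta, and border sets of two cell types are
classified conserved / fuzzy / cell-type-specific by nearest-counterpart
distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix


@dataclass(frozen=True)
class TadCallingParams:
    step: int = 2000                       # bp between evaluation points
    window_sizes: tuple[int, ...] = (10_000, 20_000, 30_000)  # diamond depth, bp
    min_boundary_distance: int = 5000      # bp between kept borders
    p_threshold: float = 0.01
    delta_threshold: float = 0.04
    delta_strong: float = 0.08
    mtc: Literal["fdr", "bonferroni", "none"] = "fdr"
    min_tad_width: int = 5000              # bp
    max_masked_fraction: float = 0.5       # tolerated masked cells per diamond

    def __post_init__(self) -> None:
        if self.delta_strong < self.delta_threshold:
            raise ValueError("delta_strong must be >= delta_threshold")
        if self.min_tad_width <= 0:
            raise ValueError("min_tad_width must be positive")


@dataclass
class SeparationTrack:
    """Aggregate TAD-separation score per evaluation point, per chromosome."""
    chrom: str
    edge_bins: np.ndarray     # bin index k: edge between bins k-1 and k
    positions: np.ndarray     # bp coordinate of each edge
    scores: np.ndarray        # (n_points, n_windows) per-window diamond means
    aggregate: np.ndarray     # mean over windows


@dataclass
class Border:
    chrom: str
    position: int             # bp, bin edge
    edge_bin: int             # local bin index of the edge (bin to the right)
    delta: float
    p_value: float
    q_value: float
    strength: Literal["strong", "weak"] = "weak"


@dataclass
class TadSet:
    """Ordered, non-overlapping domains [start, end) per chromosome."""
    domains: pd.DataFrame     # chrom, start, end


def _z_normalized_diagonals(dense: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace each diagonal by its z-score over unmasked cells; masked
    cells become NaN."""
    n = dense.shape[0]
    z = np.full_like(dense, np.nan, dtype=float)
    valid = ~mask
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        ok = valid[i] & valid[j]
        if ok.sum() < 2:
            continue
        vals = dense[i[ok], j[ok]]
        sd = vals.std()
        zv = (vals - vals.mean()) / sd if sd > 0 else np.zeros(ok.sum())
        z[i[ok], j[ok]] = zv
        z[j[ok], i[ok]] = zv
    return z


def _windows_in_bins(window_sizes: tuple[int, ...], bin_widths: np.ndarray
                     ) -> list[int]:
    med = float(np.median(bin_widths))
    return [max(1, int(round(w / med))) for w in window_sizes]


def _diamond(z: np.ndarray, k: int, w: int) -> np.ndarray:
    """Cells spanning edge k at depth <= w: rows [k-w, k), cols [k, k+w)."""
    return z[k - w:k, k:k + w]


def tad_separation_score(
    m: ContactMatrix, params: TadCallingParams = TadCallingParams()
) -> list[SeparationTrack]:
    """Multi-window diamond insulation score at bin edges.

    Lower aggregate score means stronger insulation.  Evaluation points are
    the bin edges nearest each multiple of ``params.step``; a point is
    defined only where every window's diamond fits inside the chromosome
    and is not mostly masked.  The score is invariant under global scaling
    of the matrix (per-diagonal z-normalization).
    """
    tracks = []
    for chrom in m.bins.genome.names:
        dense = m.dense(chrom)
        cmask = m.chrom_mask(chrom)
        n = dense.shape[0]
        widths = m.bins.ends[chrom] - m.bins.starts[chrom]
        wbins = _windows_in_bins(params.window_sizes, widths)
        wmax = max(wbins)
        if n < 2 * wmax:
            tracks.append(SeparationTrack(
                chrom, np.empty(0, int), np.empty(0, int),
                np.empty((0, len(wbins))), np.empty(0)))
            continue
        z = _z_normalized_diagonals(dense, cmask)
        edges = m.bins.edge_positions(chrom)           # bp of edge k = 1..n-1
        ks = _evaluation_edges(edges, params.step)
        rows, kept_k = [], []
        for k in ks:
            if k < wmax or k > n - wmax:
                continue
            per_w = []
            for w in wbins:
                cells = _diamond(z, k, w)
                if np.isnan(cells).mean() > params.max_masked_fraction:
                    per_w.append(np.nan)
                else:
                    per_w.append(np.nanmean(cells))
            if np.isnan(per_w).any():
                continue
            rows.append(per_w)
            kept_k.append(k)
        kept_k = np.asarray(kept_k, dtype=int)
        scores = np.asarray(rows, dtype=float).reshape(len(kept_k), len(wbins))
        tracks.append(SeparationTrack(
            chrom, kept_k, edges[kept_k - 1] if len(kept_k) else kept_k,
            scores, scores.mean(axis=1) if len(kept_k) else np.empty(0)))
    return tracks


def _evaluation_edges(edges: np.ndarray, step: int) -> np.ndarray:
    """Bin-edge indices (1-based: edge k sits left of bin k) nearest each
    multiple of ``step``; every edge when edges are coarser than step."""
    if len(edges) == 0:
        return np.empty(0, dtype=int)
    if np.median(np.diff(edges)) >= step if len(edges) > 1 else True:
        return np.arange(1, len(edges) + 1)
    grid = np.arange(step, edges[-1] + 1, step)
    idx = np.abs(edges[None, :] - grid[:, None]).argmin(axis=1)
    return np.unique(idx) + 1


def call_borders(
    tracks: list[SeparationTrack],
    m: ContactMatrix,
    params: TadCallingParams = TadCallingParams(),
) -> tuple[list[Border], TadSet]:
    """Call borders at significant local minima of the separation track.

    delta is the mean aggregate score over the flanking neighbourhood
    (within ``min_boundary_distance`` bp, excluding the minimum itself)
    minus the score at the minimum.  The p-value is a one-sided rank-sum
    test of the boundary diamond's z-values against pooled flanking
    diamonds; q-values follow ``params.mtc``.  Kept borders respect the
    minimum spacing (larger delta wins; ties keep the leftmost).  Domains
    narrower than ``min_tad_width`` are dissolved by dropping their weaker
    bounding border.
    """
    candidates: list[Border] = []
    diamonds: list[tuple[np.ndarray, np.ndarray]] = []
    for track in tracks:
        if len(track.aggregate) == 0:
            continue
        dense = m.dense(track.chrom)
        cmask = m.chrom_mask(track.chrom)
        z = _z_normalized_diagonals(dense, cmask)
        widths = m.bins.ends[track.chrom] - m.bins.starts[track.chrom]
        wmax = max(_windows_in_bins(params.window_sizes, widths))
        agg = track.aggregate
        pos = track.positions
        med_width = float(np.median(widths))
        min_radius = max(params.min_boundary_distance, wmax * med_width)
        for idx in _windowed_minima(agg, pos, min_radius):
            near = np.abs(pos - pos[idx]) <= params.min_boundary_distance
            near[idx] = False
            if not near.any():
                continue
            delta = float(agg[near].mean() - agg[idx])
            if delta < params.delta_threshold:
                continue
            k = int(track.edge_bins[idx])
            n_bins_c = z.shape[0]
            boundary = _diamond(z, k, wmax).ravel()
            # intra-domain flanks: diamonds a full window away on each side,
            # disjoint from the boundary diamond
            flank_parts = []
            for fk in (k - wmax, k + wmax):
                if wmax <= fk <= n_bins_c - wmax:
                    flank_parts.append(_diamond(z, fk, wmax).ravel())
            if not flank_parts:
                continue
            flank = np.concatenate(flank_parts)
            boundary = boundary[np.isfinite(boundary)]
            flank = flank[np.isfinite(flank)]
            if len(boundary) == 0 or len(flank) == 0:
                continue
            p = stats.mannwhitneyu(boundary, flank,
                                   alternative="less").pvalue
            candidates.append(Border(track.chrom, int(pos[idx]), k,
                                     delta, float(p), float(p)))
    if not candidates:
        return [], TadSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    pvals = np.array([b.p_value for b in candidates])
    if params.mtc == "fdr":
        qvals = stats.false_discovery_control(pvals)
    elif params.mtc == "bonferroni":
        qvals = np.minimum(pvals * len(pvals), 1.0)
    else:
        qvals = pvals
    kept = [replace(b, q_value=float(q))
            for b, q in zip(candidates, qvals) if q <= params.p_threshold]
    kept = _prune_min_distance(kept, params.min_boundary_distance)
    kept, tads = _build_domains(kept, m, params)
    return kept, tads


def _windowed_minima(a: np.ndarray, pos: np.ndarray,
                     radius_bp: float) -> list[int]:
    """Interior indices that are the minimum of ``a`` within ``radius_bp``
    on both sides (ties keep the leftmost).

    The neighbourhood radius is at least the diamond window: a dip
    narrower than the measuring window cannot be resolved as a separate
    border, so jagged secondary minima on the slope of a genuine
    boundary's valley are not candidates.
    """
    out = []
    n = len(a)
    for i in range(1, n - 1):
        near = np.abs(pos - pos[i]) <= radius_bp
        vals = a[near]
        if a[i] > vals.min():
            continue
        ties = np.flatnonzero(near & (a == a[i]))
        if ties[0] == i:
            out.append(i)
    return out


def _prune_min_distance(borders: list[Border], min_dist: int) -> list[Border]:
    """Greedy: repeatedly keep the best border (largest delta, ties leftmost)
    and drop others of the same chromosome within min_dist."""
    kept: list[Border] = []
    pool = sorted(borders, key=lambda b: (-b.delta, b.chrom, b.position))
    for b in pool:
        if all(k.chrom != b.chrom or abs(k.position - b.position) >= min_dist
               for k in kept):
            kept.append(b)
    return sorted(kept, key=lambda b: (b.chrom, b.position))


def _build_domains(borders: list[Border], m: ContactMatrix,
                   params: TadCallingParams) -> tuple[list[Border], TadSet]:
    by_chrom: dict[str, list[Border]] = {}
    for b in borders:
        by_chrom.setdefault(b.chrom, []).append(b)
    final: list[Border] = []
    rows = []
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.position)
        length = m.bins.genome.lengths[chrom]
        # dissolve domains narrower than min_tad_width (chromosome ends are
        # immovable: an end-adjacent narrow stub drops its single border)
        changed = True
        while changed and bs:
            changed = False
            edges = [0] + [b.position for b in bs] + [length]
            for i in range(len(edges) - 1):
                if edges[i + 1] - edges[i] < params.min_tad_width:
                    left = bs[i - 1] if i > 0 else None
                    right = bs[i] if i < len(bs) else None
                    if left is None:
                        victim = right
                    elif right is None:
                        victim = left
                    else:
                        victim = left if left.delta <= right.delta else right
                    bs.remove(victim)  # type: ignore[arg-type]
                    changed = True
                    break
        final.extend(bs)
        edges = [0] + [b.position for b in bs] + [length]
        for a, b_ in zip(edges[:-1], edges[1:]):
            rows.append({"chrom": chrom, "start": a, "end": b_})
    tads = TadSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return sorted(final, key=lambda b: (b.chrom, b.position)), tads


def grade_borders(borders: list[Border], delta_strong: float = 0.08
                  ) -> list[Border]:
    """Label each border strong (delta >= delta_strong) or weak."""
    return [replace(b, strength="strong" if b.delta >= delta_strong
                    else "weak") for b in borders]


# ------------------------------------------------- cross-cell classification


def classify_borders(
    borders_a: list[Border],
    borders_b: list[Border],
    fuzzy_radius: int = 2000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conservation taxonomy of two border sets.

    Per border the distance d to the nearest counterpart border on the same
    chromosome decides the label: d == 0 conserved (matched one-to-one),
    0 < d < fuzzy_radius fuzzy, d >= fuzzy_radius cell-type-specific.
    Returns one DataFrame per input set with columns chrom, position, delta,
    strength, label, distance.
    """
    df_a = _classify_one(borders_a, borders_b, "specific_A", fuzzy_radius)
    df_b = _classify_one(borders_b, borders_a, "specific_B", fuzzy_radius)
    return df_a, df_b


def _classify_one(mine: list[Border], other: list[Border],
                  specific_label: str, fuzzy_radius: int) -> pd.DataFrame:
    other_pos: dict[str, np.ndarray] = {}
    for b in other:
        other_pos.setdefault(b.chrom, [])
    for b in other:
        other_pos[b.chrom].append(b.position)  # type: ignore[union-attr]
    other_pos = {c: np.sort(np.asarray(v)) for c, v in other_pos.items()}
    rows = []
    for b in sorted(mine, key=lambda x: (x.chrom, x.position)):
        arr = other_pos.get(b.chrom)
        if arr is None or len(arr) == 0:
            d = np.inf
        else:
            i = np.searchsorted(arr, b.position)
            cands = arr[max(0, i - 1):i + 1]
            d = float(np.min(np.abs(cands - b.position)))
        if d == 0:
            label = "conserved"
        elif d < fuzzy_radius:
            label = "fuzzy"
        else:
            label = specific_label
        rows.append({"chrom": b.chrom, "position": b.position,
                     "delta": b.delta, "strength": b.strength,
                     "label": label, "distance": d})
    return pd.DataFrame(rows, columns=["chrom", "position", "delta",
                                       "strength", "label", "distance"])


def border_distance_distribution(
    borders_a: list[Border], borders_b: list[Border], n_bins: int = 20
) -> dict:
    """Nearest-counterpart distances of A's borders, with the zero-distance
    (identical restriction site) fraction reported separately."""
    if not borders_a or not borders_b:
        raise ValueError("both border sets must be non-empty")
    df, _ = classify_borders(borders_a, borders_b)
    d = df["distance"].to_numpy()
    finite = d[np.isfinite(d)]
    zero_frac = float((d == 0).mean())
    nz = finite[finite > 0]
    if len(nz):
        edges = np.geomspace(nz.min(), nz.max() + 1, n_bins + 1)
        counts, _ = np.histogram(nz, bins=edges)
    else:
        edges, counts = np.array([0.0, 1.0]), np.array([0])
    return {"distances": d, "zero_fraction": zero_frac,
            "hist_edges": edges, "hist_counts": counts}
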