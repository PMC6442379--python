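"""Interval annotations at TAD borders and the associated proportion tests.

Enhancers mapped in two cell types are split into cell-specific and common
sets by mutual overlap; borders are tested for overlap with enhancers,
genomic regulatory blocks (GRBs) and other interval sets within a window;
and differences in overlap proportions between border classes are assessed
with Fisher's exact test and a label-permutation randomization test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


def load_bed(path: str, name: str = "") -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            rows.append({"chrom": parts[0], "start": int(parts[1]),
                         "end": int(parts[2])})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.attrs["name"] = name
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\n")


def _build_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for _, r in df.iterrows():
        trees.setdefault(r["chrom"], IntervalTree()).addi(
            int(r["start"]), int(r["end"]))
    return trees


def classify_enhancers(
    set_a: pd.DataFrame, set_b: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Split two enhancer catalogues into specific and common sets.

    An interval is common iff it overlaps (>= 1 bp) any interval of the
    other set, else specific to its own set.  Returns the three interval
    sets (common = union of mutually overlapping intervals from both
    catalogues) and Venn-style counts per catalogue.
    """
    trees_a, trees_b = _build_trees(set_a), _build_trees(set_b)

    def split(df: pd.DataFrame, other: dict[str, IntervalTree]
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
        is_common = []
        for _, r in df.iterrows():
            tree = other.get(r["chrom"])
            is_common.append(bool(tree and tree.overlap(r["start"], r["end"])))
        flag = np.asarray(is_common, dtype=bool) if is_common else \
            np.empty(0, dtype=bool)
        return df[~flag].reset_index(drop=True), df[flag].reset_index(drop=True)

    spec_a, common_a = split(set_a, trees_b)
    spec_b, common_b = split(set_b, trees_a)
    common = pd.concat([common_a, common_b], ignore_index=True)
    sets = {"specific_A": spec_a, "specific_B": spec_b, "common": common}
    counts = {"specific_A": len(spec_a), "specific_B": len(spec_b),
              "common_A": len(common_a), "common_B": len(common_b)}
    return sets, counts


def border_overlap(
    borders: pd.DataFrame, intervals: pd.DataFrame, window: int = 1000
) -> pd.DataFrame:
    """Per border class: how many borders fall within ``window`` bp of an
    interval.

    A border at position p overlaps iff [p - window, p + window) intersects
    an interval (half-open on both sides).  ``borders`` needs chrom,
    position, label columns.
    """
    trees = _build_trees(intervals)
    flags = []
    for _, r in borders.iterrows():
        tree = trees.get(r["chrom"])
        pos = int(r["position"])
        # window 0 degrades to the point query [pos, pos+1)
        lo, hi = pos - window, max(pos + window, pos + 1)
        flags.append(bool(tree and tree.overlap(lo, hi)))
    tmp = borders.assign(overlaps=flags)
    rep = (tmp.groupby("label")
           .agg(n_borders=("overlaps", "size"),
                n_overlapping=("overlaps", "sum"))
           .reset_index())
    rep["fraction"] = rep["n_overlapping"] / rep["n_borders"]
    return rep


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed the observed one
    (relative tolerance 1e-7 for ties).  A zero margin gives p = 1 by
    convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def permutation_two_proportions(
    table: Sequence[Sequence[int]], n_perm: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Randomization test for equality of two proportions.

    Rows of the 2x2 table are the groups; the statistic is the absolute
    difference of group success proportions.  Group labels are permuted
    (equivalently, successes redistributed hypergeometrically) ``n_perm``
    times; p uses the add-one estimator (1 + #{perm >= obs})/(n_perm + 1).
    Returns (p, Monte-Carlo standard error).
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    s = a + c
    if n1 == 0 or n2 == 0 or s == 0 or s == n1 + n2:
        return 1.0, 0.0
    obs = abs(a / n1 - c / n2)
    rng = np.random.default_rng(seed)
    perm_a = rng.hypergeometric(s, n1 + n2 - s, n1, size=n_perm)
    perm_stat = np.abs(perm_a / n1 - (s - perm_a) / n2)
    exceed = int((perm_stat >= obs - 1e-12).sum())
    p = (1 + exceed) / (n_perm + 1)
    se = float(np.sqrt(p * (1 - p) / n_perm))
    return float(p), se


def overlap_test_table(
    borders: pd.DataFrame,
    intervals: pd.DataFrame,
    class_a: str,
    class_b: str,
    window: int = 1000,
) -> list[list[int]]:
    """2x2 table (overlap yes/no by border class) feeding the Fisher and
    permutation tests."""
    rep = border_overlap(borders, intervals, window).set_index("label")
    out = []
    for cls in (class_a, class_b):
        if cls in rep.index:
            k = int(rep.loc[cls, "n_overlapping"])
            n = int(rep.loc[cls, "n_borders"])
        else:
            k = n = 0
        out.append([k, n - k])
    return out
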