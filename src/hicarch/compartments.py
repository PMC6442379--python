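"""A/B compartment calling from the contact correlation eigenvector.

Per chromosome the corrected matrix is O/E-transformed, turned into a
Pearson correlation matrix over unmasked bins, and its leading eigenvector
extracted.  The eigenvector's sign is arbitrary, so it is oriented by its
correlation with GC content (active A compartment is GC-richer); positive
entries are labeled A, negative B, and masked/undefined bins N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, oe_dense
from .tads import Border


@dataclass
class CompartmentTrack:
    """Per-bin eigenvector value and A/B/N label on the matrix's bin grid."""
    values: np.ndarray          # NaN on N bins
    labels: np.ndarray          # '<U1' array of 'A' / 'B' / 'N'


def compartment_eigenvector(
    m: ContactMatrix, gc: np.ndarray, min_bins: int = 10
) -> CompartmentTrack:
    """Leading eigenvector of the per-chromosome O/E Pearson matrix,
    sign-flipped to correlate positively with GC.

    Bins masked in the matrix or missing GC become N.  A chromosome with
    fewer than ``min_bins`` usable bins is entirely N.
    """
    if len(gc) != m.n_bins:
        raise ValueError("GC track length does not match bin count")
    values = np.full(m.n_bins, np.nan)
    for chrom in m.bins.genome.names:
        sl = m.bins.chrom_slice(chrom)
        cmask = m.chrom_mask(chrom) | ~np.isfinite(gc[sl])
        usable = ~cmask
        if usable.sum() < min_bins:
            continue
        oe = oe_dense(m.dense(chrom), cmask)
        sub = oe[np.ix_(usable, usable)]
        sub = np.nan_to_num(sub, nan=1.0)   # isolated undefined cells -> neutral
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        w, v = np.linalg.eigh(corr)
        ev = v[:, -1]                        # largest eigenvalue
        cg = gc[sl][usable]
        r = np.corrcoef(ev, cg)[0, 1]
        if np.isfinite(r) and r < 0:
            ev = -ev
        out = np.full(usable.shape, np.nan)
        out[usable] = ev
        values[sl] = out
    labels = np.where(np.isnan(values), "N",
                      np.where(values > 0, "A", "B")).astype("<U1")
    labels[values == 0] = "N"
    return CompartmentTrack(values, labels)


def compartment_switching(a: CompartmentTrack, b: CompartmentTrack) -> dict:
    """Transition fractions between two compartment tracks on one bin grid.

    Fractions (AA, AB, BA, BB) are over bins classified A or B in both
    tracks; the fraction of bins involving N is reported separately.
    """
    if len(a.labels) != len(b.labels):
        raise ValueError("compartment tracks on different bin grids")
    la, lb = a.labels, b.labels
    both = (la != "N") & (lb != "N")
    n_both = int(both.sum())
    out = {"n_classified": n_both,
           "n_involving_N": int(len(la) - n_both)}
    for x in "AB":
        for y in "AB":
            key = f"{x}_to_{y}"
            if n_both:
                out[key] = float(((la == x) & (lb == y) & both).sum() / n_both)
            else:
                out[key] = 0.0
    return out


def borders_in_compartments(
    borders_df: pd.DataFrame, track: CompartmentTrack, m: ContactMatrix
) -> pd.DataFrame:
    """Count borders per (border class, compartment label).

    Each border takes the label of the bin containing its position
    (half-open convention).  ``borders_df`` needs chrom, position, label
    columns (the output of the border classifier).
    """
    rows = []
    for _, r in borders_df.iterrows():
        pos = int(r["position"])
        chrom = r["chrom"]
        length = m.bins.genome.lengths[chrom]
        idx = m.bins.bin_index(chrom, min(pos, length - 1))
        rows.append({"border_class": r["label"],
                     "compartment": track.labels[idx]})
    df = pd.DataFrame(rows, columns=["border_class", "compartment"])
    return (df.groupby(["border_class", "compartment"], sort=True)
            .size().rename("count").reset_index())


def write_compartments(track: CompartmentTrack, m: ContactMatrix,
                       bedgraph_path: str, bed_path: str) -> None:
    """Eigenvector as bedGraph and labels as BED over the matrix's bins."""
    bins = m.bins
    with open(bedgraph_path, "w") as fg, open(bed_path, "w") as fb:
        for chrom in bins.genome.names:
            sl = bins.chrom_slice(chrom)
            for s, e, v, lab in zip(bins.starts[chrom], bins.ends[chrom],
                                    track.values[sl], track.labels[sl]):
                if np.isfinite(v):
                    fg.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
                fb.write(f"{chrom}\t{s}\t{e}\t{lab}\n")
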