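"""Paired synthetic "cell-type" Hi-C datasets with planted ground truth.

The generator plants, on a single synthetic chromosome, every structure
the analysis pipeline is designed to recover: a power-law distance decay
with within-TAD enrichment, two cell types sharing a subset of TAD borders
at identical coordinates (plus optionally fuzzy-shifted and cell-specific
borders), a GC-correlated checkerboard compartment signal, focal loop
pixels, multiplicative per-bin bias, strand-specific transcription tracks
with divergent peaks at borders, and border-linked enhancer/GRB
annotations.  Counts are Poisson; everything is deterministic under a
fixed seed.

Cell intensity model (bin pair i, j at distance d bins, bin width w):

    mu_ij = Z * b_i * b_j * (d*w + s0)^(-alpha) * tau^[same TAD]
            * (1 + c * e_i * e_j) * lambda_loop^[loop footprint]

with Z chosen so the expected total (upper triangle incl. diagonal)
equals ``total_contacts``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fragments import FragmentBinMap, GenomeModel, fixed_width_bins
from .matrix import ContactMatrix
from .signal_tracks import StrandTrackPair


@dataclass(frozen=True)
class SimulationParams:
    """Standard simulation: 500 bins of 2 kb (a 1-Mb chromosome), one
    million contacts, within-TAD enrichment 2.5, checkerboard strength 0.3,
    six-fold loop enrichment, log-normal bias with sigma 0.25."""

    n_bins: int = 500
    bin_width: int = 2000
    alpha: float = 1.0              # decay exponent
    s0: float = 1000.0              # decay offset, bp
    tau: float = 2.5                # within-TAD enrichment
    comp_strength: float = 0.3      # checkerboard strength c
    loop_enrichment: float = 6.0
    bias_sigma: float = 0.25        # log-normal per-bin bias SD
    total_contacts: int = 1_000_000
    n_conserved: int = 4
    n_fuzzy: int = 0                # needs bin_width < 2000 to be feasible
    n_specific_a: int = 3
    n_specific_b: int = 3
    min_border_spacing_bins: int = 40
    n_loops: int = 8
    comp_block_mean_bins: int = 50  # geometric block length
    comp_switch_fraction: float = 0.1
    divergent_fraction: float = 0.75
    strand_rate_ratio: float = 1.0  # plus:minus rate at divergent borders
    signal_rate: float = 20.0       # expected transcription per bp in peaks
    background_rate: float = 0.02   # expected background per bp
    transcription_noise: bool = True
    enhancer_width: int = 400
    grb_width: int = 5000
    p_enhancer: dict = field(default_factory=lambda: {
        "conserved": 0.2, "fuzzy": 0.2, "specific_A": 0.6, "specific_B": 0.2})
    p_grb: dict = field(default_factory=lambda: {
        "conserved": 0.2, "fuzzy": 0.2, "specific_A": 0.5, "specific_B": 0.2})
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.tau < 1 or self.loop_enrichment < 1:
            raise ValueError("require alpha > 0, tau >= 1, loop_enrichment >= 1")
        if not 0 <= self.comp_strength < 1:
            raise ValueError("compartment strength must be in [0, 1)")
        if self.total_contacts <= 0:
            raise ValueError("total_contacts must be positive")
        if self.n_fuzzy > 0 and self.bin_width >= 2000:
            raise ValueError("fuzzy borders need bin_width < 2000 "
                             "(offsets are < 2 kb, snapped to bin edges)")


@dataclass
class SyntheticTruth:
    """Planted structure; positions are bp on a single chromosome."""

    params: SimulationParams
    bins: FragmentBinMap
    borders_a: np.ndarray          # bp, sorted
    borders_b: np.ndarray
    labels_a: list[str]            # conserved / fuzzy / specific_A per border
    labels_b: list[str]
    loops: np.ndarray              # (n_loops, 2) bin indices, i < j
    comp_a: np.ndarray             # per-bin sign in {-1, +1}
    comp_b: np.ndarray
    bias_a: np.ndarray             # per-bin positive, unit geometric mean
    bias_b: np.ndarray
    gc: np.ndarray                 # per-bin GC fraction
    divergent_a: np.ndarray        # bool per border of cell A
    divergent_b: np.ndarray

    def tads(self, cell: str) -> np.ndarray:
        borders = self.borders_a if cell == "A" else self.borders_b
        length = self.params.n_bins * self.params.bin_width
        edges = np.concatenate(([0], borders, [length]))
        return np.column_stack([edges[:-1], edges[1:]])

    def same_tad_matrix(self, cell: str) -> np.ndarray:
        """Boolean (n_bins, n_bins): both bins inside the same TAD."""
        p = self.params
        borders = self.borders_a if cell == "A" else self.borders_b
        edges = np.concatenate(([0], borders,
                                [p.n_bins * p.bin_width]))
        starts = np.arange(p.n_bins) * p.bin_width
        dom = np.searchsorted(edges, starts, side="right") - 1
        return dom[:, None] == dom[None, :]

    # ---------------------------------------------------------------- I/O

    def to_json(self, path: str) -> None:
        payload = {
            "params": {k: v for k, v in asdict(self.params).items()},
            "borders_a": self.borders_a.tolist(),
            "borders_b": self.borders_b.tolist(),
            "labels_a": self.labels_a,
            "labels_b": self.labels_b,
            "loops": self.loops.tolist(),
            "comp_a": self.comp_a.tolist(),
            "comp_b": self.comp_b.tolist(),
            "bias_a": self.bias_a.tolist(),
            "bias_b": self.bias_b.tolist(),
            "gc": self.gc.tolist(),
            "divergent_a": self.divergent_a.tolist(),
            "divergent_b": self.divergent_b.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        params = SimulationParams(**payload["params"])
        truth = generate_truth(params)  # rebuild bins/genome
        return cls(
            params, truth.bins,
            np.asarray(payload["borders_a"]), np.asarray(payload["borders_b"]),
            payload["labels_a"], payload["labels_b"],
            np.asarray(payload["loops"]).reshape(-1, 2),
            np.asarray(payload["comp_a"]), np.asarray(payload["comp_b"]),
            np.asarray(payload["bias_a"]), np.asarray(payload["bias_b"]),
            np.asarray(payload["gc"]),
            np.asarray(payload["divergent_a"], dtype=bool),
            np.asarray(payload["divergent_b"], dtype=bool),
        )


# ----------------------------------------------------------------- truth


def _place_border_edges(rng: np.random.Generator, n_sites: int,
                        n_bins: int, spacing: int) -> np.ndarray:
    """Distinct interior bin edges with pairwise spacing >= ``spacing`` bins
    (and at least ``spacing`` from both chromosome ends)."""
    if n_sites == 0:
        return np.empty(0, dtype=int)
    usable = n_bins - (n_sites + 1) * spacing
    if usable < 0:
        raise ValueError("infeasible border spacing for this chromosome size")
    # stars-and-bars: distribute slack among the n_sites+1 gaps
    slack = rng.multinomial(usable, np.ones(n_sites + 1) / (n_sites + 1))
    edges = np.cumsum(slack[:-1] + spacing)
    return edges


def generate_truth(params: SimulationParams) -> SyntheticTruth:
    """Plant borders, loops, compartments, bias, GC and divergent subsets."""
    p = params
    rng = np.random.default_rng(p.seed)
    genome = GenomeModel.from_dict({p.chrom: p.n_bins * p.bin_width})
    bins = fixed_width_bins(genome, p.bin_width)

    # --- borders: one pool of distinct, well-spaced sites, then classes
    n_sites = p.n_conserved + p.n_fuzzy + p.n_specific_a + p.n_specific_b
    edges = _place_border_edges(rng, n_sites, p.n_bins,
                                p.min_border_spacing_bins)
    order = rng.permutation(n_sites)
    classes = (["conserved"] * p.n_conserved + ["fuzzy"] * p.n_fuzzy
               + ["specific_A"] * p.n_specific_a
               + ["specific_B"] * p.n_specific_b)
    site_class = dict(zip(edges[order].tolist(), classes))

    borders_a, labels_a, borders_b, labels_b = [], [], [], []
    for edge in sorted(site_class):
        cls = site_class[edge]
        pos = edge * p.bin_width
        if cls == "conserved":
            borders_a.append(pos), labels_a.append(cls)
            borders_b.append(pos), labels_b.append(cls)
        elif cls == "fuzzy":
            max_off = (2000 - 1) // p.bin_width
            off = int(rng.integers(1, max_off + 1)) * p.bin_width
            off *= int(rng.choice([-1, 1]))
            borders_a.append(pos), labels_a.append(cls)
            borders_b.append(pos + off), labels_b.append(cls)
        elif cls == "specific_A":
            borders_a.append(pos), labels_a.append(cls)
        else:
            borders_b.append(pos), labels_b.append(cls)
    oa = np.argsort(borders_a)
    ob = np.argsort(borders_b)
    borders_a = np.asarray(borders_a)[oa]
    labels_a = [labels_a[i] for i in oa]
    borders_b = np.asarray(borders_b)[ob]
    labels_b = [labels_b[i] for i in ob]

    # --- compartments: blocks whose boundaries sit on planted border sites.
    # A compartment transition is itself an insulation boundary, so letting
    # transitions fall between planted borders would plant unlabeled
    # borders; real compartment switches align with domain boundaries.
    comp_a = np.empty(p.n_bins, dtype=int)
    sign = 1 if rng.random() < 0.5 else -1
    conserved_edges = sorted(
        int(pos) // p.bin_width
        for pos, cls in zip(borders_a, labels_a) if cls == "conserved")
    grid = [0] + conserved_edges + [p.n_bins]
    blocks = list(zip(grid[:-1], grid[1:]))
    for lo, hi in blocks:
        comp_a[lo:hi] = sign
        # flip between blocks often enough to give a checkerboard whose
        # blocks average a few conserved domains (~comp_block_mean_bins)
        if rng.random() < min(1.0, (hi - lo) / p.comp_block_mean_bins):
            sign = -sign
    comp_b = comp_a.copy()
    n_switch = int(round(p.comp_switch_fraction * p.n_bins))
    # cell B switches whole conserved-bounded blocks, so its transitions are
    # also conserved borders; stop once the requested bin fraction flipped
    switched = 0
    for bi in rng.permutation(len(blocks)):
        lo, hi = blocks[bi]
        if switched >= n_switch or switched + (hi - lo) > 2 * n_switch:
            continue
        comp_b[lo:hi] *= -1
        switched += hi - lo

    gc = 0.42 + 0.04 * comp_a + rng.normal(0, 0.005, p.n_bins)
    gc = np.clip(gc, 0.0, 1.0)

    # --- biases, per cell type, unit geometric mean
    def bias() -> np.ndarray:
        b = np.exp(rng.normal(0.0, p.bias_sigma, p.n_bins))
        return b / np.exp(np.mean(np.log(b)))

    bias_a, bias_b = bias(), bias()

    # --- loops: pixels with both anchors inside the same domain in both
    # cell types (segments between consecutive union-border edges), at
    # anchor offsets of 20-60 bins (40-120 kb at standard width) where the
    # standard depth supports focal detection; mutually well separated
    union_edges = sorted(set(
        [0, p.n_bins]
        + [int(b) // p.bin_width for b in borders_a]
        + [int(b) // p.bin_width for b in borders_b]))
    segments = [(lo, hi) for lo, hi in zip(union_edges[:-1], union_edges[1:])
                if hi - lo >= 24]
    loops = []
    attempts = 0
    while len(loops) < p.n_loops and attempts < 10_000 and segments:
        attempts += 1
        lo, hi = segments[int(rng.integers(len(segments)))]
        d = int(rng.integers(20, min(60, hi - lo - 2) + 1))
        i = int(rng.integers(lo + 1, hi - d))
        j = i + d
        if all(max(abs(i - x), abs(j - y)) > 12 for x, y in loops):
            loops.append((i, j))
    loops_arr = np.asarray(sorted(loops), dtype=int).reshape(-1, 2)

    divergent_a = rng.random(len(borders_a)) < p.divergent_fraction
    divergent_b = rng.random(len(borders_b)) < p.divergent_fraction

    return SyntheticTruth(p, bins, borders_a, borders_b, labels_a, labels_b,
                          loops_arr, comp_a, comp_b, bias_a, bias_b, gc,
                          divergent_a, divergent_b)


# ------------------------------------------------------------------- Hi-C


def expected_intensity(truth: SyntheticTruth, cell: str = "A") -> np.ndarray:
    """Dense symmetric expected-count matrix mu (upper-triangle total equals
    ``total_contacts``)."""
    p = truth.params
    n = p.n_bins
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    dist = d * p.bin_width + p.s0
    # overflow guard: same-bin contacts act at half a bin width when s0 = 0
    dist = np.where(dist <= 0, p.bin_width / 2, dist)
    mu = dist ** (-p.alpha)
    mu = mu * np.where(truth.same_tad_matrix(cell), p.tau, 1.0)
    comp = truth.comp_a if cell == "A" else truth.comp_b
    mu = mu * (1.0 + p.comp_strength * np.outer(comp, comp))
    for i, j in truth.loops:
        mu[i, j] *= p.loop_enrichment
        mu[j, i] *= p.loop_enrichment
    b = truth.bias_a if cell == "A" else truth.bias_b
    mu = mu * np.outer(b, b)
    upper_sum = np.triu(mu).sum()
    return mu * (p.total_contacts / upper_sum)


def simulate_hic(truth: SyntheticTruth, cell: str = "A",
                 seed: int | None = None) -> ContactMatrix:
    """Poisson-sample a contact matrix from the planted intensity model."""
    p = truth.params
    rng = np.random.default_rng(p.seed + 1 if seed is None else seed)
    mu = expected_intensity(truth, cell)
    upper = np.triu(rng.poisson(mu).astype(float))
    return ContactMatrix(truth.bins, sp.csr_matrix(upper))


def emit_pairs(m: ContactMatrix, path: str, seed: int = 0) -> None:
    """Expand a contact matrix into a pairs TSV (uniform positions within
    bins, random strands); ingesting the file reproduces the matrix."""
    rng = np.random.default_rng(seed)
    bins = m.bins
    starts = np.concatenate([bins.starts[c] for c in bins.genome.names])
    ends = np.concatenate([bins.ends[c] for c in bins.genome.names])
    chrom_of = np.concatenate([
        np.full(len(bins.starts[c]), c, dtype=object)
        for c in bins.genome.names])
    coo = m.counts.tocoo()
    with open(path, "w") as fh:
        fh.write("#chrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            n = int(v)
            p1 = rng.integers(starts[i], ends[i], size=n)
            p2 = rng.integers(starts[j], ends[j], size=n)
            s1 = rng.choice(["+", "-"], size=n)
            s2 = rng.choice(["+", "-"], size=n)
            for k in range(n):
                fh.write(f"{chrom_of[i]}\t{p1[k]}\t{s1[k]}\t"
                         f"{chrom_of[j]}\t{p2[k]}\t{s2[k]}\n")


# ---------------------------------------------------------- transcription


def simulate_transcription(truth: SyntheticTruth, cell: str = "A",
                           seed: int | None = None) -> StrandTrackPair:
    """Strand-specific nascent-transcription tracks with divergent peaks.

    At each divergent border the plus strand carries a rectangle over
    [pos+500, pos+1000) and the minus strand over [pos-1000, pos-500); the
    plus:minus rate ratio is ``strand_rate_ratio``.  Poisson noise per bp
    unless ``transcription_noise`` is off.
    """
    p = truth.params
    rng = np.random.default_rng(p.seed + 2 if seed is None else seed)
    length = p.n_bins * p.bin_width
    rate_plus = np.full(length, p.background_rate if p.transcription_noise
                        else 0.0)
    rate_minus = rate_plus.copy()
    borders = truth.borders_a if cell == "A" else truth.borders_b
    divergent = truth.divergent_a if cell == "A" else truth.divergent_b
    ratio = p.strand_rate_ratio
    minus_rate = p.signal_rate
    plus_rate = p.signal_rate * ratio
    for pos, div in zip(borders, divergent):
        if not div:
            continue
        lo_p, hi_p = pos + 500, min(pos + 1000, length)
        lo_m, hi_m = max(pos - 1000, 0), pos - 500
        rate_plus[lo_p:hi_p] += plus_rate
        if hi_m > lo_m:
            rate_minus[lo_m:hi_m] += minus_rate
    if p.transcription_noise:
        plus = rng.poisson(rate_plus).astype(float)
        minus = rng.poisson(rate_minus).astype(float)
    else:
        plus, minus = rate_plus, rate_minus
    return StrandTrackPair({p.chrom: plus}, {p.chrom: minus})


# ------------------------------------------------------------ annotations


def simulate_annotations(truth: SyntheticTruth, seed: int | None = None
                         ) -> dict[str, pd.DataFrame]:
    """Enhancers (per cell type), GRBs, promoters and ncRNAs.

    Enhancers are placed centred on borders with class-dependent
    probabilities; common enhancers (placed for both cell types at
    conserved borders) are identical intervals in both sets.  GRBs are
    wider intervals with their own class bias.  Promoters/ncRNAs sit at
    loop-anchor bins with probability 0.5 / 0.1.
    """
    p = truth.params
    rng = np.random.default_rng(p.seed + 3 if seed is None else seed)
    enh_a, enh_b, grbs = [], [], []

    def interval(pos: int, width: int) -> dict:
        return {"chrom": p.chrom, "start": max(0, pos - width // 2),
                "end": min(p.n_bins * p.bin_width, pos + width // 2)}

    seen_b = set()
    for pos, cls in zip(truth.borders_a, truth.labels_a):
        if cls == "conserved" and rng.random() < p.p_enhancer["conserved"]:
            iv = interval(pos, p.enhancer_width)
            enh_a.append(iv)
            enh_b.append(dict(iv))       # common: identical in both sets
            seen_b.add(pos)
        elif cls != "conserved" and rng.random() < p.p_enhancer.get(cls, 0.0):
            enh_a.append(interval(pos, p.enhancer_width))
        if rng.random() < p.p_grb.get(cls, 0.0):
            grbs.append(interval(pos, p.grb_width))
    for pos, cls in zip(truth.borders_b, truth.labels_b):
        if pos in seen_b or cls == "conserved":
            continue
        if rng.random() < p.p_enhancer.get(cls, 0.0):
            enh_b.append(interval(pos, p.enhancer_width))

    promoters, ncrnas = [], []
    for i, j in truth.loops:
        for anchor in (i, j):
            pos = anchor * p.bin_width + p.bin_width // 2
            if rng.random() < 0.5:
                promoters.append(interval(pos, 500))
            if rng.random() < 0.1:
                ncrnas.append(interval(pos, 500))

    def frame(rows: list[dict]) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return df.sort_values(["chrom", "start"]).reset_index(drop=True)

    return {"enhancers_A": frame(enh_a), "enhancers_B": frame(enh_b),
            "grbs": frame(grbs), "promoters": frame(promoters),
            "ncrnas": frame(ncrnas)}


# ----------------------------------------------------- recovery utilities


def match_positions(called: np.ndarray, truth: np.ndarray,
                    tol_bp: int) -> tuple[float, float]:
    """(recall, precision) of called positions vs planted positions with a
    one-to-one greedy nearest match within ``tol_bp``."""
    called = np.sort(np.asarray(called, dtype=float))
    truth = np.sort(np.asarray(truth, dtype=float))
    if len(truth) == 0:
        return 1.0, 1.0 if len(called) == 0 else 0.0
    if len(called) == 0:
        return 0.0, 1.0
    used = np.zeros(len(called), dtype=bool)
    hits = 0
    for t in truth:
        d = np.abs(called - t)
        d[used] = np.inf
        k = int(np.argmin(d))
        if d[k] <= tol_bp:
            used[k] = True
            hits += 1
    return hits / len(truth), hits / len(called)


def match_loops(called: pd.DataFrame, truth_loops: np.ndarray,
                tol_bins: int = 2) -> tuple[float, float]:
    """(recall, precision) of called loop pixels vs planted pixels within a
    Chebyshev tolerance."""
    truths = [tuple(t) for t in truth_loops]
    calls = list(zip(called["bin1"], called["bin2"])) if len(called) else []
    if not truths:
        return 1.0, 1.0 if not calls else 0.0
    if not calls:
        return 0.0, 1.0
    used = [False] * len(calls)
    hits = 0
    for ti, tj in truths:
        best, best_d = None, np.inf
        for k, (ci, cj) in enumerate(calls):
            if used[k]:
                continue
            d = max(abs(ci - ti), abs(cj - tj))
            if d < best_d:
                best, best_d = k, d
        if best is not None and best_d <= tol_bins:
            used[best] = True
            hits += 1
    return hits / len(truths), hits / len(calls)
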