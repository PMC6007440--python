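"""Selection-scan layer: pairwise Fst, the d_i statistic, windowing,
empirical region calling and ΔCLR integration.

The scan standardizes per-SNV pairwise Fst between the focal population i
and each comparison population j by its genome-wide moments and sums over
comparisons:

    d_i = Σ_{j≠i} ( Fst^ij − E[Fst^ij] ) / sd[Fst^ij]

d_i is averaged over SNVs in non-overlapping fixed-size windows (100 kb by
default) and the empirical right tail (top 1% by default) of the window
distribution is called as candidate sweep regions.  CLR grids produced by
SweepFinder2 are windowed onto the same layout and combined as

    ΔCLR = CLR_focal − mean(CLR_other1, CLR_other2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import (
    CLRTrack,
    ConfigError,
    GenomeLayout,
    RegionSet,
    ValidationError,
    merge_regions,
    intersect_regions,
    regions_overlap_any,
)
from .allele_stats import FreqTable

logger = logging.getLogger("popsweep")

DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_TAIL = 0.01
DEFAULT_MIN_SNVS = 10


# ---------------------------------------------------------------------------
# Pairwise Fst
# ---------------------------------------------------------------------------


def hudson_fst(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Hudson's per-SNV Fst estimator (ratio form, finite-sample corrected).

    numerator   = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    denominator = p1(1−p2) + p2(1−p1)

    ``n1``/``n2`` are called allele counts.  NaN where either n ≤ 1, where
    the denominator is zero (both populations monomorphic for the same
    allele), or where a frequency is undefined.  Negative values are
    retained: clamping would bias the genome-wide moments.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num / den
    bad = (n1 <= 1) | (n2 <= 1) | (den == 0)
    fst = np.where(bad, np.nan, fst)
    return fst


def weir_cockerham_fst(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Weir–Cockerham θ for two populations from allele frequencies and
    allele counts (no within-individual component).  Exposed for
    sensitivity analysis alongside the Hudson default."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n1 + n2
        pbar = (n1 * p1 + n2 * p2) / n_tot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r-1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2)
        nc = n_tot - (n1**2 + n2**2) / n_tot
        theta = (msp - msg) / (msp + (nc - 1) * msg)
    bad = (n1 <= 1) | (n2 <= 1) | ((msp + (nc - 1) * msg) == 0)
    return np.where(bad, np.nan, theta)


_ESTIMATORS = {"hudson": hudson_fst, "wc": weir_cockerham_fst}


def pairwise_fst(
    freq: FreqTable, pair: tuple[str, str], estimator: str = "hudson"
) -> np.ndarray:
    """Per-SNV Fst between two populations of a FreqTable."""
    if estimator not in _ESTIMATORS:
        raise ConfigError(f"unknown Fst estimator {estimator!r}")
    a, b = pair
    return _ESTIMATORS[estimator](
        freq.freq_of(a), freq.counts_of(a), freq.freq_of(b), freq.counts_of(b)
    )


@dataclass
class FstMatrix:
    """Per-SNV Fst for each population pair plus genome-wide moments.

    Moments are computed over sites on chromosomes listed in the layout
    (so an autosome-only layout restricts them to autosomes).
    """

    chrom: np.ndarray
    pos: np.ndarray
    pairs: dict[tuple[str, str], np.ndarray]
    mean: dict[tuple[str, str], float]
    sd: dict[tuple[str, str], float]

    def get(self, a: str, b: str) -> np.ndarray:
        key = (a, b) if (a, b) in self.pairs else (b, a)
        return self.pairs[key]

    def moments(self, a: str, b: str) -> tuple[float, float]:
        key = (a, b) if (a, b) in self.pairs else (b, a)
        return self.mean[key], self.sd[key]


def fst_matrix(
    freq: FreqTable,
    pairs: list[tuple[str, str]] | None = None,
    layout: GenomeLayout | None = None,
    estimator: str = "hudson",
) -> FstMatrix:
    """Compute per-SNV Fst and genome-wide moments for population pairs.

    ``pairs`` defaults to all unordered pairs.  When a layout is given,
    moments use only SNVs on its chromosomes.
    """
    if pairs is None:
        pops = freq.populations
        pairs = [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]
    in_layout = (
        np.isin(freq.chrom.astype(str), np.asarray(layout.names, dtype=str))
        if layout is not None
        else np.ones(freq.n_sites, dtype=bool)
    )
    values: dict[tuple[str, str], np.ndarray] = {}
    means: dict[tuple[str, str], float] = {}
    sds: dict[tuple[str, str], float] = {}
    for pair in pairs:
        fst = pairwise_fst(freq, pair, estimator=estimator)
        use = in_layout & ~np.isnan(fst)
        if not use.any():
            raise ValidationError(f"no defined Fst values for pair {pair}")
        values[pair] = fst
        means[pair] = float(np.mean(fst[use]))
        sds[pair] = float(np.std(fst[use]))
    return FstMatrix(freq.chrom, freq.pos, values, means, sds)


def di_statistic(fst: FstMatrix, focal: str) -> np.ndarray:
    """Per-SNV d_i: sum over non-focal populations of z-scored pairwise Fst.

    Undefined (NaN) wherever any contributing pairwise Fst is undefined.
    """
    others = sorted({p for pair in fst.pairs for p in pair if p != focal})
    if not others:
        raise ValidationError(f"no pairs involving focal population {focal!r}")
    d = np.zeros(fst.pos.shape[0], dtype=float)
    for j in others:
        values = fst.get(focal, j)
        mean, sd = fst.moments(focal, j)
        if sd == 0:
            raise ValidationError(
                f"sd of Fst for pair ({focal}, {j}) is zero; "
                "check that the input is not degenerate"
            )
        d = d + (values - mean) / sd
    return d


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


@dataclass
class WindowTrack:
    """Per-window statistic values on a fixed tiling of the genome.

    ``value`` is NaN for masked windows (fewer contributing SNVs than the
    configured minimum, or no data).
    """

    chrom: np.ndarray   # object, per window
    start: np.ndarray   # int64
    end: np.ndarray     # int64
    value: np.ndarray   # float64, NaN = masked
    n_snvs: np.ndarray  # int64

    def __len__(self) -> int:
        return int(self.start.shape[0])

    @property
    def unmasked(self) -> np.ndarray:
        return ~np.isnan(self.value)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tn_snvs\tvalue\n")
            for i in range(len(self)):
                v = "NA" if np.isnan(self.value[i]) else repr(float(self.value[i]))
                fh.write(
                    f"{self.chrom[i]}\t{self.start[i]}\t{self.end[i]}\t"
                    f"{self.n_snvs[i]}\t{v}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "WindowTrack":
        chroms, starts, ends, ns, vals = [], [], [], [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("chrom\t"):
                raise ValidationError(f"window track {path}: missing header")
            for line in fh:
                c, s, e, n, v = line.rstrip("\n").split("\t")
                chroms.append(c)
                starts.append(int(s))
                ends.append(int(e))
                ns.append(int(n))
                vals.append(np.nan if v == "NA" else float(v))
        return cls(
            np.asarray(chroms, dtype=object),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.asarray(vals, dtype=np.float64),
            np.asarray(ns, dtype=np.int64),
        )


def _window_index(
    layout: GenomeLayout, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, int]]:
    """Window tiling plus the offset of each chromosome's first window."""
    chroms, starts, ends = layout.windows(size)
    offsets: dict[str, int] = {}
    for name in layout.names:
        offsets[name] = int(np.flatnonzero(chroms == name)[0]) if np.any(chroms == name) else 0
    return chroms, starts, ends, offsets


def window_mean(
    chrom: np.ndarray,
    pos0: np.ndarray,
    values: np.ndarray,
    layout: GenomeLayout,
    size: int = DEFAULT_WINDOW_SIZE,
    min_snvs: int = DEFAULT_MIN_SNVS,
) -> WindowTrack:
    """Arithmetic mean of defined per-SNV values in non-overlapping windows.

    ``pos0`` are 0-based point positions; a SNV falls in the window
    [start, start+size).  Windows with fewer than ``min_snvs`` defined
    values are masked.
    """
    if size <= 0:
        raise ConfigError(f"window size must be positive, got {size}")
    wchrom, wstart, wend, offsets = _window_index(layout, size)
    n_win = len(wstart)
    total = np.zeros(n_win)
    count = np.zeros(n_win, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    defined = ~np.isnan(values)
    for name in layout.names:
        on = (np.asarray(chrom, dtype=object) == name) & defined
        if not on.any():
            continue
        widx = offsets[name] + (np.asarray(pos0)[on] // size)
        np.add.at(total, widx, values[on])
        np.add.at(count, widx, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count >= max(min_snvs, 1), total / np.maximum(count, 1), np.nan)
    return WindowTrack(wchrom, wstart, wend, mean, count)


def empirical_top_regions(
    track: WindowTrack, tail: float = DEFAULT_TAIL
) -> tuple[RegionSet, float]:
    """Call the empirical right tail of a window track as regions.

    The threshold is the empirical (1−tail) quantile of unmasked window
    values; windows strictly above it are selected (ties at the threshold
    are excluded), and adjacent selected windows on the same chromosome are
    merged into regions scored by their maximum window value.
    """
    if not (0 < tail < 1):
        raise ConfigError(f"tail must be in (0, 1), got {tail}")
    ok = track.unmasked
    if not ok.any():
        raise ValidationError("all windows are masked")
    n_ok = int(ok.sum())
    if n_ok < 1.0 / tail:
        logger.warning(
            "empirical_top_regions: only %d unmasked windows for tail %g", n_ok, tail
        )
    threshold = float(np.quantile(track.value[ok], 1.0 - tail))
    selected = ok & (track.value > threshold)
    regions = _merge_adjacent_windows(track, selected, score="max")
    logger.info(
        "empirical_top_regions: threshold %.6g, %d windows -> %d regions",
        threshold, int(selected.sum()), len(regions),
    )
    return regions, threshold


def _merge_adjacent_windows(
    track: WindowTrack, selected: np.ndarray, score: str = "max"
) -> RegionSet:
    """Merge runs of adjacent selected windows into scored regions."""
    idx = np.flatnonzero(selected)
    if idx.size == 0:
        return RegionSet.empty()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    scores: list[float] = []
    run: list[int] = [int(idx[0])]
    for i in idx[1:]:
        i = int(i)
        prev = run[-1]
        if i == prev + 1 and track.chrom[i] == track.chrom[prev]:
            run.append(i)
        else:
            chroms.append(track.chrom[run[0]])
            starts.append(int(track.start[run[0]]))
            ends.append(int(track.end[run[-1]]))
            scores.append(_score_run(track, run, score))
            run = [i]
    chroms.append(track.chrom[run[0]])
    starts.append(int(track.start[run[0]]))
    ends.append(int(track.end[run[-1]]))
    scores.append(_score_run(track, run, score))
    return RegionSet(
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        score=np.asarray(scores, dtype=np.float64),
    )


def _score_run(track: WindowTrack, run: list[int], how: str) -> float:
    vals = track.value[run]
    return float(np.max(vals) if how == "max" else np.mean(vals))


# ---------------------------------------------------------------------------
# ΔCLR
# ---------------------------------------------------------------------------


def window_clr(
    clr: CLRTrack, layout: GenomeLayout, size: int = DEFAULT_WINDOW_SIZE
) -> WindowTrack:
    """Average CLR grid points within windows; windows without any grid
    point are masked."""
    return window_mean(clr.chrom, clr.pos, clr.clr, layout, size=size, min_snvs=1)


def delta_clr(
    focal: CLRTrack,
    others: tuple[CLRTrack, CLRTrack],
    layout: GenomeLayout,
    size: int = DEFAULT_WINDOW_SIZE,
) -> WindowTrack:
    """Per-window ΔCLR = CLR_focal − mean(CLR_other1, CLR_other2).

    Grid points are averaged within windows first; a window lacking any of
    the three tracks is masked.
    """
    wf = window_clr(focal, layout, size)
    w1 = window_clr(others[0], layout, size)
    w2 = window_clr(others[1], layout, size)
    value = wf.value - (w1.value + w2.value) / 2.0
    n = np.minimum(np.minimum(wf.n_snvs, w1.n_snvs), w2.n_snvs)
    return WindowTrack(wf.chrom, wf.start, wf.end, value, n)


# ---------------------------------------------------------------------------
# Region overlap and gene annotation
# ---------------------------------------------------------------------------


def overlap_fraction(a: RegionSet, b: RegionSet) -> tuple[float, RegionSet]:
    """Fraction of a's regions sharing ≥ 1 bp with b, plus the bp intersection."""
    if len(a) == 0:
        logger.warning("overlap_fraction: empty query region set")
        return 0.0, RegionSet.empty()
    hits = regions_overlap_any(a, b)
    return float(hits.mean()), intersect_regions(a, b)


def annotate_regions_with_genes(
    regions: RegionSet, genes: RegionSet
) -> tuple[list[list[str]], int]:
    """Genes intersecting each region, plus the global unique gene count.

    A gene spanning two regions appears in both per-region lists but is
    counted once globally.
    """
    if genes.name is None or any(n == "" for n in genes.name):
        raise ValidationError("gene intervals must carry names")
    per_region: list[list[str]] = []
    seen: set[str] = set()
    for i in range(len(regions)):
        on = genes.chrom == regions.chrom[i]
        hit = on & (genes.start < regions.end[i]) & (genes.end > regions.start[i])
        names = sorted(set(genes.name[hit].tolist()))
        per_region.append(names)
        seen.update(names)
    return per_region, len(seen)
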