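"""Haplotype-sharing introgression scan: IBD segments and the nIBD statistic.

For two populations A and B, every cross-population haplotype pair is a
potential sharing event.  In fixed genomic bins (10 kb by default) the
normalized IBD statistic is

    nIBD = cIBD / tIBD

where cIBD counts cross-population haplotype pairs with an IBD segment
overlapping the bin and tIBD = (2·n_A)·(2·n_B) is the total number of such
pairs.  The empirical top tail (5% by default) of the bin distribution is
called as introgressed regions.

The built-in segment caller is a deterministic run-based substitute for
HMM-based IBD callers: it emits maximal runs of identical alleles between a
haplotype pair (allowing a configurable number of mismatches) that span at
least a minimum physical length.  Externally produced segments may be
supplied instead via ``read_segments``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_io import (
    ConfigError,
    GenomeLayout,
    PopulationMap,
    RegionSet,
    ValidationError,
    VariantTable,
    intersect_regions,
    merge_regions,
    regions_overlap_any,
)
from .sweep_scan import WindowTrack, _merge_adjacent_windows

logger = logging.getLogger("popsweep")

DEFAULT_BIN_SIZE = 10_000
DEFAULT_TAIL = 0.05
DEFAULT_MIN_LENGTH = 150_000
DEFAULT_MAX_MISMATCH = 0


@dataclass
class IBDSegmentSet:
    """Pairwise haplotype IBD segments (0-based half-open coordinates).

    Haplotype ids are ``sample|0`` / ``sample|1``; ``pair`` is an integer
    id shared by all segments of one (hap A, hap B) pair.
    """

    hap_a: np.ndarray   # object: haplotype id in population A
    hap_b: np.ndarray   # object: haplotype id in population B
    pop_a: str
    pop_b: str
    chrom: np.ndarray   # object
    start: np.ndarray   # int64
    end: np.ndarray     # int64

    def __post_init__(self) -> None:
        if np.any(self.end <= self.start):
            raise ValidationError("IBD segment with end <= start")

    def __len__(self) -> int:
        return int(self.start.shape[0])

    def normalized(self) -> "IBDSegmentSet":
        """Merge overlapping segments of the same pair; idempotent."""
        if len(self) == 0:
            return self
        keys = np.array(
            [f"{a}\t{b}\t{c}" for a, b, c in zip(self.hap_a, self.hap_b, self.chrom)],
            dtype=object,
        )
        order = np.lexsort((self.start, keys.astype(str)))
        ha, hb, ch, st, en = [], [], [], [], []
        for i in order:
            i = int(i)
            if (
                ha
                and ha[-1] == self.hap_a[i]
                and hb[-1] == self.hap_b[i]
                and ch[-1] == self.chrom[i]
                and self.start[i] <= en[-1]
            ):
                en[-1] = max(en[-1], int(self.end[i]))
            else:
                ha.append(self.hap_a[i])
                hb.append(self.hap_b[i])
                ch.append(self.chrom[i])
                st.append(int(self.start[i]))
                en.append(int(self.end[i]))
        return IBDSegmentSet(
            np.asarray(ha, dtype=object),
            np.asarray(hb, dtype=object),
            self.pop_a,
            self.pop_b,
            np.asarray(ch, dtype=object),
            np.asarray(st, dtype=np.int64),
            np.asarray(en, dtype=np.int64),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hap_a\thap_b\tchrom\tstart\tend\n")
            for i in range(len(self)):
                fh.write(
                    f"{self.hap_a[i]}\t{self.hap_b[i]}\t{self.chrom[i]}\t"
                    f"{self.start[i]}\t{self.end[i]}\n"
                )


def read_segments(path: str | Path, pop_a: str, pop_b: str) -> IBDSegmentSet:
    """Read externally produced segments (hap_a hap_b chrom start end TSV)."""
    ha, hb, ch, st, en = [], [], [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["hap_a", "hap_b"]:
            raise ValidationError(f"segment file {path}: unexpected header {header}")
        for line in fh:
            a, b, c, s, e = line.rstrip("\n").split("\t")
            ha.append(a)
            hb.append(b)
            ch.append(c)
            st.append(int(s))
            en.append(int(e))
    return IBDSegmentSet(
        np.asarray(ha, dtype=object),
        np.asarray(hb, dtype=object),
        pop_a,
        pop_b,
        np.asarray(ch, dtype=object),
        np.asarray(st, dtype=np.int64),
        np.asarray(en, dtype=np.int64),
    )


def call_ibd_runs(
    vt: VariantTable,
    pm: PopulationMap,
    pop_a: str,
    pop_b: str,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> IBDSegmentSet:
    """Run-based IBD segment calling between two populations' haplotypes.

    For every cross-population haplotype pair, maximal runs of consecutive
    SNVs with identical alleles (allowing at most ``max_mismatch``
    mismatches inside a run) that span at least ``min_length`` bp are
    emitted, bounded by the first and last matching SNV positions.

    This deterministic caller substitutes for LD-aware HMM callers; supply
    precomputed segments via :func:`read_segments` when available.
    """
    if vt.haplotypes is None:
        raise ValidationError(
            "phased haplotypes required; supply precomputed IBD segments "
            "for unphased data"
        )
    pm.validate_samples(vt.samples)
    ia = pm.haplotype_indices(pop_a, vt.samples)
    ib = pm.haplotype_indices(pop_b, vt.samples)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("both populations need at least one sample")

    def hap_id(k: int) -> str:
        return f"{vt.samples[k // 2]}|{k % 2}"

    ha_out: list[str] = []
    hb_out: list[str] = []
    ch_out: list[str] = []
    st_out: list[int] = []
    en_out: list[int] = []
    for name in np.unique(vt.chrom):
        on = vt.chrom == name
        pos0 = vt.pos0[on]
        H = vt.haplotypes[:, on]
        S = pos0.shape[0]
        for i in ia:
            hi = H[i]
            for j in ib:
                mism = np.flatnonzero(hi != H[j])
                bounds = np.concatenate(([-1], mism, [S]))
                k = max_mismatch
                # run from bounds[t]+1 .. bounds[t+k+1]-1 spans <= k mismatches
                run_start = bounds[: len(bounds) - k - 1] + 1
                run_end = bounds[k + 1 :] - 1
                ok = run_end >= run_start
                run_start, run_end = run_start[ok], run_end[ok]
                if run_start.size == 0:
                    continue
                span_ok = pos0[run_end] - pos0[run_start] + 1 >= min_length
                for s, e in zip(run_start[span_ok], run_end[span_ok]):
                    ha_out.append(hap_id(int(i)))
                    hb_out.append(hap_id(int(j)))
                    ch_out.append(name)
                    st_out.append(int(pos0[s]))
                    en_out.append(int(pos0[e]) + 1)
    segs = IBDSegmentSet(
        np.asarray(ha_out, dtype=object),
        np.asarray(hb_out, dtype=object),
        pop_a,
        pop_b,
        np.asarray(ch_out, dtype=object),
        np.asarray(st_out, dtype=np.int64),
        np.asarray(en_out, dtype=np.int64),
    ).normalized()
    logger.info(
        "call_ibd_runs: %d segments (%s vs %s, min_length=%d, max_mismatch=%d)",
        len(segs), pop_a, pop_b, min_length, max_mismatch,
    )
    return segs


@dataclass
class IbdBinTrack:
    """Per-bin cIBD / tIBD accounting on a fixed genome tiling."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    cibd: np.ndarray    # int64: distinct cross-population pairs IBD over the bin
    tibd: int           # total cross-population haplotype pairs
    nibd: np.ndarray    # float64 = cibd / tibd

    def __len__(self) -> int:
        return int(self.start.shape[0])

    def as_window_track(self) -> WindowTrack:
        return WindowTrack(self.chrom, self.start, self.end, self.nibd, self.cibd)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tcibd\ttibd\tnibd\n")
            for i in range(len(self)):
                fh.write(
                    f"{self.chrom[i]}\t{self.start[i]}\t{self.end[i]}\t"
                    f"{self.cibd[i]}\t{self.tibd}\t{repr(float(self.nibd[i]))}\n"
                )


def nibd_bins(
    segs: IBDSegmentSet,
    pm: PopulationMap,
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
    unit: str = "haplotype",
) -> IbdBinTrack:
    """nIBD = cIBD/tIBD per fixed-size bin.

    A pair contributes to cIBD in every bin one of its segments overlaps by
    at least 1 bp; multiple segments of a pair in one bin count once.  With
    ``unit="haplotype"`` (default) tIBD = (2 n_A)(2 n_B) haplotype pairs;
    ``unit="individual"`` uses n_A · n_B individual pairs and counts a pair
    as IBD in a bin when any of its four haplotype combinations is.
    """
    n_a = len(pm.samples_of(segs.pop_a))
    n_b = len(pm.samples_of(segs.pop_b))
    if n_a == 0 or n_b == 0:
        raise ValidationError("both populations need at least one sample")
    if unit == "haplotype":
        tibd = (2 * n_a) * (2 * n_b)
    elif unit == "individual":
        tibd = n_a * n_b
    else:
        raise ConfigError(f"unknown tIBD unit {unit!r}")
    bchrom, bstart, bend = layout.windows(bin_size)
    n_bins = len(bstart)
    offsets: dict[str, int] = {}
    for name in layout.names:
        loc = np.flatnonzero(bchrom == name)
        offsets[name] = int(loc[0]) if loc.size else 0

    def pair_key(i: int) -> str:
        a, b = segs.hap_a[i], segs.hap_b[i]
        if unit == "individual":
            a, b = a.split("|")[0], b.split("|")[0]
        return f"{a}\t{b}"

    lengths = layout.length_by_name
    marks: set[tuple[str, int]] = set()
    for i in range(len(segs)):
        name = segs.chrom[i]
        if name not in offsets:
            raise ValidationError(f"segment chromosome {name!r} not in layout")
        if int(segs.end[i]) > lengths[name]:
            raise ValidationError(
                f"segment end {int(segs.end[i])} exceeds chromosome {name} length"
            )
        b0 = int(segs.start[i]) // bin_size
        b1 = (int(segs.end[i]) - 1) // bin_size
        key = pair_key(i)
        base = offsets[name]
        for b in range(b0, b1 + 1):
            marks.add((key, base + b))
    cibd = np.zeros(n_bins, dtype=np.int64)
    for _, b in marks:
        cibd[b] += 1
    return IbdBinTrack(bchrom, bstart, bend, cibd, tibd, cibd / tibd)


def call_introgressed_regions(
    track: IbdBinTrack,
    tail: float = DEFAULT_TAIL,
    min_avg: float | None = None,
) -> tuple[RegionSet, float]:
    """Call the top tail of the nIBD bin distribution as introgressed regions.

    The threshold is the empirical (1−tail) quantile of bin nIBD values, or
    ``min_avg`` when given (mirroring a fixed published cutoff); bins
    strictly above it are selected and adjacent selected bins merged.  Each
    region's score is its mean bin nIBD.
    """
    if not (0 < tail < 1):
        raise ConfigError(f"tail must be in (0, 1), got {tail}")
    if len(track) < 20:
        logger.warning("call_introgressed_regions: only %d bins", len(track))
    if min_avg is not None:
        threshold = float(min_avg)
    else:
        threshold = float(np.quantile(track.nibd, 1.0 - tail))
    selected = track.nibd > threshold
    wt = track.as_window_track()
    regions = _merge_adjacent_windows(wt, selected, score="mean")
    logger.info(
        "call_introgressed_regions: threshold %.6g, %d bins -> %d regions",
        threshold, int(selected.sum()), len(regions),
    )
    return regions, threshold


def compare_known_regions(
    called: RegionSet, known: RegionSet
) -> tuple[int, int]:
    """Shared base pairs and count of called regions overlapping known ones."""
    inter = intersect_regions(called, known)
    shared_bp = inter.total_length()
    shared_count = int(regions_overlap_any(called, known).sum())
    return shared_bp, shared_count
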