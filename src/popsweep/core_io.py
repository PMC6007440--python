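"""Shared data model and format I/O.

Reads and writes the standard formats the pipeline touches — VCF (genotypes,
optionally phased), two-column population maps, BED / GFF3-lite interval
tables, SweepFinder2 composite-likelihood grids and Newick trees — into a
small set of in-memory containers shared by every analysis stage.

Coordinate conventions
----------------------
Interval coordinates are 0-based half-open internally (the BED convention);
VCF and GFF3, which are 1-based, are converted at the boundary.  Per-SNV
positions are stored 1-based as printed in the VCF (``VariantTable.pos``);
``VariantTable.pos0`` exposes the 0-based point coordinate used for window
arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("popsweep")

#: Closed vocabulary of per-SNV functional class labels.
FUNCTIONAL_CLASSES: tuple[str, ...] = (
    "exonic-synonymous",
    "exonic-nonsynonymous",
    "exonic-stopgain",
    "exonic-stoploss",
    "splicing",
    "intronic",
    "UTR5",
    "UTR3",
    "upstream",
    "downstream",
    "intergenic",
)

_BASES = frozenset("ACGT")


class PopsweepError(Exception):
    """Base class for all errors raised by this package."""


class VcfParseError(PopsweepError):
    """A VCF file could not be parsed; the message names the offending line."""


class ValidationError(PopsweepError):
    """Input data violated a structural invariant."""


class ConfigError(PopsweepError):
    """An operation was configured with inconsistent parameters."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp).

    Only chromosomes listed here enter genome-wide moment computations; a
    layout restricted to autosomes therefore excludes sex chromosomes from
    the standardization of pairwise Fst by construction.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValidationError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise ValidationError("names and lengths differ in length")
        for name, length in zip(self.names, self.lengths):
            if length < 1:
                raise ValidationError(f"chromosome {name!r} has length {length} < 1")

    @property
    def length_by_name(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def n_windows(self, size: int) -> int:
        if size <= 0:
            raise ConfigError(f"window size must be positive, got {size}")
        return int(sum(-(-length // size) for length in self.lengths))

    def windows(self, size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Tile every chromosome from 0 in non-overlapping ``size``-bp windows.

        Returns parallel arrays (chrom, start, end); the trailing partial
        window is retained with its true (clipped) end.
        """
        if size <= 0:
            raise ConfigError(f"window size must be positive, got {size}")
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        for name, length in zip(self.names, self.lengths):
            s = np.arange(0, length, size, dtype=np.int64)
            chroms.extend([name] * len(s))
            starts.extend(s.tolist())
            ends.extend(np.minimum(s + size, length).tolist())
        return (
            np.asarray(chroms, dtype=object),
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        names: list[str] = []
        lengths: list[int] = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValidationError(f"layout line {raw!r}: expected 'name length'")
            names.append(parts[0])
            lengths.append(int(parts[1]))
        if not names:
            raise ValidationError(f"layout file {path} is empty")
        return cls(tuple(names), tuple(lengths))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Variant table
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Biallelic SNVs with a samples × sites genotype matrix.

    ``genotypes`` holds alternate-allele dosages in {0, 1, 2} with -1 for
    missing.  ``haplotypes``, when present, is the 2·samples × sites phased
    allele matrix (rows 2i, 2i+1 belong to sample i) and sums to the
    genotype matrix wherever the genotype is called.
    """

    chrom: np.ndarray          # object dtype, per site
    pos: np.ndarray            # int64, 1-based, per site
    ref: np.ndarray            # object dtype, single base
    alt: np.ndarray            # object dtype, single base
    samples: tuple[str, ...]
    genotypes: np.ndarray      # int8 (n_samples, n_sites)
    haplotypes: np.ndarray | None = None   # int8 (2*n_samples, n_sites)
    n_skipped_records: int = 0

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pos0(self) -> np.ndarray:
        """0-based point coordinates for window arithmetic."""
        return self.pos - 1

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def validate(self, layout: GenomeLayout | None = None) -> None:
        if self.genotypes.shape != (self.n_samples, self.n_sites):
            raise ValidationError("genotype matrix shape mismatch")
        for name in np.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {name}"
                )
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * self.n_samples, self.n_sites):
                raise ValidationError("haplotype matrix shape mismatch")
            hsum = self.haplotypes[0::2] + self.haplotypes[1::2]
            called = self.genotypes >= 0
            if not np.array_equal(hsum[called], self.genotypes[called]):
                raise ValidationError("haplotypes do not sum to genotypes")
        if layout is not None:
            lengths = layout.length_by_name
            for name in np.unique(self.chrom):
                if name not in lengths:
                    raise ValidationError(f"chromosome {name} not in layout")
                if int(self.pos[self.chrom == name].max()) > lengths[name]:
                    raise ValidationError(
                        f"position exceeds length of chromosome {name}"
                    )

    def take_sites(self, index: np.ndarray) -> "VariantTable":
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[:, index],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, index],
        )


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------


@dataclass
class PopulationMap:
    """Sample → population assignment with an optional focal designation."""

    assignment: dict[str, str]
    populations: tuple[str, ...]
    focal: str | None = None

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise ValidationError("need at least 2 populations")
        if self.focal is not None and self.focal not in self.populations:
            raise ValidationError(f"focal population {self.focal!r} not in map")

    def samples_of(self, pop: str) -> list[str]:
        if pop not in self.populations:
            raise ValidationError(f"unknown population {pop!r}")
        return [s for s, p in self.assignment.items() if p == pop]

    def sample_indices(self, pop: str, samples: Sequence[str]) -> np.ndarray:
        members = set(self.samples_of(pop))
        return np.asarray([i for i, s in enumerate(samples) if s in members], dtype=np.intp)

    def haplotype_indices(self, pop: str, samples: Sequence[str]) -> np.ndarray:
        si = self.sample_indices(pop, samples)
        return np.sort(np.concatenate([2 * si, 2 * si + 1]))

    def validate_samples(self, samples: Iterable[str]) -> None:
        for s in samples:
            if s not in self.assignment:
                raise ValidationError(f"sample {s!r} missing from population map")

    def population_labels(self, samples: Sequence[str]) -> np.ndarray:
        self.validate_samples(samples)
        return np.asarray([self.assignment[s] for s in samples], dtype=object)


def read_population_map(path: str | Path, focal: str | None = None) -> PopulationMap:
    """Read a two-column (sample, population) whitespace-separated table."""
    assignment: dict[str, str] = {}
    order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValidationError(f"population map line {raw!r}: expected 'sample population'")
        sample, pop = parts[0], parts[1]
        if sample in assignment:
            raise ValidationError(f"duplicate sample {sample!r} in population map")
        assignment[sample] = pop
        if pop not in order:
            order.append(pop)
    if not assignment:
        raise ValidationError(f"population map {path} is empty")
    return PopulationMap(assignment, tuple(order), focal=focal)


def write_population_map(pm: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pm.assignment.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """One functional class label per SNV, aligned with a VariantTable."""

    classes: np.ndarray  # object dtype, per site

    def __post_init__(self) -> None:
        bad = set(np.unique(self.classes)) - set(FUNCTIONAL_CLASSES)
        if bad:
            raise ValidationError(f"unknown functional classes: {sorted(bad)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        labels = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            labels.append(line.split("\t")[-1])
        return cls(np.asarray(labels, dtype=object))

    def to_tsv(self, path: str | Path, vt: VariantTable | None = None) -> None:
        with open(path, "w") as fh:
            if vt is None:
                for c in self.classes:
                    fh.write(f"{c}\n")
            else:
                for chrom, pos, c in zip(vt.chrom, vt.pos, self.classes):
                    fh.write(f"{chrom}\t{pos}\t{c}\n")


# ---------------------------------------------------------------------------
# CLR track (SweepFinder2 grid)
# ---------------------------------------------------------------------------


@dataclass
class CLRTrack:
    """Composite-likelihood-ratio grid for one population."""

    population: str
    chrom: np.ndarray  # object dtype
    pos: np.ndarray    # int64, 0-based (grid positions floored)
    clr: np.ndarray    # float64, >= 0

    def __post_init__(self) -> None:
        if np.any(self.clr < 0):
            raise ValidationError("CLR values must be non-negative")
        for name in np.unique(self.chrom):
            p = self.pos[self.chrom == name]
            if np.any(np.diff(p) < 0):
                raise ValidationError(f"CLR grid positions decrease on chromosome {name}")


def read_clr_grid(
    path: str | Path, population: str = "", default_chrom: str = "1"
) -> CLRTrack:
    """Read a SweepFinder2 output grid (``location\\tLR\\talpha``).

    SweepFinder2 emits one file per chromosome without a chromosome column;
    ``default_chrom`` names it.  A leading ``chrom`` column is honoured when
    present.  Fractional grid locations are floored to integer base
    positions (then shifted to 0-based).
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"CLR grid {path} is empty (no header)")
    header = lines[0].rstrip("\n").split("\t")
    cols = {c.strip().lower(): i for i, c in enumerate(header)}
    if "location" not in cols or not ({"lr", "clr"} & set(cols)):
        raise ValidationError(f"CLR grid {path}: header must contain 'location' and 'LR'")
    lr_col = cols.get("lr", cols.get("clr"))
    chrom_col = cols.get("chrom", cols.get("chromosome"))
    chroms: list[str] = []
    poss: list[int] = []
    lrs: list[float] = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        lr = float(parts[lr_col])
        if lr < 0:
            raise ValidationError(f"negative LR value {lr} in {path}")
        chroms.append(parts[chrom_col] if chrom_col is not None else default_chrom)
        poss.append(int(np.floor(float(parts[cols['location']]))) - 1)
        lrs.append(lr)
    return CLRTrack(
        population,
        np.asarray(chroms, dtype=object),
        np.asarray(poss, dtype=np.int64),
        np.asarray(lrs, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# Region sets (BED / GFF3-lite)
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """Genomic intervals, 0-based half-open, with optional names and scores."""

    chrom: np.ndarray                 # object dtype
    start: np.ndarray                 # int64
    end: np.ndarray                   # int64
    name: np.ndarray | None = None    # object dtype
    score: np.ndarray | None = None   # float64

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.name is not None:
            self.name = np.asarray(self.name, dtype=object)
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=np.float64)
        if np.any(self.end <= self.start):
            bad = int(np.flatnonzero(self.end <= self.start)[0])
            raise ValidationError(
                f"interval {self.chrom[bad]}:{self.start[bad]}-{self.end[bad]}: end <= start"
            )

    def __len__(self) -> int:
        return int(self.start.shape[0])

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(
            np.asarray([], dtype=object),
            np.asarray([], dtype=np.int64),
            np.asarray([], dtype=np.int64),
        )

    def total_length(self) -> int:
        return int((self.end - self.start).sum())

    def sorted(self) -> "RegionSet":
        order = np.lexsort((self.start, self.chrom.astype(str)))
        return RegionSet(
            self.chrom[order],
            self.start[order],
            self.end[order],
            None if self.name is None else self.name[order],
            None if self.score is None else self.score[order],
        )

    def equals(self, other: "RegionSet") -> bool:
        return (
            np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.start, other.start)
            and np.array_equal(self.end, other.end)
        )


def merge_regions(rs: RegionSet) -> RegionSet:
    """Merge overlapping or touching intervals; result sorted and disjoint."""
    if len(rs) == 0:
        return RegionSet.empty()
    s = rs.sorted()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for c, a, b in zip(s.chrom, s.start, s.end):
        if chroms and chroms[-1] == c and a <= ends[-1]:
            ends[-1] = max(ends[-1], int(b))
        else:
            chroms.append(c)
            starts.append(int(a))
            ends.append(int(b))
    return RegionSet(
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
    )


def intersect_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Base-pair intersection of two (not necessarily disjoint) region sets."""
    if len(a) == 0 or len(b) == 0:
        return RegionSet.empty()
    am, bm = merge_regions(a), merge_regions(b)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name in sorted(set(am.chrom) & set(bm.chrom)):
        ai = np.flatnonzero(am.chrom == name)
        bi = np.flatnonzero(bm.chrom == name)
        i = j = 0
        while i < len(ai) and j < len(bi):
            s = max(am.start[ai[i]], bm.start[bi[j]])
            e = min(am.end[ai[i]], bm.end[bi[j]])
            if s < e:
                chroms.append(name)
                starts.append(int(s))
                ends.append(int(e))
            if am.end[ai[i]] < bm.end[bi[j]]:
                i += 1
            else:
                j += 1
    if not chroms:
        return RegionSet.empty()
    return RegionSet(
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
    )


def regions_overlap_any(a: RegionSet, b: RegionSet) -> np.ndarray:
    """Boolean per region of ``a``: does it share >= 1 bp with any region of ``b``."""
    out = np.zeros(len(a), dtype=bool)
    if len(a) == 0 or len(b) == 0:
        return out
    bm = merge_regions(b)
    for i in range(len(a)):
        on = bm.chrom == a.chrom[i]
        if not on.any():
            continue
        s, e = bm.start[on], bm.end[on]
        out[i] = bool(np.any((s < a.end[i]) & (e > a.start[i])))
    return out


def read_intervals(path: str | Path, layout: GenomeLayout | None = None) -> RegionSet:
    """Read BED3/BED4(+score) or GFF3-lite gene records into a RegionSet.

    GFF3 is detected from the ``##gff-version`` pragma or a .gff/.gff3
    suffix; only ``gene`` features are kept and their 1-based inclusive
    coordinates are converted to 0-based half-open.
    """
    path = Path(path)
    text = path.read_text()
    is_gff = path.suffix.lower() in {".gff", ".gff3"} or text.startswith("##gff-version")
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    scores: list[float] = []
    have_name = have_score = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("track"):
            continue
        parts = line.split("\t")
        if is_gff:
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end = parts[0], int(parts[3]) - 1, int(parts[4])
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name", attrs.get("ID", ""))
            if name:
                have_name = True
            names.append(name)
        else:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if len(parts) > 3:
                have_name = True
                names.append(parts[3])
            else:
                names.append("")
            if len(parts) > 4:
                have_score = True
                scores.append(float(parts[4]))
            else:
                scores.append(np.nan)
        if end <= start:
            raise ValidationError(f"interval line {raw!r}: end <= start")
        if layout is not None and chrom not in layout:
            raise ValidationError(f"interval chromosome {chrom!r} not in layout")
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
    return RegionSet(
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(names, dtype=object) if have_name else None,
        np.asarray(scores, dtype=np.float64) if have_score else None,
    )


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3/BED4/BED5 (columns present iff populated)."""
    with open(path, "w") as fh:
        for i in range(len(regions)):
            cols = [str(regions.chrom[i]), str(regions.start[i]), str(regions.end[i])]
            if regions.name is not None or regions.score is not None:
                cols.append(str(regions.name[i]) if regions.name is not None else ".")
            if regions.score is not None:
                cols.append(format(float(regions.score[i]), "g"))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _check_vcf_structure(path: Path) -> None:
    """Cheap structural pass so parse errors can name the offending line."""
    n_fields: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_fields = len(line.split("\t"))
                if n_fields < 10:
                    raise VcfParseError(
                        f"line {lineno}: #CHROM header has no sample columns"
                    )
                continue
            if n_fields is None:
                raise VcfParseError(f"line {lineno}: data before #CHROM header")
            parts = line.split("\t")
            if len(parts) != n_fields:
                raise VcfParseError(
                    f"line {lineno}: expected {n_fields} fields, found {len(parts)}"
                )
            if not parts[1].isdigit():
                raise VcfParseError(f"line {lineno}: POS {parts[1]!r} is not an integer")
    if n_fields is None:
        raise VcfParseError("no #CHROM header line found")


def layout_from_vcf(path: str | Path) -> GenomeLayout:
    """Build a GenomeLayout from the ##contig header lines of a VCF."""
    from cyvcf2 import VCF

    v = VCF(str(path))
    names, lengths = list(v.seqnames), list(v.seqlens)
    v.close()
    if not names:
        raise ValidationError(f"VCF {path} has no ##contig header lines")
    return GenomeLayout(tuple(names), tuple(int(x) for x in lengths))


def read_vcf(path: str | Path, layout: GenomeLayout | None = None) -> VariantTable:
    """Read biallelic SNVs from a VCF 4.x file.

    Multiallelic and non-SNV records are skipped (counted in
    ``n_skipped_records``).  Phased haplotypes are populated iff every
    retained genotype uses the ``|`` separator and is fully called.
    """
    from cyvcf2 import VCF

    path = Path(path)
    _check_vcf_structure(path)
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    n = len(samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gt_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        if v.REF not in _BASES or v.ALT[0] not in _BASES:
            skipped += 1
            continue
        g = np.empty(n, dtype=np.int8)
        h = np.empty(2 * n, dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a, b = int(gt[0]), int(gt[1])
            phased = bool(gt[2])
            if a < 0 or b < 0:
                g[i] = -1
                all_phased = False
            else:
                g[i] = a + b
                h[2 * i] = a
                h[2 * i + 1] = b
                if not phased:
                    all_phased = False
        chroms.append(v.CHROM)
        poss.append(int(v.POS))
        refs.append(v.REF)
        alts.append(v.ALT[0])
        gt_cols.append(g)
        hap_cols.append(h)
    vcf.close()
    n_sites = len(poss)
    genotypes = (
        np.stack(gt_cols, axis=1) if n_sites else np.empty((n, 0), dtype=np.int8)
    )
    haplotypes = None
    if all_phased and n_sites:
        haplotypes = np.stack(hap_cols, axis=1)
    vt = VariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        samples=samples,
        genotypes=genotypes,
        haplotypes=haplotypes,
        n_skipped_records=skipped,
    )
    vt.validate(layout)
    logger.info(
        "read_vcf: %d SNVs, %d samples, %d records skipped (%s)",
        n_sites, n, skipped, path.name,
    )
    return vt


def write_vcf(
    vt: VariantTable, path: str | Path, layout: GenomeLayout | None = None
) -> None:
    """Write a VariantTable as a minimal, deterministic VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsweep\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if layout is not None:
            for name, length in zip(layout.names, layout.lengths):
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.samples)
            + "\n"
        )
        phased = vt.haplotypes is not None
        for j in range(vt.n_sites):
            fields = [
                str(vt.chrom[j]), str(vt.pos[j]), ".",
                str(vt.ref[j]), str(vt.alt[j]), ".", ".", ".", "GT",
            ]
            for i in range(vt.n_samples):
                g = int(vt.genotypes[i, j])
                if g < 0:
                    fields.append("./.")
                elif phased:
                    a = int(vt.haplotypes[2 * i, j])
                    b = int(vt.haplotypes[2 * i + 1, j])
                    fields.append(f"{a}|{b}")
                else:
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[g])
            fh.write("\t".join(fields) + "\n")
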