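"""Three-population synthetic datasets with known truth.

Background differentiation follows the Balding–Nichols model: an ancestral
allele frequency p ~ Uniform(0.05, 0.95) per SNV, and each population draws
its own frequency from Beta(p(1−F)/F, (1−p)(1−F)/F), where F is the drift
coefficient.  Phased haplotypes are then Bernoulli draws from the
population frequency, independent across sites (no linkage model; copied
introgression tracts supply the linkage signal where the IBD caller needs
one).  On top of the drifted background the generator plants

* sweep regions — per-SNV frequencies inside the region overwritten by
  configured focal / non-focal targets (near-fixed differentiation, the
  end-state signature a frequency scan detects);
* introgressed tracts — a seeded fraction of recipient-population
  haplotypes has its in-tract alleles replaced by a randomly chosen donor
  haplotype's alleles;
* per-SNV functional class labels, optionally tilted (by an odds factor)
  toward one class inside a configured ΔAF range.

Every draw flows from one ``numpy`` Generator seeded from the config, so a
fixed seed yields byte-identical output files.  The emitted truth set
(sweep BED, tract BED with carriers, fixed-difference SNV list, class TSV)
gives each pipeline stage an exact reference to recover.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    AnnotationTable,
    FUNCTIONAL_CLASSES,
    GenomeLayout,
    PopulationMap,
    RegionSet,
    ValidationError,
    VariantTable,
    write_population_map,
    write_regions,
    write_vcf,
)
from .allele_stats import alt_allele_freq, delta_af

logger = logging.getLogger("popsweep")

#: Genome-wide functional class proportions used by default, ordered as
#: FUNCTIONAL_CLASSES.  Roughly the composition of a mammalian SNV set:
#: mostly intergenic and intronic, a few percent exonic.
DEFAULT_CLASS_PROPORTIONS: tuple[float, ...] = (
    0.040,   # exonic-synonymous
    0.035,   # exonic-nonsynonymous
    0.0025,  # exonic-stopgain
    0.0025,  # exonic-stoploss
    0.005,   # splicing
    0.300,   # intronic
    0.005,   # UTR5
    0.010,   # UTR3
    0.030,   # upstream
    0.030,   # downstream
    0.540,   # intergenic
)


@dataclass(frozen=True)
class SweepRegionSpec:
    chrom: str
    start: int            # 0-based half-open
    end: int
    focal_target: float   # AltAF imposed on the focal population in-region
    nonfocal_target: float


@dataclass(frozen=True)
class TractSpec:
    chrom: str
    start: int
    end: int
    donor: str
    recipient: str
    carrier_fraction: float


@dataclass(frozen=True)
class ClassTiltSpec:
    """Odds-multiplier for one class inside one ΔAF range."""

    functional_class: str
    lo: float
    hi: float
    odds: float


@dataclass
class SimConfig:
    """Study conditions for the synthetic three-population genome.

    Defaults describe the sweep-scan condition: one 10-Mb chromosome
    carrying 2,000 SNVs (100 windows of 100 kb), three populations of 30
    samples drifted at F = 0.1, and a single planted fixed-difference
    region in the focal population.
    """

    seed: int = 0
    populations: tuple[tuple[str, int], ...] = (("MS", 30), ("DU", 30), ("TB", 30))
    focal: str = "MS"
    chrom_names: tuple[str, ...] = ("1",)
    chrom_lengths: tuple[int, ...] = (10_000_000,)
    n_snvs: int = 2_000
    drift: dict[str, float] = field(default_factory=lambda: {"MS": 0.1, "DU": 0.1, "TB": 0.1})
    sweep_regions: tuple[SweepRegionSpec, ...] = (
        SweepRegionSpec("1", 4_500_000, 4_600_000, 1.0, 0.0),
    )
    tracts: tuple[TractSpec, ...] = ()
    class_proportions: tuple[float, ...] = DEFAULT_CLASS_PROPORTIONS
    class_tilt: ClassTiltSpec | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValidationError("class proportions must sum to 1")
        for pop, f in self.drift.items():
            if not (0 < f < 1):
                raise ValidationError(f"drift F for {pop!r} must be in (0, 1), got {f}")
        lengths = dict(zip(self.chrom_names, self.chrom_lengths))
        for r in self.sweep_regions:
            if r.chrom not in lengths or r.end > lengths[r.chrom] or r.start < 0:
                raise ValidationError(f"sweep region {r} outside layout")
            if not (0 <= r.focal_target <= 1 and 0 <= r.nonfocal_target <= 1):
                raise ValidationError(f"sweep region targets outside [0, 1]: {r}")
        for t in self.tracts:
            if t.chrom not in lengths or t.end > lengths[t.chrom] or t.start < 0:
                raise ValidationError(f"tract {t} outside layout")
            if not (0 <= t.carrier_fraction <= 1):
                raise ValidationError(f"carrier fraction outside [0, 1]: {t}")
            if t.donor == t.recipient:
                raise ValidationError("tract donor and recipient must differ")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_names, self.chrom_lengths)

    @property
    def pop_labels(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.populations)

    def population_map(self) -> PopulationMap:
        assignment: dict[str, str] = {}
        for pop, size in self.populations:
            for i in range(size):
                assignment[f"{pop}_{i:03d}"] = pop
        return PopulationMap(assignment, self.pop_labels, focal=self.focal)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_regions"] = [dataclasses.asdict(r) for r in self.sweep_regions]
        d["tracts"] = [dataclasses.asdict(t) for t in self.tracts]
        if self.class_tilt is not None:
            d["class_tilt"] = dataclasses.asdict(self.class_tilt)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["populations"] = tuple((p, int(n)) for p, n in d.get("populations", cls().populations))
        d["chrom_names"] = tuple(d.get("chrom_names", cls().chrom_names))
        d["chrom_lengths"] = tuple(int(x) for x in d.get("chrom_lengths", cls().chrom_lengths))
        if "sweep_regions" in d:
            d["sweep_regions"] = tuple(SweepRegionSpec(**r) for r in d["sweep_regions"])
        if "tracts" in d:
            d["tracts"] = tuple(TractSpec(**t) for t in d["tracts"])
        if d.get("class_tilt"):
            d["class_tilt"] = ClassTiltSpec(**d["class_tilt"])
        if "class_proportions" in d:
            d["class_proportions"] = tuple(d["class_proportions"])
        return cls(**d)


# --- scenario presets -------------------------------------------------------


def sweep_scenario(seed: int = 0) -> SimConfig:
    """Default sweep-scan condition (see SimConfig defaults)."""
    return SimConfig(seed=seed)


def introgression_scenario(seed: int = 0) -> SimConfig:
    """Introgression condition: a denser 10,000-SNV panel (run-based IBD
    detection needs marker density that frequency scans do not) and two
    planted 200-kb donor tracts at carrier fraction 0.5; no sweep regions."""
    return SimConfig(
        seed=seed,
        n_snvs=10_000,
        sweep_regions=(),
        tracts=(
            TractSpec("1", 1_500_000, 1_700_000, "MS", "DU", 0.5),
            TractSpec("1", 7_000_000, 7_200_000, "MS", "DU", 0.5),
        ),
    )


def enrichment_scenario(
    seed: int = 0,
    n_snvs: int = 2_000,
    tilt: ClassTiltSpec | None = ClassTiltSpec("intronic", 0.8, 1.0, 3.0),
) -> SimConfig:
    """Enrichment condition: stronger drift (F = 0.2) plus eight planted
    near-fixed sweep windows so the high-ΔAF range is populated, with an
    optional class tilt inside a ΔAF range."""
    sweeps = tuple(
        SweepRegionSpec("1", s, s + 100_000, 1.0, 0.0)
        for s in range(1_000_000, 8_600_000, 1_000_000)
    )
    return SimConfig(
        seed=seed,
        n_snvs=n_snvs,
        drift={"MS": 0.2, "DU": 0.2, "TB": 0.2},
        sweep_regions=sweeps,
        class_tilt=tilt,
    )


# --- truth ------------------------------------------------------------------


@dataclass
class TruthSet:
    """Planted ground truth aligned with the emitted VariantTable."""

    sweep_regions: RegionSet
    tracts: RegionSet
    tract_carriers: list[list[str]]      # haplotype ids per tract
    fixed_difference_sites: np.ndarray   # site indices with ΔAF target = 1
    classes: AnnotationTable | None = None


# --- operations -------------------------------------------------------------


def _distinct_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on a chromosome of given length."""
    if n > length:
        raise ValidationError("more SNVs requested than positions available")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos


def simulate_frequencies(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Balding–Nichols per-SNV per-population frequencies.

    Returns (chrom, pos(1-based), ancestral p, freq matrix (n_pops, n_snvs)).
    Inside sweep regions the focal / non-focal frequencies are overwritten
    by the configured targets.
    """
    n_per_chrom = np.full(len(cfg.chrom_names), cfg.n_snvs // len(cfg.chrom_names))
    n_per_chrom[: cfg.n_snvs % len(cfg.chrom_names)] += 1
    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    for name, length, n in zip(cfg.chrom_names, cfg.chrom_lengths, n_per_chrom):
        p = _distinct_positions(rng, length, int(n))
        chroms.append(np.full(p.shape, name, dtype=object))
        poss.append(p)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    n_snvs = pos.shape[0]
    anc = rng.uniform(0.05, 0.95, size=n_snvs)
    pops = cfg.pop_labels
    freq = np.empty((len(pops), n_snvs))
    for k, pop in enumerate(pops):
        f = cfg.drift[pop]
        a = anc * (1 - f) / f
        b = (1 - anc) * (1 - f) / f
        freq[k] = rng.beta(a, b)
    focal_idx = pops.index(cfg.focal)
    for r in cfg.sweep_regions:
        inr = (chrom == r.chrom) & (pos - 1 >= r.start) & (pos - 1 < r.end)
        for k in range(len(pops)):
            freq[k, inr] = r.focal_target if k == focal_idx else r.nonfocal_target
    return chrom, pos, anc, freq


def sample_genotypes(
    chrom: np.ndarray,
    pos: np.ndarray,
    freq: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> VariantTable:
    """Draw phased haplotypes ~ Bernoulli(population frequency) per site."""
    pm = cfg.population_map()
    samples = tuple(pm.assignment)
    n_samples = len(samples)
    n_snvs = pos.shape[0]
    hap = np.empty((2 * n_samples, n_snvs), dtype=np.int8)
    pops = cfg.pop_labels
    for k, pop in enumerate(pops):
        hidx = pm.haplotype_indices(pop, samples)
        u = rng.random((hidx.size, n_snvs))
        hap[hidx] = (u < freq[k]).astype(np.int8)
    gt = (hap[0::2] + hap[1::2]).astype(np.int8)
    ref = np.full(n_snvs, "A", dtype=object)
    alt = np.full(n_snvs, "G", dtype=object)
    return VariantTable(chrom, pos.astype(np.int64), ref, alt, samples, gt, hap)


def impose_introgression(
    vt: VariantTable, cfg: SimConfig, rng: np.random.Generator
) -> tuple[VariantTable, RegionSet, list[list[str]]]:
    """Copy donor haplotype alleles into a carrier subset of recipient
    haplotypes inside each configured tract.  Returns the modified table,
    the tract RegionSet and per-tract carrier haplotype ids."""
    if not cfg.tracts:
        return vt, RegionSet.empty(), []
    pm = cfg.population_map()
    hap = vt.haplotypes.copy()
    carriers_out: list[list[str]] = []
    chs, sts, ens, nms = [], [], [], []
    for t in cfg.tracts:
        donor_h = pm.haplotype_indices(t.donor, vt.samples)
        recip_h = pm.haplotype_indices(t.recipient, vt.samples)
        n_carriers = int(round(t.carrier_fraction * recip_h.size))
        carriers = rng.choice(recip_h, size=n_carriers, replace=False)
        carriers = np.sort(carriers)
        in_tract = (vt.chrom == t.chrom) & (vt.pos0 >= t.start) & (vt.pos0 < t.end)
        ids: list[str] = []
        for c in carriers:
            donor = int(rng.choice(donor_h))
            hap[int(c), in_tract] = hap[donor, in_tract]
            ids.append(f"{vt.samples[int(c) // 2]}|{int(c) % 2}")
        carriers_out.append(ids)
        chs.append(t.chrom)
        sts.append(t.start)
        ens.append(t.end)
        nms.append(f"{t.donor}->{t.recipient}")
    gt = (hap[0::2] + hap[1::2]).astype(np.int8)
    vt2 = dataclasses.replace(vt, genotypes=gt, haplotypes=hap)
    tracts = RegionSet(
        np.asarray(chs, dtype=object),
        np.asarray(sts, dtype=np.int64),
        np.asarray(ens, dtype=np.int64),
        np.asarray(nms, dtype=object),
    )
    return vt2, tracts, carriers_out


def assign_classes(
    vt: VariantTable, cfg: SimConfig, rng: np.random.Generator
) -> AnnotationTable:
    """Draw per-SNV functional classes from the configured proportions.

    With a class tilt configured, SNVs whose realized ΔAF (focal vs the
    two comparison populations) falls in [lo, hi] have the tilted class's
    probability multiplied by the odds factor (renormalized).
    """
    props = np.asarray(cfg.class_proportions)
    n = vt.n_sites
    probs = np.tile(props, (n, 1))
    if cfg.class_tilt is not None:
        t = cfg.class_tilt
        pm = cfg.population_map()
        freq = alt_allele_freq(vt, pm)
        others = tuple(p for p in cfg.pop_labels if p != cfg.focal)
        d = delta_af(freq, cfg.focal, (others[0], others[1]))
        inr = (d >= t.lo) & (d <= t.hi)
        ci = FUNCTIONAL_CLASSES.index(t.functional_class)
        probs[inr, ci] *= t.odds
        probs[inr] /= probs[inr].sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    labels = np.asarray(FUNCTIONAL_CLASSES, dtype=object)[idx]
    return AnnotationTable(labels)


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[VariantTable, PopulationMap, TruthSet]:
    """Run the full generator: frequencies → haplotypes → tracts → classes."""
    rng = np.random.default_rng(cfg.seed)
    chrom, pos, _, freq = simulate_frequencies(cfg, rng)
    vt = sample_genotypes(chrom, pos, freq, cfg, rng)
    vt, tracts, carriers = impose_introgression(vt, cfg, rng)
    classes = assign_classes(vt, cfg, rng)
    pm = cfg.population_map()
    fixed = _fixed_difference_sites(cfg, chrom, pos)
    sweep_bed = (
        RegionSet(
            np.asarray([r.chrom for r in cfg.sweep_regions], dtype=object),
            np.asarray([r.start for r in cfg.sweep_regions], dtype=np.int64),
            np.asarray([r.end for r in cfg.sweep_regions], dtype=np.int64),
            np.asarray(
                [f"sweep_{i}" for i in range(len(cfg.sweep_regions))], dtype=object
            ),
        )
        if cfg.sweep_regions
        else RegionSet.empty()
    )
    truth = TruthSet(sweep_bed, tracts, carriers, fixed, classes)
    vt.validate(cfg.layout)
    return vt, pm, truth


def _fixed_difference_sites(
    cfg: SimConfig, chrom: np.ndarray, pos: np.ndarray
) -> np.ndarray:
    """Site indices inside sweep regions with targets (1, 0) — planted
    fixed differences with ΔAF = 1 by construction."""
    mask = np.zeros(pos.shape[0], dtype=bool)
    for r in cfg.sweep_regions:
        if r.focal_target == 1.0 and r.nonfocal_target == 0.0:
            mask |= (chrom == r.chrom) & (pos - 1 >= r.start) & (pos - 1 < r.end)
    return np.flatnonzero(mask)


def write_dataset(
    vt: VariantTable,
    pm: PopulationMap,
    truth: TruthSet,
    cfg: SimConfig,
    outdir: str | Path,
) -> dict[str, str]:
    """Emit VCF, population map, truth BEDs, class TSV and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "synthetic.vcf"),
        "popmap": str(outdir / "popmap.tsv"),
        "sweep_truth": str(outdir / "sweep_truth.bed"),
        "tract_truth": str(outdir / "tract_truth.bed"),
        "classes": str(outdir / "classes.tsv"),
        "manifest": str(outdir / "manifest.json"),
    }
    write_vcf(vt, paths["vcf"], layout=cfg.layout)
    write_population_map(pm, paths["popmap"])
    write_regions(truth.sweep_regions, paths["sweep_truth"])
    write_regions(truth.tracts, paths["tract_truth"])
    if truth.classes is not None:
        truth.classes.to_tsv(paths["classes"], vt)
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_snvs": vt.n_sites,
        "n_samples": vt.n_samples,
        "tract_carriers": truth.tract_carriers,
        "fixed_difference_sites": truth.fixed_difference_sites.tolist(),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("write_dataset: %d SNVs, %d samples -> %s", vt.n_sites, vt.n_samples, outdir)
    return paths
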