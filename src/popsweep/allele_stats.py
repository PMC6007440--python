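"""Per-population allele frequencies and the ΔAF differentiation layer.

ΔAF contrasts the focal population's alternate-allele frequency with the
mean of two comparison populations:

    ΔAF = | AltAF_focal − (AltAF_other1 + AltAF_other2) / 2 |

High ΔAF marks SNVs differentiated specifically in the focal population;
ΔAF = 1 identifies alleles fixed in the focal population and absent
elsewhere.  The module also calls fixed breed-specific SNVs by frequency
thresholds, bins ΔAF in steps of 0.05, and tests functional classes for
enrichment of ΔAF ranges with a Pearson χ² on 2×2 tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import (
    AnnotationTable,
    ConfigError,
    FUNCTIONAL_CLASSES,
    PopulationMap,
    ValidationError,
    VariantTable,
)

logger = logging.getLogger("popsweep")


@dataclass
class FreqTable:
    """Per-SNV, per-population alternate-allele frequencies and counts.

    ``freq[p, s]`` is the alternate-allele frequency of population ``p`` at
    site ``s`` (NaN where no allele was called); ``counts[p, s]`` is the
    number of called allele copies (2 × non-missing genotypes).
    """

    chrom: np.ndarray
    pos: np.ndarray
    populations: tuple[str, ...]
    freq: np.ndarray      # float64 (n_pops, n_sites), NaN = undefined
    counts: np.ndarray    # int64 (n_pops, n_sites)
    delta_af: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    def pop_index(self, label: str) -> int:
        try:
            return self.populations.index(label)
        except ValueError:
            raise ValidationError(f"unknown population {label!r}") from None

    def freq_of(self, label: str) -> np.ndarray:
        return self.freq[self.pop_index(label)]

    def counts_of(self, label: str) -> np.ndarray:
        return self.counts[self.pop_index(label)]


def alt_allele_freq(vt: VariantTable, pm: PopulationMap) -> FreqTable:
    """Alternate-allele frequency per population per SNV.

    Missing genotypes are excluded from allele counts; sites with zero
    called alleles in a population are undefined (NaN) there.
    """
    pm.validate_samples(vt.samples)
    pops = pm.populations
    n_sites = vt.n_sites
    freq = np.full((len(pops), n_sites), np.nan)
    counts = np.zeros((len(pops), n_sites), dtype=np.int64)
    for p, pop in enumerate(pops):
        idx = pm.sample_indices(pop, vt.samples)
        if idx.size == 0:
            raise ValidationError(f"population {pop!r} has no samples in the table")
        g = vt.genotypes[idx]
        called = g >= 0
        n_called = 2 * called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        counts[p] = n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[p] = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    return FreqTable(vt.chrom.copy(), vt.pos.copy(), pops, freq, counts)


def delta_af(freq: FreqTable, focal: str, others: tuple[str, str]) -> np.ndarray:
    """ΔAF = |AltAF_focal − mean(AltAF_other1, AltAF_other2)| per SNV.

    NaN wherever any of the three frequencies is undefined; the result is
    stored on the FreqTable and returned.
    """
    f = freq.freq_of(focal)
    o1 = freq.freq_of(others[0])
    o2 = freq.freq_of(others[1])
    d = np.abs(f - (o1 + o2) / 2.0)
    freq.delta_af = d
    return d


def call_breed_specific(
    freq: FreqTable,
    focal: str,
    hi: float = 0.95,
    lo: float = 0.05,
    pooled: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sites where AltAF_focal > hi and every non-focal population < lo.

    Thresholds are strict inequalities.  In ``pooled`` mode the non-focal
    criterion is applied to the count-weighted pooled frequency of all
    non-focal populations instead of each one separately.

    Returns (site index array, ΔAF at those sites).  ΔAF is computed
    against the non-focal populations (their plain mean of frequencies)
    when exactly two are present; otherwise NaN is reported.
    """
    if hi <= lo:
        raise ConfigError(f"hi ({hi}) must exceed lo ({lo})")
    fi = freq.pop_index(focal)
    others = [p for p in range(len(freq.populations)) if p != fi]
    f_focal = freq.freq[fi]
    ok = f_focal > hi
    if pooled:
        alt = np.zeros(freq.n_sites)
        tot = np.zeros(freq.n_sites)
        for p in others:
            w = np.where(np.isnan(freq.freq[p]), 0.0, freq.freq[p])
            alt += w * freq.counts[p]
            tot += np.where(np.isnan(freq.freq[p]), 0, freq.counts[p])
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled_f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        ok &= pooled_f < lo
    else:
        for p in others:
            ok &= freq.freq[p] < lo
    # undefined frequencies fail the strict comparisons via NaN propagation
    idx = np.flatnonzero(ok)
    if len(others) == 2:
        d = np.abs(f_focal[idx] - (freq.freq[others[0]][idx] + freq.freq[others[1]][idx]) / 2.0)
    else:
        d = np.full(idx.shape, np.nan)
    logger.info("call_breed_specific: %d sites at hi=%g lo=%g", idx.size, hi, lo)
    return idx, d


def bin_delta_af(values: np.ndarray, step: float = 0.05) -> np.ndarray:
    """Histogram ΔAF values into bins of width ``step`` over [0, 1].

    Bin b covers [b·step, (b+1)·step) except the last, which is closed at
    1.0.  NaN (undefined) values are excluded; values outside [0, 1] raise.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValidationError("ΔAF values must lie in [0, 1]")
    n_bins = int(round(1.0 / step))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    return counts


@dataclass
class EnrichmentResult:
    """χ² test of one functional class against one ΔAF range."""

    functional_class: str
    bin_range: tuple[float, float]
    table: np.ndarray            # 2x2: rows class/other, cols in-range/outside
    chi2: float
    p_value: float
    odds_ratio: float
    skipped: bool = False        # True when a margin is zero and no test was run
    p_bonferroni: float | None = None


def _in_range(d: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """[lo, hi) membership, closed at 1.0 when hi reaches 1."""
    inr = (d >= lo) & (d < hi)
    if hi >= 1.0:
        inr |= d == 1.0
    return inr


def enrichment_chi2(
    deltas: np.ndarray,
    classes: AnnotationTable,
    bin_range: tuple[float, float],
    bonferroni: bool = False,
) -> list[EnrichmentResult]:
    """Per functional class: 2×2 χ² of class membership × ΔAF-range membership.

    Rows are {in class, not in class}, columns are {ΔAF in range, outside}.
    Pearson χ² with 1 df, no continuity correction.  SNVs with undefined
    ΔAF are excluded.  A class whose table has a zero margin is reported
    with ``skipped=True``.
    """
    lo, hi = bin_range
    d = np.asarray(deltas, dtype=float)
    labels = np.asarray(classes.classes, dtype=object)
    if labels.shape[0] != d.shape[0]:
        raise ValidationError("ΔAF vector and class labels differ in length")
    defined = ~np.isnan(d)
    d, labels = d[defined], labels[defined]
    inr = _in_range(d, lo, hi)
    results: list[EnrichmentResult] = []
    present = [c for c in FUNCTIONAL_CLASSES if c in set(labels)]
    for cls in present:
        inc = labels == cls
        a = int(np.sum(inc & inr))
        b = int(np.sum(inc & ~inr))
        c = int(np.sum(~inc & inr))
        e = int(np.sum(~inc & ~inr))
        table = np.array([[a, b], [c, e]], dtype=np.int64)
        if min(table.sum(axis=0).min(), table.sum(axis=1).min()) == 0:
            results.append(
                EnrichmentResult(cls, bin_range, table, np.nan, np.nan, np.nan, skipped=True)
            )
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * e) / (b * c) if b * c > 0 else np.inf
        results.append(EnrichmentResult(cls, bin_range, table, float(chi2), float(p), float(odds)))
    if bonferroni:
        m = sum(1 for r in results if not r.skipped)
        for r in results:
            if not r.skipped:
                r.p_bonferroni = min(1.0, r.p_value * m)
    return results


def joint_bin_matrix(
    freq: FreqTable, focal: str, other: str, step: float = 0.05
) -> np.ndarray:
    """Joint 20×20 SNV count matrix of focal vs comparison frequency bins."""
    f = freq.freq_of(focal)
    o = freq.freq_of(other)
    ok = ~(np.isnan(f) | np.isnan(o))
    n_bins = int(round(1.0 / step))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h, _, _ = np.histogram2d(f[ok], o[ok], bins=(edges, edges))
    return h.astype(np.int64)
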