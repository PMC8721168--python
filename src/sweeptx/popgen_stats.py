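"""Windowed nucleotide diversity and FST, the scan's two selection statistics.

Per-site nucleotide diversity uses the unbiased pairwise estimator
``pi = 2 * n_ref * n_alt / (n * (n - 1))`` over the ``n`` non-missing
alleles sampled in a population.  Window diversity is the sum of site pi
over the window divided by the full window span in bp.

FST follows the Weir & Cockerham (1984) two-population ANOVA: each site
contributes among-population (a), among-individual (b) and
within-individual (c) variance components, and a window's FST is the
ratio of sums ``sum(a) / sum(a + b + c)`` over its usable sites.  A
Hudson-style estimator is available as an alternative.  Missing genotypes
are excluded site-wise per population (pairwise deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix
from .errors import ConfigError

WINDOW_SIZE = 40_000
WINDOW_STEP = 20_000


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int   # 0-based half-open
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: dict[str, int], size: int = WINDOW_SIZE,
                 step: int = WINDOW_STEP) -> list[Window]:
    """Sliding windows of ``size`` bp advancing by ``step`` bp.

    Windows start at multiples of the step while the start lies inside the
    chromosome; the last windows are truncated at the chromosome end.
    """
    if not (size >= step > 0):
        raise ConfigError("require size >= step > 0")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ConfigError(f"non-positive length for {chrom}")
        start = 0
        while start < length:
            windows.append(Window(chrom, start, min(start + size, length)))
            start += step
    return windows


@dataclass
class SiteCounts:
    """Per-site allele and genotype counts for one population."""

    n_ind: np.ndarray   # non-missing diploid individuals
    n_alt: np.ndarray   # alternate alleles among them
    n_het: np.ndarray   # observed heterozygotes

    @property
    def n_alleles(self) -> np.ndarray:
        return 2 * self.n_ind

    @property
    def n_ref(self) -> np.ndarray:
        return self.n_alleles - self.n_alt


def pop_site_counts(gm: GenotypeMatrix, pop: str) -> SiteCounts:
    d = gm.dosage[gm.sample_indices(pop)]
    present = d != MISSING
    return SiteCounts(
        n_ind=present.sum(axis=0),
        n_alt=np.where(present, d, 0).sum(axis=0),
        n_het=(d == 1).sum(axis=0),
    )


def site_pi(n_ref, n_alt):
    """Mean pairwise difference among sampled alleles at one site.

    Sites with fewer than two sampled alleles yield NaN (skipped by the
    window aggregation).
    """
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    n = n_ref + n_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * n_ref * n_alt / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def _window_slices(gm: GenotypeMatrix, windows: list[Window]) -> list[slice]:
    """Per-window slice into the site arrays (positions are 1-based)."""
    out: list[slice] = []
    chrom_offsets: dict[str, tuple[int, np.ndarray]] = {}
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        chrom_offsets[c] = (int(idx[0]) if idx.size else 0, gm.pos[idx])
    for w in windows:
        if w.chrom not in chrom_offsets:
            out.append(slice(0, 0))
            continue
        off, pos = chrom_offsets[w.chrom]
        lo = int(np.searchsorted(pos, w.start + 1, side="left"))
        hi = int(np.searchsorted(pos, w.end, side="right"))
        out.append(slice(off + lo, off + hi))
    return out


def window_pi(gm: GenotypeMatrix, pop: str, windows: list[Window]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window diversity per bp and the count of usable SNPs.

    Windows with zero usable SNPs get pi = 0 (their n_snps marks them).
    """
    sc = pop_site_counts(gm, pop)
    pi = site_pi(sc.n_ref, sc.n_alt)
    usable = ~np.isnan(pi)
    pi_filled = np.where(usable, pi, 0.0)
    cum_pi = np.concatenate([[0.0], np.cumsum(pi_filled)])
    cum_n = np.concatenate([[0], np.cumsum(usable.astype(np.int64))])
    out_pi = np.empty(len(windows))
    out_n = np.empty(len(windows), dtype=np.int64)
    for i, (w, sl) in enumerate(zip(windows, _window_slices(gm, windows))):
        out_pi[i] = (cum_pi[sl.stop] - cum_pi[sl.start]) / w.span
        out_n[i] = cum_n[sl.stop] - cum_n[sl.start]
    return out_pi, out_n


def site_fst_components(a_counts: SiteCounts, b_counts: SiteCounts
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) variance components for two populations.

    Returns ``(a, b, c, usable)`` arrays; ``a`` is the among-population
    component, ``b`` among-individual within population, ``c``
    within-individual.  A site is usable when both populations have at
    least one non-missing diploid and the mean sample size exceeds one.
    """
    n1 = a_counts.n_ind.astype(float)
    n2 = b_counts.n_ind.astype(float)
    usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = a_counts.n_alt / (2.0 * n1)
        p2 = b_counts.n_alt / (2.0 * n2)
        h1 = a_counts.n_het / n1
        h2 = b_counts.n_het / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    zero = np.zeros_like(n1)
    return (np.where(usable, a, zero), np.where(usable, b, zero),
            np.where(usable, c, zero), usable)


def site_fst_hudson(a_counts: SiteCounts, b_counts: SiteCounts
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hudson-style numerator/denominator per site (alternative estimator)."""
    m1 = a_counts.n_alleles.astype(float)
    m2 = b_counts.n_alleles.astype(float)
    usable = (m1 >= 2) & (m2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = a_counts.n_alt / m1
        p2 = b_counts.n_alt / m2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (m1 - 1.0)
               - p2 * (1 - p2) / (m2 - 1.0))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    zero = np.zeros_like(m1)
    return np.where(usable, num, zero), np.where(usable, den, zero), usable


def window_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str, windows: list[Window],
               estimator: str = "wc") -> tuple[np.ndarray, np.ndarray]:
    """Windowed FST as a ratio of sums over usable sites.

    Returns ``(fst, defined)``: windows whose denominator sums to zero are
    NaN and marked undefined.  Negative values are retained (the estimator
    can dip below zero under no differentiation).
    """
    ca = pop_site_counts(gm, pop_a)
    cb = pop_site_counts(gm, pop_b)
    if estimator == "wc":
        a, b, c, usable = site_fst_components(ca, cb)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den, usable = site_fst_hudson(ca, cb)
    else:
        raise ConfigError(f"unknown FST estimator {estimator!r}")
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    cum_num = np.concatenate([[0.0], np.cumsum(num)])
    cum_den = np.concatenate([[0.0], np.cumsum(den)])
    fst = np.empty(len(windows))
    defined = np.empty(len(windows), dtype=bool)
    for i, sl in enumerate(_window_slices(gm, windows)):
        d = cum_den[sl.stop] - cum_den[sl.start]
        defined[i] = d > 0
        fst[i] = (cum_num[sl.stop] - cum_num[sl.start]) / d if d > 0 else np.nan
    return fst, defined


def window_scan(gm: GenotypeMatrix, chrom_lengths: dict[str, int],
                size: int = WINDOW_SIZE, step: int = WINDOW_STEP,
                pairs: list[tuple[str, str]] | None = None,
                estimator: str = "wc") -> pd.DataFrame:
    """Window-level table: per-population diversity and pairwise FST.

    Columns: chrom, start, end (BED-compatible, 0-based half-open),
    n_snps, ``pi_<pop>``, ``n_snps_<pop>``, ``fst_<a>_<b>``.
    """
    windows = make_windows(chrom_lengths, size, step)
    pops = gm.populations
    if pairs is None:
        pairs = [(pops[i], pops[j]) for i in range(len(pops))
                 for j in range(i + 1, len(pops))]
    df = pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
    })
    n_any = None
    for pop in pops:
        pi, n = window_pi(gm, pop, windows)
        df[f"pi_{pop}"] = pi
        df[f"n_snps_{pop}"] = n
        n_any = n if n_any is None else np.maximum(n_any, n)
    df.insert(3, "n_snps", n_any)
    for a, b in pairs:
        fst, defined = window_fst(gm, a, b, windows, estimator=estimator)
        df[f"fst_{a}_{b}"] = np.where(defined, fst, np.nan)
    return df
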