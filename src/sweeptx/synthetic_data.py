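"""Synthetic genotype, annotation, and expression data with known truth.

The generator emulates the statistical signature the downstream scan looks
for rather than simulating genealogies:

* Per-population allele frequencies follow the Balding-Nichols model
  around a shared ancestral frequency, so background differentiation is
  analytically controlled by ``F``.
* A selective sweep is a deterministic transformation of the selected
  population's frequencies inside a region: expected heterozygosity is
  multiplied by ``diversity_reduction`` (frequency moved toward the nearer
  boundary) and then displaced further toward that boundary by
  ``differentiation_boost``, producing locally reduced diversity and
  elevated differentiation with exactly known truth windows.
* RNA-seq counts are negative-binomial (gamma-Poisson) around log-normal
  gene means with per-sample depth multipliers; DE genes receive a
  multiplicative fold change in group 2, half up and half down.

All randomness flows from one master seed through named substreams, so
each generator is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import core_io
from .core_io import CountsTable, GeneModel, GenotypeMatrix
from .errors import ConfigError

_STREAMS = {"genotypes": 0, "counts": 1, "annotation": 2}


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int                     # 0-based half-open
    end: int
    selected_pop: str
    diversity_reduction: float     # multiplies expected heterozygosity, in (0, 1]
    differentiation_boost: float   # extra push toward the nearer allele-frequency boundary


@dataclass
class RnaSeqConfig:
    n_genes: int = 2000
    n_per_group: int = 4
    mean_log_expression: float = 4.0   # natural-log mean of gene base means
    sd_log_expression: float = 1.0
    dispersion: float = 0.1            # NB dispersion alpha (Var = mu + alpha mu^2)
    n_de: int = 200
    lfc_de: float = 2.0                # |log2 fold change| of planted DE genes


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic genome + transcriptome."""

    seed: int = 0
    n_pops: int = 2
    samples_per_pop: int = 8
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    n_snps: int = 100_000
    fst_background: float | list[float] = 0.05
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    rnaseq: RnaSeqConfig = field(default_factory=RnaSeqConfig)
    mean_depth: float = 120.0
    depth_overdispersion: float = 0.3
    frac_low_qual: float = 0.0
    missing_rate: float = 0.0
    window_size: int = 40_000
    window_step: int = 20_000
    pop_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.pop_names is None:
            self.pop_names = [f"pop{i + 1}" for i in range(self.n_pops)]
        if len(self.pop_names) != self.n_pops:
            raise ConfigError("pop_names length must equal n_pops")
        for p in (self.frac_low_qual, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        for f in self.fst_values():
            if not 0.0 <= f < 1.0:
                raise ConfigError("fst_background must lie in [0, 1)")
        for r in self.sweep_regions:
            if r.chrom not in self.chrom_lengths:
                raise ConfigError(f"sweep region on unknown chromosome {r.chrom!r}")
            if not (0 <= r.start < r.end <= self.chrom_lengths[r.chrom]):
                raise ConfigError(f"sweep region [{r.start},{r.end}) outside {r.chrom}")
            if not 0.0 < r.diversity_reduction <= 1.0:
                raise ConfigError("diversity_reduction must lie in (0, 1]")
            if r.selected_pop not in self.pop_names:
                raise ConfigError(f"unknown selected_pop {r.selected_pop!r}")
        if self.rnaseq.n_de > self.rnaseq.n_genes:
            raise ConfigError("n_de cannot exceed n_genes")

    def fst_values(self) -> list[float]:
        if isinstance(self.fst_background, (int, float)):
            return [float(self.fst_background)] * self.n_pops
        return [float(f) for f in self.fst_background]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{p}_{i + 1}" for p in self.pop_names for i in range(self.samples_per_pop)]

    @property
    def pop_labels(self) -> dict[str, str]:
        return {f"{p}_{i + 1}": p for p in self.pop_names
                for i in range(self.samples_per_pop)}


@dataclass
class TruthSet:
    """Ground truth recorded by the generators for parameter-recovery tests."""

    sweep_regions: list[SweepRegion] = field(default_factory=list)
    sweep_windows: list[tuple[str, int, int]] = field(default_factory=list)
    pop_allele_freqs: dict[str, np.ndarray] | None = None
    de_genes: dict[str, float] = field(default_factory=dict)   # gene -> true log2FC
    size_factors: dict[str, float] = field(default_factory=dict)
    sweep_interior_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sweep_regions": [vars(r) for r in self.sweep_regions],
            "sweep_windows": [list(w) for w in self.sweep_windows],
            "de_genes": self.de_genes,
            "size_factors": self.size_factors,
            "sweep_interior_genes": self.sweep_interior_genes,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            sweep_regions=[SweepRegion(**r) for r in d["sweep_regions"]],
            sweep_windows=[tuple(w) for w in d["sweep_windows"]],
            de_genes=d["de_genes"],
            size_factors=d["size_factors"],
            sweep_interior_genes=d["sweep_interior_genes"],
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _sweep_transform(p: np.ndarray, reduction: float, boost: float) -> np.ndarray:
    """Move frequencies toward the nearer boundary.

    First solve p'(1-p') = reduction * p(1-p) on the same side of 1/2
    (heterozygosity scaling), then move the remaining distance to the
    boundary by fraction ``boost``.
    """
    c = reduction * p * (1.0 - p)
    root = np.sqrt(np.maximum(0.0, 1.0 - 4.0 * c))
    lower = (1.0 - root) / 2.0
    upper = (1.0 + root) / 2.0
    q = np.where(p <= 0.5, lower, upper)
    return np.where(q <= 0.5, q * (1.0 - boost), q + boost * (1.0 - q))


def _positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions on a chromosome."""
    if n > length:
        raise ConfigError("more SNPs requested than base pairs available")
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_genotypes(cfg: SimConfig,
                       out_dir: str | Path | None = None) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate diploid genotypes under Balding-Nichols with optional sweeps.

    Returns the matrix plus a TruthSet holding per-population frequencies
    and the windows fully inside each sweep region.  If ``out_dir`` is
    given, writes ``genotypes.vcf``, ``samples.tsv`` and ``truth.json``.
    """
    from .popgen_stats import make_windows

    rng = substream(cfg.seed, "genotypes")

    chroms_order = list(cfg.chrom_lengths)
    total_len = sum(cfg.chrom_lengths.values())
    # allocate SNPs to chromosomes proportionally to length, remainder first
    alloc = {c: int(cfg.n_snps * cfg.chrom_lengths[c] / total_len) for c in chroms_order}
    for c in chroms_order:
        if sum(alloc.values()) >= cfg.n_snps:
            break
        alloc[c] += 1

    chrom_arr: list[str] = []
    pos_arr: list[np.ndarray] = []
    for c in chroms_order:
        p = _positions(rng, cfg.chrom_lengths[c], alloc[c])
        pos_arr.append(p)
        chrom_arr.extend([c] * alloc[c])
    chrom = np.asarray(chrom_arr, dtype=object)
    pos = np.concatenate(pos_arr) if pos_arr else np.empty(0, dtype=np.int64)
    m = pos.size

    # ancestral frequencies: Beta(0.8, 0.8) rescaled to (0.05, 0.95)
    anc = 0.05 + 0.9 * rng.beta(0.8, 0.8, size=m)

    fsts = cfg.fst_values()
    pop_freqs: dict[str, np.ndarray] = {}
    for pop, f in zip(cfg.pop_names, fsts):
        if f == 0.0:
            pf = anc.copy()
        else:
            a = anc * (1.0 - f) / f
            b = (1.0 - anc) * (1.0 - f) / f
            pf = rng.beta(a, b, size=m)
        pop_freqs[pop] = pf

    for r in cfg.sweep_regions:
        in_region = (chrom == r.chrom) & (pos - 1 >= r.start) & (pos - 1 < r.end)
        pf = pop_freqs[r.selected_pop]
        pf[in_region] = _sweep_transform(pf[in_region], r.diversity_reduction,
                                         r.differentiation_boost)

    n_samples = cfg.n_pops * cfg.samples_per_pop
    dosage = np.empty((n_samples, m), dtype=np.int8)
    row = 0
    for pop in cfg.pop_names:
        pf = pop_freqs[pop]
        dosage[row:row + cfg.samples_per_pop] = rng.binomial(
            2, pf[None, :], size=(cfg.samples_per_pop, m)).astype(np.int8)
        row += cfg.samples_per_pop
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = core_io.MISSING

    # QUAL: a configured fraction falls below the Phred-20 filter boundary
    low = rng.random(m) < cfg.frac_low_qual
    qual = np.where(low, 2.0 + 17.9 * rng.random(m), 20.0 + 40.0 * rng.random(m))
    # site depth: gamma-Poisson around mean_depth
    if cfg.depth_overdispersion > 0:
        lam = rng.gamma(1.0 / cfg.depth_overdispersion,
                        cfg.mean_depth * cfg.depth_overdispersion, size=m)
    else:
        lam = np.full(m, cfg.mean_depth)
    depth = rng.poisson(lam).astype(np.int64)

    ref_alt = np.array(["A", "C", "G", "T"], dtype=object)
    ref = ref_alt[rng.integers(0, 4, size=m)]
    shift = rng.integers(1, 4, size=m)
    alt = ref_alt[(np.searchsorted(ref_alt, ref) + shift) % 4]

    gm = GenotypeMatrix(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=np.round(qual, 2),
        site_depth=depth, dosage=dosage,
        sample_ids=cfg.sample_ids, pop_labels=cfg.pop_labels,
        depth_source="INFO/DP",
    )

    windows = make_windows(cfg.chrom_lengths, cfg.window_size, cfg.window_step)
    sweep_windows = [
        (w.chrom, w.start, w.end)
        for w in windows
        for r in cfg.sweep_regions
        if w.chrom == r.chrom and w.start >= r.start and w.end <= r.end
    ]
    truth = TruthSet(sweep_regions=list(cfg.sweep_regions),
                     sweep_windows=sweep_windows,
                     pop_allele_freqs=pop_freqs)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        core_io.write_vcf(gm, out / "genotypes.vcf", contig_lengths=cfg.chrom_lengths)
        core_io.write_sample_map(cfg.pop_labels, out / "samples.tsv")
        truth.to_json(out / "truth_genotypes.json")
    return gm, truth


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(cfg: SimConfig,
                        out_dir: str | Path | None = None) -> tuple[list[GeneModel], TruthSet]:
    """Tile non-overlapping genes over the chromosomes.

    Every sweep region receives at least one gene strictly inside it and
    one gene spanning its start boundary, so the window-to-gene mapping is
    exercised on both containment and partial overlap.
    """
    rng = substream(cfg.seed, "annotation")
    n_genes = cfg.rnaseq.n_genes
    total_len = sum(cfg.chrom_lengths.values())
    chroms = list(cfg.chrom_lengths)
    alloc = {c: max(1, int(round(n_genes * cfg.chrom_lengths[c] / total_len))) for c in chroms}
    # trim/pad to hit the exact count
    while sum(alloc.values()) > n_genes:
        alloc[max(alloc, key=alloc.get)] -= 1
    while sum(alloc.values()) < n_genes:
        alloc[min(alloc, key=alloc.get)] += 1

    slots: list[tuple[str, float, float]] = []   # (chrom, slot_start, slot_end)
    for c in chroms:
        width = cfg.chrom_lengths[c] / alloc[c]
        if width < 200:
            raise ConfigError(f"cannot fit {alloc[c]} genes on {c}")
        for k in range(alloc[c]):
            slots.append((c, k * width, (k + 1) * width))

    intervals: list[list] = []
    for c, s0, s1 in slots:
        w = s1 - s0
        start = int(s0 + 0.15 * w)
        end = int(s0 + 0.85 * w)
        intervals.append([c, start, end])

    interior_idx: set[int] = set()

    def slot_index(chrom: str, coord: float) -> int:
        width = cfg.chrom_lengths[chrom] / alloc[chrom]
        k = min(int(coord // width), alloc[chrom] - 1)
        offset = sum(alloc[c] for c in chroms[:chroms.index(chrom)])
        return offset + k

    for r in cfg.sweep_regions:
        width = cfg.chrom_lengths[r.chrom] / alloc[r.chrom]
        if r.end - r.start < 2.5 * width:
            raise ConfigError(
                f"sweep region [{r.start},{r.end}) too narrow for the gene grid on {r.chrom}")
        # one gene strictly inside the region, in the slot holding its centre
        i = slot_index(r.chrom, (r.start + r.end) / 2)
        c, s0, s1 = slots[i]
        lo = max(s0, r.start) + 0.05 * width
        hi = min(s1, r.end) - 0.05 * width
        intervals[i] = [c, int(lo), int(hi)]
        interior_idx.add(i)
        # one gene spanning the region's start boundary; if the boundary sits
        # at a slot edge, use the previous slot and let its gene reach across
        j = slot_index(r.chrom, r.start)
        c, s0, s1 = slots[j]
        chrom_first = sum(alloc[cc] for cc in chroms[:chroms.index(r.chrom)])
        if r.start - s0 < 0.2 * width and j - 1 >= chrom_first:
            j = j - 1
            c, s0, s1 = slots[j]
        if j != i and r.start > 0:
            next_start = intervals[j + 1][1] if j + 1 < len(intervals) \
                and intervals[j + 1][0] == c else cfg.chrom_lengths[c]
            lo = max(s0 + 1, r.start - 0.3 * width)
            hi = min(r.start + 0.3 * width, next_start - 1)
            if lo < r.start < hi:
                intervals[j] = [c, int(lo), int(hi)]

    models: list[GeneModel] = []
    digits = max(5, len(str(n_genes)))
    interior_ids: list[str] = []
    for i, (c, start, end) in enumerate(intervals):
        gid = f"g{i + 1:0{digits}d}"
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_ex - 2, replace=False)) \
            if end - start > 2 * n_ex else np.empty(0, dtype=int)
        bounds = [start, *cuts.tolist(), end]
        exons = tuple((bounds[k], bounds[k + 1]) for k in range(0, len(bounds) - 1, 2))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gid, c, start, end, strand, exons))
        if i in interior_idx:
            interior_ids.append(gid)

    truth = TruthSet(sweep_regions=list(cfg.sweep_regions),
                     sweep_interior_genes=interior_ids)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        core_io.write_gff(models, out / "genes.gff3", cfg.chrom_lengths)
        truth.to_json(out / "truth_annotation.json")
    return models, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(cfg: SimConfig, genes: list[GeneModel] | None = None,
                    sweep_interior_genes: list[str] | None = None,
                    out_dir: str | Path | None = None) -> tuple[CountsTable, TruthSet]:
    """Simulate an NB count matrix with planted DE genes.

    If ``sweep_interior_genes`` is given, those genes are planted as DE
    first (so the genome-transcriptome intersection has known truth);
    remaining DE slots are filled at random.  Half of the DE genes go up,
    half down.
    """
    rc = cfg.rnaseq
    if rc.n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2")
    rng = substream(cfg.seed, "counts")

    if genes is not None:
        gene_ids = [g.gene_id for g in genes]
        if len(gene_ids) != rc.n_genes:
            raise ConfigError("annotation gene count does not match rnaseq.n_genes")
    else:
        digits = max(5, len(str(rc.n_genes)))
        gene_ids = [f"g{i + 1:0{digits}d}" for i in range(rc.n_genes)]

    n = rc.n_per_group
    sample_ids = [f"grp1_s{i + 1}" for i in range(n)] + [f"grp2_s{i + 1}" for i in range(n)]
    group_labels = {s: ("group1" if i < n else "group2") for i, s in enumerate(sample_ids)}

    base = rng.lognormal(rc.mean_log_expression, rc.sd_log_expression, size=rc.n_genes)

    de_idx: list[int] = []
    if sweep_interior_genes:
        pos = {g: i for i, g in enumerate(gene_ids)}
        de_idx = [pos[g] for g in sweep_interior_genes if g in pos][: rc.n_de]
    remaining = rc.n_de - len(de_idx)
    if remaining > 0:
        pool = np.setdiff1d(np.arange(rc.n_genes), np.asarray(de_idx, dtype=int))
        de_idx.extend(rng.choice(pool, size=remaining, replace=False).tolist())
    signs = np.where(np.arange(len(de_idx)) % 2 == 0, 1.0, -1.0)

    lfc = np.zeros(rc.n_genes)
    for k, gi in enumerate(de_idx):
        lfc[gi] = signs[k] * rc.lfc_de

    sf = np.exp(rng.normal(0.0, 0.15, size=2 * n))
    sf /= np.exp(np.mean(np.log(sf)))

    mu = base[:, None] * sf[None, :]
    mu[:, n:] *= (2.0 ** lfc)[:, None]
    if rc.dispersion > 1e-8:
        shape = 1.0 / rc.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    mapped = np.ceil(counts.sum(axis=0) / 0.95).astype(np.int64)
    ct = CountsTable(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts,
                     group_labels=group_labels, mapped_reads=mapped)
    truth = TruthSet(
        de_genes={gene_ids[gi]: float(lfc[gi]) for gi in de_idx},
        size_factors={s: float(f) for s, f in zip(sample_ids, sf)},
        sweep_interior_genes=list(sweep_interior_genes or []),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        core_io.write_counts(ct, out / "counts.tsv")
        core_io.write_sample_map(group_labels, out / "groups.tsv", ("sample", "group"))
        core_io.write_sample_map({s: str(int(v)) for s, v in zip(sample_ids, mapped)},
                                 out / "mapped_reads.tsv", ("sample", "mapped_reads"))
        truth.to_json(out / "truth_counts.json")
    return ct, truth
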