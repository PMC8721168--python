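"""End-to-end orchestration: simulate -> filter -> scan -> sweep ->
structure -> express -> integrate, from one validated config.

Each stage writes its outputs plus a JSON provenance block (stage
parameters, SHA-256 of inputs, seed, package version) into the run
manifest.  Reruns with an identical config and seed reproduce identical
bytes: every random draw descends from the master seed and no output
carries a timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, core_io, expression, pop_structure, popgen_stats, sweep_scan
from .config import PipelineConfig, sim_config_from
from .errors import SweeptxError
from .integration import integrate
from .synthetic_data import TruthSet, simulate_annotation, simulate_counts, simulate_genotypes
from .variant_filter import apply_filters

log = logging.getLogger("sweeptx")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Mutable run state shared between stages."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": []}
        self.gm = None
        self.gm_filtered = None
        self.genes = None
        self.counts = None
        self.window_table = None
        self.sweep_calls: dict[str, sweep_scan.SweepCall] = {}
        self.deg_called: pd.DataFrame | None = None
        self.truth = TruthSet()

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.manifest["stages"].append({
            "stage": stage,
            "params": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        })
        log.info("stage %s: %d output(s)", stage, len(outputs))

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(run: PipelineRun) -> None:
    cfg = run.cfg
    sim = sim_config_from(cfg)
    data_dir = run.outdir / "data"
    run.gm, truth_g = simulate_genotypes(sim, out_dir=data_dir)
    run.genes, truth_a = simulate_annotation(sim, out_dir=data_dir)
    run.counts, truth_c = simulate_counts(
        sim, genes=run.genes, sweep_interior_genes=truth_a.sweep_interior_genes,
        out_dir=data_dir)
    run.truth = TruthSet(
        sweep_regions=truth_g.sweep_regions,
        sweep_windows=truth_g.sweep_windows,
        pop_allele_freqs=truth_g.pop_allele_freqs,
        de_genes=truth_c.de_genes,
        size_factors=truth_c.size_factors,
        sweep_interior_genes=truth_a.sweep_interior_genes,
    )
    run.truth.to_json(data_dir / "truth.json")
    outputs = [data_dir / n for n in
               ("genotypes.vcf", "samples.tsv", "genes.gff3", "counts.tsv",
                "groups.tsv", "mapped_reads.tsv", "truth.json")]
    run.record("simulate", {"n_snps": sim.n_snps, "n_pops": sim.n_pops,
                            "samples_per_pop": sim.samples_per_pop,
                            "fst_background": cfg.simulate.fst_background,
                            "n_sweeps": len(sim.sweep_regions)}, outputs)


def stage_load(run: PipelineRun) -> None:
    inp = run.cfg.inputs
    run.gm = core_io.read_vcf(inp.vcf, inp.sample_map)
    run.genes = core_io.read_gff(inp.gff)
    run.counts = core_io.read_counts(inp.counts, inp.group_map, inp.mapped_reads)
    run.record("load", {"vcf": inp.vcf, "gff": inp.gff, "counts": inp.counts}, [])


def stage_filter(run: PipelineRun) -> None:
    p = run.cfg.params
    run.gm_filtered, report = apply_filters(
        run.gm, min_qual=p.min_qual, min_spacing_bp=p.min_spacing,
        low_mult=p.depth_low_mult, high_mult=p.depth_high_mult)
    vcf_path = run.outdir / "filtered.vcf"
    core_io.write_vcf(run.gm_filtered, vcf_path, contig_lengths=_contig_lengths(run))
    rep_path = run.outdir / "filter_report.json"
    with open(rep_path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    log.info("filter: %d/%d sites pass (qual %d, spacing %d, depth %d fail)",
             report.n_pass, report.n_input, report.n_fail_qual,
             report.n_fail_spacing, report.n_fail_depth)
    run.record("filter", {"min_qual": p.min_qual, "min_spacing": p.min_spacing,
                          "depth_low_mult": p.depth_low_mult,
                          "depth_high_mult": p.depth_high_mult},
               [vcf_path, rep_path])


def _contig_lengths(run: PipelineRun) -> dict[str, int]:
    if run.cfg.simulate is not None:
        return dict(run.cfg.simulate.chrom_lengths)
    gm = run.gm
    lengths: dict[str, int] = {}
    for c, p in zip(gm.chrom, gm.pos):
        lengths[c] = max(lengths.get(c, 0), int(p))
    return lengths


def stage_scan(run: PipelineRun) -> None:
    p = run.cfg.params
    gm = run.gm_filtered if run.gm_filtered is not None else run.gm
    pairs = [(c.selected, c.control) for c in run.cfg.comparisons] or None
    run.window_table = popgen_stats.window_scan(
        gm, _contig_lengths(run), size=p.window_size, step=p.window_step,
        pairs=pairs, estimator=p.fst_estimator)
    path = run.outdir / "windows.tsv"
    run.window_table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    run.record("scan-stats", {"window_size": p.window_size, "window_step": p.window_step,
                              "estimator": p.fst_estimator}, [path])


def stage_sweep(run: PipelineRun) -> None:
    p = run.cfg.params
    outputs: list[Path] = []
    comparisons = run.cfg.comparisons or _default_comparisons(run)
    for comp in comparisons:
        sel, ctl = comp.selected, comp.control
        call = sweep_scan.joint_outliers(run.window_table, sel, ctl,
                                         top_fraction=p.top_fraction,
                                         min_snps=p.min_snps_per_window)
        call.genes = sweep_scan.windows_to_genes(call.outlier_windows, run.genes)
        run.sweep_calls[f"{sel}_vs_{ctl}"] = call
        tag = f"{sel}_vs_{ctl}"
        bed = run.outdir / f"outliers_{tag}.bed"
        out_w = call.outlier_windows
        with open(bed, "w", encoding="utf-8") as fh:
            for _, row in out_w.iterrows():
                fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                         f"{row[_fst_col(out_w, sel, ctl)]:.6g}\t{row['log2_ratio']:.6g}\n")
        genes_tsv = run.outdir / f"sweep_genes_{tag}.tsv"
        with open(genes_tsv, "w", encoding="utf-8") as fh:
            fh.write("gene_id\n")
            for g in sorted(call.genes):
                fh.write(g + "\n")
        log.info("sweep %s: %d outliers of %d rankable (fst>=%.4g, ratio>=%.4g), %d genes",
                 tag, call.n_outliers, call.n_rankable, call.fst_threshold,
                 call.ratio_threshold, len(call.genes))
        outputs += [bed, genes_tsv]
    summary = {
        tag: {"n_outliers": c.n_outliers, "n_rankable": c.n_rankable,
              "fst_threshold": c.fst_threshold,
              "ratio_threshold": None if not np.isfinite(c.ratio_threshold)
              else c.ratio_threshold,
              "n_genes": len(c.genes)}
        for tag, c in run.sweep_calls.items()
    }
    if len(run.sweep_calls) >= 2:
        tags = list(run.sweep_calls)
        summary["venn_sweep_genes"] = sweep_scan.overlap_sets(
            *[run.sweep_calls[t].genes for t in tags[:3]], names=tags[:3])
    spath = run.outdir / "sweep_summary.json"
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    outputs.append(spath)
    run.record("sweep", {"top_fraction": p.top_fraction,
                         "min_snps": p.min_snps_per_window}, outputs)


def _fst_col(df: pd.DataFrame, a: str, b: str) -> str:
    return f"fst_{a}_{b}" if f"fst_{a}_{b}" in df.columns else f"fst_{b}_{a}"


def _default_comparisons(run: PipelineRun):
    from .config import ComparisonConfig
    pops = run.gm.populations
    return [ComparisonConfig(selected=pops[i], control=pops[j])
            for i in range(len(pops)) for j in range(len(pops)) if i != j][:2]


def stage_structure(run: PipelineRun) -> None:
    p = run.cfg.params
    gm = run.gm_filtered if run.gm_filtered is not None else run.gm
    tree = pop_structure.bootstrap_support(gm, n_boot=p.n_boot, seed=run.cfg.seed,
                                           metric=p.distance_metric)
    nwk = run.outdir / "nj_tree.nwk"
    nwk.write_text(tree.newick() + "\n", encoding="utf-8")
    res = pop_structure.pca(gm, k=p.pca_components)
    scores = pd.DataFrame(res.scores, index=res.sample_ids,
                          columns=[f"PC{i + 1}" for i in range(res.scores.shape[1])])
    scores.insert(0, "population", [gm.pop_labels[s] for s in res.sample_ids])
    pca_path = run.outdir / "pca_scores.tsv"
    with open(pca_path, "w", encoding="utf-8") as fh:
        fh.write("# variance_explained\t"
                 + "\t".join(f"{v:.6g}" for v in res.variance_explained) + "\n")
        scores.to_csv(fh, sep="\t", index_label="sample")
    run.record("structure", {"n_boot": p.n_boot, "metric": p.distance_metric,
                             "pca_components": p.pca_components}, [nwk, pca_path])


def stage_express(run: PipelineRun) -> None:
    p = run.cfg.params
    fpkm_df = expression.fpkm(run.counts, run.genes)
    fpkm_path = run.outdir / "fpkm.tsv"
    fpkm_df.to_csv(fpkm_path, sep="\t", float_format="%.6g")
    table = expression.deg_test(run.counts)
    called = expression.call_degs(table, fc_hi=p.fc_hi, fc_lo=p.fc_lo,
                                  alpha=p.alpha, use_adjusted=p.use_adjusted_p)
    run.deg_called = called
    deg_path = run.outdir / "deg_table.tsv"
    called.to_csv(deg_path, sep="\t", float_format="%.6g")
    up, down = expression.deg_gene_sets(called)
    lists_path = run.outdir / "deg_lists.json"
    with open(lists_path, "w", encoding="utf-8") as fh:
        json.dump({"up": sorted(up), "down": sorted(down)}, fh, indent=1)
    log.info("express: %d up, %d down of %d genes", len(up), len(down), len(called))
    run.record("express", {"fc_hi": p.fc_hi, "fc_lo": p.fc_lo, "alpha": p.alpha,
                           "use_adjusted_p": p.use_adjusted_p},
               [fpkm_path, deg_path, lists_path])


def stage_integrate(run: PipelineRun) -> None:
    p = run.cfg.params
    outputs: list[Path] = []
    annotation_ids = {g.gene_id for g in run.genes}
    reports = {}
    for tag, call in run.sweep_calls.items():
        rep = integrate(call, [run.deg_called], shared_deg_rule=p.shared_deg_rule,
                        comparison=tag, annotation_ids=annotation_ids)
        reports[tag] = rep
        ev_path = run.outdir / f"candidates_{tag}.tsv"
        rep.evidence.to_csv(ev_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(ev_path)
        log.info("integrate %s: %d candidates (%d sweep genes x %d shared DEGs)",
                 tag, len(rep.candidates), len(rep.sweep_genes), len(rep.deg_genes))
    venn_path = run.outdir / "integration_venn.json"
    with open(venn_path, "w", encoding="utf-8") as fh:
        json.dump({t: r.venn for t, r in reports.items()}, fh, indent=1, sort_keys=True)
    outputs.append(venn_path)
    run.record("integrate", {"shared_deg_rule": p.shared_deg_rule}, outputs)


_STAGE_ORDER = ["simulate", "filter", "scan-stats", "sweep", "structure",
                "express", "integrate"]


def run_pipeline(cfg: PipelineConfig) -> PipelineRun:
    """Run every stage in dependency order; any failure names its stage."""
    run = PipelineRun(cfg)
    stages = [
        ("simulate", stage_simulate) if cfg.simulate is not None else ("load", stage_load),
        ("filter", stage_filter),
        ("scan-stats", stage_scan),
        ("sweep", stage_sweep),
        ("structure", stage_structure),
        ("express", stage_express),
        ("integrate", stage_integrate),
    ]
    for name, fn in stages:
        try:
            fn(run)
        except SweeptxError as exc:
            raise SweeptxError(f"stage {name!r} failed: {exc}") from exc
    run.write_manifest()
    return run
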