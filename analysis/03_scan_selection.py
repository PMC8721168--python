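#!/usr/bin/env python
"""Windowed diversity/FST scan and joint top-5% sweep calling per comparison.

For each (selected, control) pair: writes the window table, outlier BED and
sweep gene lists, then scores recall of the planted truth windows and
reports the overlap between the two meat-line gene sets.
"""

import json
from pathlib import Path

from sweeptx import core_io, popgen_stats as ps, sweep_scan as sw
from sweeptx.config import validate_config
from sweeptx.synthetic_data import TruthSet

HERE = Path(__file__).parent


def main() -> None:
    cfg = validate_config(HERE / "config.yaml")
    out = Path(cfg.outdir)
    gm = core_io.read_vcf(out / "filtered.vcf", out / "data" / "samples.tsv")
    genes = core_io.read_gff(out / "data" / "genes.gff3")
    truth = TruthSet.from_json(out / "data" / "truth_genotypes.json")
    p = cfg.params

    pairs = [(c.selected, c.control) for c in cfg.comparisons]
    wt = ps.window_scan(gm, dict(cfg.simulate.chrom_lengths),
                        size=p.window_size, step=p.window_step, pairs=pairs)
    wt.to_csv(out / "windows.tsv", sep="\t", index=False, float_format="%.6g")

    truth_by_pop = {}
    for r in truth.sweep_regions:
        truth_by_pop.setdefault(r.selected_pop, []).append(r)

    gene_sets = {}
    for sel, ctl in pairs:
        call = sw.joint_outliers(wt, sel, ctl, top_fraction=p.top_fraction,
                                 min_snps=p.min_snps_per_window)
        call.genes = sw.windows_to_genes(call.outlier_windows, genes)
        gene_sets[f"{sel}_vs_{ctl}"] = call.genes
        ow = call.outlier_windows
        flagged = set(zip(ow["chrom"], ow["start"].astype(int), ow["end"].astype(int)))
        tw = {w for w in map(tuple, truth.sweep_windows)
              if any(w[0] == r.chrom and w[1] >= r.start and w[2] <= r.end
                     for r in truth_by_pop.get(sel, []))}
        recall = len(tw & flagged) / len(tw) if tw else float("nan")
        with open(out / f"sweep_genes_{sel}_vs_{ctl}.tsv", "w") as fh:
            fh.write("gene_id\n" + "".join(g + "\n" for g in sorted(call.genes)))
        print(f"{sel} vs {ctl}: {call.n_outliers} outlier windows of "
              f"{call.n_rankable} rankable "
              f"(FST >= {call.fst_threshold:.3f}, ratio >= {call.ratio_threshold:.3f}); "
              f"{len(call.genes)} genes; truth-window recall "
              f"{'n/a' if tw == set() else f'{recall:.0%}'}")

    meat_tags = [t for t in gene_sets if not t.startswith("control_vs")]
    if len(meat_tags) >= 2:
        venn = sw.overlap_sets(gene_sets[meat_tags[0]], gene_sets[meat_tags[1]],
                               names=meat_tags[:2])
        shared = venn["regions"]["11"]["count"]
        print(f"shared selected genes between {meat_tags[0]} and {meat_tags[1]}: "
              f"{shared}")
        with open(out / "sweep_venn.json", "w", encoding="utf-8") as fh:
            json.dump(venn, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
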