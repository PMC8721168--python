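#!/usr/bin/env python
"""Generate the synthetic study data (genotypes, annotation, counts) with truth.

Writes VCF/GFF/TSV inputs plus the truth record under results/study/data/.
"""

from pathlib import Path

from sweeptx.config import sim_config_from, validate_config
from sweeptx.synthetic_data import simulate_annotation, simulate_counts, simulate_genotypes

HERE = Path(__file__).parent


def main() -> None:
    cfg = validate_config(HERE / "config.yaml")
    sim = sim_config_from(cfg)
    data_dir = Path(cfg.outdir) / "data"
    gm, truth_g = simulate_genotypes(sim, out_dir=data_dir)
    genes, truth_a = simulate_annotation(sim, out_dir=data_dir)
    ct, truth_c = simulate_counts(sim, genes=genes,
                                  sweep_interior_genes=truth_a.sweep_interior_genes,
                                  out_dir=data_dir)
    print(f"simulated {gm.n_variants:,} SNPs across {gm.n_samples} samples "
          f"in {len(set(gm.pop_labels.values()))} populations")
    print(f"planted {len(truth_g.sweep_regions)} sweep regions covering "
          f"{len(truth_g.sweep_windows)} truth windows")
    print(f"annotation: {len(genes):,} genes; interior sweep genes: "
          f"{truth_a.sweep_interior_genes}")
    print(f"counts: {ct.counts.shape[0]:,} genes x {ct.counts.shape[1]} samples, "
          f"{len(truth_c.de_genes)} planted DE genes")
    print(f"outputs in {data_dir}")


if __name__ == "__main__":
    main()
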