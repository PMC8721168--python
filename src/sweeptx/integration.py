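"""Genome x transcriptome candidate genes and over-representation tests.

The headline call of the pipeline: genes under a selective-sweep signal
that are also differentially expressed between the selected and control
groups.  The shared DEG set defaults to the intersection of the two
selected-vs-control DEG lists before intersecting with the sweep genes.
Enrichment of a study set against a background uses the upper-tail
hypergeometric probability per term with BH adjustment (no gene-length
bias correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .sets import venn_partition
from .sweep_scan import SweepCall


@dataclass
class CandidateGeneReport:
    comparison: str
    sweep_genes: set[str]
    deg_genes: dict[str, str]              # gene -> direction among shared DEGs
    candidates: set[str]
    venn: dict
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)


def shared_degs(deg_tables: list[pd.DataFrame], rule: str = "intersection"
                ) -> dict[str, str]:
    """Combine called DEG tables into one gene -> direction map.

    ``intersection`` keeps genes called (non-ns) in every table;
    ``union`` keeps genes called in any.  Direction comes from the first
    table calling the gene; a conflict between tables is recorded as
    ``mixed``.
    """
    if rule not in {"intersection", "union"}:
        raise ValidationError(f"unknown shared-DEG rule {rule!r}")
    calls: list[dict[str, str]] = []
    for t in deg_tables:
        called = t[t["call"] != "ns"]
        calls.append(dict(zip(called.index, called["call"])))
    if not calls:
        return {}
    keys = set(calls[0])
    for c in calls[1:]:
        keys = keys & set(c) if rule == "intersection" else keys | set(c)
    out: dict[str, str] = {}
    for g in keys:
        dirs = {c[g] for c in calls if g in c}
        out[g] = dirs.pop() if len(dirs) == 1 else "mixed"
    return out


def integrate(sweep: SweepCall, deg_tables: list[pd.DataFrame],
              shared_deg_rule: str = "intersection",
              comparison: str | None = None,
              annotation_ids: set[str] | None = None) -> CandidateGeneReport:
    """Intersect sweep genes with the shared DEG set.

    ``deg_tables`` are called DEG tables (one per selected-vs-control
    transcriptome comparison); candidates are sweep genes that are also
    shared DEGs, with per-gene evidence (direction, log2fc, p) attached.
    When ``annotation_ids`` is given, a zero identifier overlap between
    annotation and counts is a hard error (disjoint namespaces).
    """
    degs = shared_degs(deg_tables, shared_deg_rule)
    all_deg_ids: set[str] = set()
    for t in deg_tables:
        all_deg_ids |= set(t.index)
    if annotation_ids is not None and all_deg_ids and not annotation_ids & all_deg_ids:
        raise ValidationError("annotation and counts share no gene identifiers")
    candidates = sweep.genes & set(degs)
    rows = []
    for g in sorted(candidates):
        row = {"gene_id": g, "direction": degs[g]}
        for k, t in enumerate(deg_tables, 1):
            if g in t.index:
                row[f"log2fc_{k}"] = float(t.loc[g, "log2fc"])
                row[f"p_{k}"] = float(t.loc[g, "p"])
        rows.append(row)
    label = comparison or f"{sweep.selected_pop}_vs_{sweep.control_pop}"
    return CandidateGeneReport(
        comparison=label,
        sweep_genes=set(sweep.genes),
        deg_genes=degs,
        candidates=candidates,
        venn=venn_partition(sweep.genes, set(degs),
                            names=["sweep_genes", "shared_degs"]),
        evidence=pd.DataFrame(rows),
    )


def hypergeom_enrich(study: set[str], background: set[str],
                     term_map: dict[str, set[str]]) -> pd.DataFrame:
    """Per-term over-representation of ``study`` within ``background``.

    Term gene sets are intersected with the background before testing.
    p is the upper-tail hypergeometric probability of at least the
    observed overlap when drawing |study| genes from the background.
    """
    study = set(study)
    background = set(background)
    if not study <= background:
        raise ValidationError("study set must be a subset of the background")
    n_bg = len(background)
    n_study = len(study)
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & background
        k_term = len(term_genes)
        if k_term == 0:
            continue
        overlap = len(term_genes & study)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=k_term, n=n_study)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, k_term, n_study))
        expected = k_term * n_study / n_bg
        rows.append({
            "term_id": term,
            "term_size": k_term,
            "overlap_size": overlap,
            "fold_enrichment": (overlap / n_study) / (k_term / n_bg) if n_study else np.nan,
            "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["padj", "p", "term_id"]).reset_index(drop=True)
    return df
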