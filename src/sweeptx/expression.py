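"""FPKM quantification and negative-binomial differential expression.

FPKM follows the standard definition
``FPKM[g, s] = counts[g, s] / (mapped_reads[s] / 1e6 * exon_length_kb[g])``
with the gene length taken as the merged-exon (union) length.

The DEG test is a from-scratch NB Wald test in the DESeq2 mould,
deliberately simplified: median-of-ratios size factors, per-gene
method-of-moments dispersion on pooled within-group residuals (no
shrinkage across genes), log2 fold change with a 0.5 pseudocount, a
delta-method standard error and a two-sided p-value from a Student-t
reference with the pooled residual degrees of freedom (the small-sample
correction that keeps the unshrunk test calibrated at n = 4 per group),
then BH adjustment.  The calling rule is fold change > 2 or < 0.5 combined with
raw p < 0.05 by default (the adjusted p is emitted alongside).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountsTable, GeneModel
from .errors import ValidationError

FC_HI = 2.0
FC_LO = 0.5
ALPHA = 0.05
_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def fpkm(ct: CountsTable, genes: list[GeneModel]) -> pd.DataFrame:
    """Fragments per kilobase of exon model per million mapped reads."""
    by_id = {g.gene_id: g for g in genes}
    missing = [g for g in ct.gene_ids if g not in by_id]
    if missing:
        raise ValidationError(
            f"{len(missing)} counted genes missing from annotation, e.g. {missing[:5]}")
    if np.any(ct.mapped_reads <= 0):
        raise ValidationError("zero mapped reads for some sample")
    length_kb = np.array([by_id[g].exon_union_length_kb for g in ct.gene_ids])
    if np.any(length_kb <= 0):
        raise ValidationError("non-positive exon union length")
    denom = (ct.mapped_reads / 1e6)[None, :] * length_kb[:, None]
    return pd.DataFrame(ct.counts / denom,
                        index=pd.Index(ct.gene_ids, name="gene_id"),
                        columns=ct.sample_ids)


def size_factors(ct: CountsTable) -> np.ndarray:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Genes with a zero count in any sample are excluded from the reference
    geometric mean; if none remain, falls back to library-size scaling.
    """
    counts = ct.counts.astype(float)
    all_pos = np.all(counts > 0, axis=1)
    if all_pos.any():
        ref = np.exp(np.mean(np.log(counts[all_pos]), axis=1))
        factors = np.median(counts[all_pos] / ref[:, None], axis=0)
    else:
        lib = counts.sum(axis=0)
        if np.any(lib == 0):
            raise ValidationError("a sample has zero total counts")
        factors = lib / lib.mean()
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def deg_test(ct: CountsTable, group1: str | None = None,
             group2: str | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test between two groups of samples.

    Returns a table with base_mean, log2fc (group2 over group1), lfc_se,
    p, padj.  All-zero genes get log2fc 0 and p 1.  Swapping the group
    labels negates every log2fc and leaves every p unchanged.
    """
    groups = ct.groups
    if group1 is None or group2 is None:
        if len(groups) != 2:
            raise ValidationError(f"need exactly two groups, found {groups}")
        group1, group2 = groups
    i1 = ct.group_indices(group1)
    i2 = ct.group_indices(group2)
    if len(i1) < 2 or len(i2) < 2:
        raise ValidationError("each group needs at least two samples")

    sf = size_factors(ct)
    norm = ct.counts / sf[None, :]
    y1, y2 = norm[:, i1], norm[:, i2]
    n1, n2 = y1.shape[1], y2.shape[1]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    base_mean = norm.mean(axis=1)

    log2fc = np.log2((m2 + _PSEUDOCOUNT) / (m1 + _PSEUDOCOUNT))

    # method-of-moments NB dispersion from pooled within-group residuals
    ss = ((y1 - m1[:, None]) ** 2).sum(axis=1) + ((y2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / (n1 + n2 - 2)
    mu_bar = (m1 + m2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu_bar) / mu_bar ** 2
    alpha = np.where(np.isfinite(alpha), alpha, _DISPERSION_FLOOR)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)

    # delta method: Var(log2 mean) = Var(mean) / (mean^2 ln(2)^2),
    # with the NB variance mu + alpha mu^2 at each group mean
    ln2sq = np.log(2.0) ** 2
    m1p, m2p = m1 + _PSEUDOCOUNT, m2 + _PSEUDOCOUNT
    var1 = (m1p + alpha * m1p ** 2) / n1
    var2 = (m2p + alpha * m2p ** 2) / n2
    se = np.sqrt(var1 / (m1p ** 2 * ln2sq) + var2 / (m2p ** 2 * ln2sq))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    # t reference with the pooled residual df: the dispersion entering the
    # SE is itself estimated from n1+n2-2 residual degrees of freedom, and
    # a normal reference is visibly anticonservative at n=4 per group
    p = 2.0 * stats.t.sf(np.abs(z), df=n1 + n2 - 2)
    all_zero = (m1 == 0) & (m2 == 0)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.where(all_zero | ~np.isfinite(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "lfc_se": se,
            "p": p,
            "padj": padj,
        },
        index=pd.Index(ct.gene_ids, name="gene_id"),
    )


def call_degs(table: pd.DataFrame, fc_hi: float = FC_HI, fc_lo: float = FC_LO,
              alpha: float = ALPHA, use_adjusted: bool = False) -> pd.DataFrame:
    """Direction calls at the fold-change + p-value rule.

    ``up`` iff FC > fc_hi (strict) and the p criterion holds; ``down`` iff
    FC < fc_lo and the p criterion holds; otherwise ``ns``.  The p
    criterion is raw p < alpha by default, adjusted p when requested.
    """
    fc = 2.0 ** table["log2fc"].to_numpy()
    pcol = table["padj" if use_adjusted else "p"].to_numpy()
    sig = pcol < alpha
    call = np.where(sig & (fc > fc_hi), "up",
                    np.where(sig & (fc < fc_lo), "down", "ns"))
    out = table.copy()
    out["call"] = call
    return out


def deg_gene_sets(called: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets from a called DEG table."""
    up = set(called.index[called["call"] == "up"])
    down = set(called.index[called["call"] == "down"])
    return up, down
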