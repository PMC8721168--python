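"""Joint top-5% outlier calling over windowed FST and log2 diversity ratio.

A window is a sweep candidate for a (selected, control) comparison when it
is simultaneously in the upper tail of windowed FST and of
``log2(pi_control / pi_selected)``.  Thresholds are the empirical
(1 - top_fraction) quantiles actually applied, reported alongside the
calls.  Outlier windows are merged and mapped to genes by any-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GeneModel, merge_intervals
from .errors import ValidationError
from .sets import venn_partition  # re-export for callers building Venn summaries

TOP_FRACTION = 0.05


@dataclass
class SweepCall:
    """Outlier calls for one selected-vs-control comparison."""

    selected_pop: str
    control_pop: str
    windows: pd.DataFrame          # window table + log2_ratio, rank passes, outlier
    fst_threshold: float
    ratio_threshold: float
    top_fraction: float
    n_rankable: int
    genes: set[str] = field(default_factory=set)

    @property
    def outlier_windows(self) -> pd.DataFrame:
        return self.windows[self.windows["outlier"]]

    @property
    def n_outliers(self) -> int:
        return int(self.windows["outlier"].sum())


def log2_pi_ratio(pi_control: np.ndarray, pi_selected: np.ndarray) -> np.ndarray:
    """log2(control diversity / selected diversity) per window.

    Diversity swept to exactly zero in the selected population (with
    nonzero control diversity) maps to +inf, the strongest possible
    signal; windows with zero diversity in both populations are NaN and
    excluded from ranking.
    """
    pi_control = np.asarray(pi_control, dtype=float)
    pi_selected = np.asarray(pi_selected, dtype=float)
    if np.any(pi_control < 0) or np.any(pi_selected < 0):
        raise ValidationError("negative diversity")
    out = np.full(pi_control.shape, np.nan)
    both_pos = (pi_control > 0) & (pi_selected > 0)
    out[both_pos] = np.log2(pi_control[both_pos] / pi_selected[both_pos])
    out[(pi_control > 0) & (pi_selected == 0)] = np.inf
    out[(pi_control == 0) & (pi_selected > 0)] = -np.inf
    return out


def _fst_column(df: pd.DataFrame, a: str, b: str) -> str:
    for col in (f"fst_{a}_{b}", f"fst_{b}_{a}"):
        if col in df.columns:
            return col
    raise ValidationError(f"no FST column for populations {a!r}, {b!r}")


def joint_outliers(window_table: pd.DataFrame, selected_pop: str, control_pop: str,
                   top_fraction: float = TOP_FRACTION,
                   min_snps: int = 1) -> SweepCall:
    """Call windows in the joint top tail of FST and log2 diversity ratio.

    Rankable windows need at least ``min_snps`` usable SNPs in both
    populations, a defined FST, and a defined ratio.  Both thresholds are
    empirical quantiles (linear interpolation) over rankable windows; the
    ratio threshold is computed over finite ratios, with +inf windows
    force-passed.  Ties at a threshold pass (inclusive >=).
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValidationError("top_fraction must lie in (0, 1]")
    df = window_table.copy()
    fst = df[_fst_column(df, selected_pop, control_pop)].to_numpy(dtype=float)
    ratio = log2_pi_ratio(df[f"pi_{control_pop}"].to_numpy(),
                          df[f"pi_{selected_pop}"].to_numpy())
    df["log2_ratio"] = ratio

    enough_snps = (df[f"n_snps_{selected_pop}"].to_numpy() >= min_snps) \
        & (df[f"n_snps_{control_pop}"].to_numpy() >= min_snps)
    rankable = enough_snps & ~np.isnan(fst) & ~np.isnan(ratio)
    n_rankable = int(rankable.sum())
    if n_rankable < 20:
        raise ValidationError(
            f"only {n_rankable} rankable windows (< 20); the empirical top-"
            f"{top_fraction:.0%} threshold would be meaningless")

    q = 1.0 - top_fraction
    fst_thr = float(np.quantile(fst[rankable], q))
    finite_ratio = ratio[rankable & np.isfinite(ratio)]
    ratio_thr = float(np.quantile(finite_ratio, q)) if finite_ratio.size else np.inf

    fst_pass = rankable & (fst >= fst_thr)
    ratio_pass = rankable & ((ratio >= ratio_thr) | np.isposinf(ratio))
    df["rankable"] = rankable
    df["fst_rank_pass"] = fst_pass
    df["ratio_rank_pass"] = ratio_pass
    df["outlier"] = fst_pass & ratio_pass
    return SweepCall(selected_pop, control_pop, df, fst_thr, ratio_thr,
                     top_fraction, n_rankable)


def merge_windows(windows: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Merge overlapping windows per chromosome into disjoint intervals."""
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        merged[str(chrom)] = merge_intervals(
            list(zip(grp["start"].astype(int), grp["end"].astype(int))))
    return merged


def windows_to_genes(outlier_windows: pd.DataFrame,
                     genes: list[GeneModel]) -> set[str]:
    """Genes whose interval overlaps any merged outlier window by >= 1 bp."""
    merged = merge_windows(outlier_windows)
    hits: set[str] = set()
    for g in genes:
        for s, e in merged.get(g.chrom, ()):
            if g.start < e and s < g.end:
                hits.add(g.gene_id)
                break
    return hits


def overlap_sets(*sets: set[str], names: list[str] | None = None) -> dict:
    """Venn partition (region cardinalities + memberships) of 2-3 gene sets."""
    return venn_partition(*sets, names=names)
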