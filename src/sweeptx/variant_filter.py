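"""SNP quality-control rules and per-rule attrition accounting.

Three site filters are applied to the raw call set:

1. Phred quality: remove sites with QUAL < 20 (sequencing error > 1%).
2. Spacing: any two SNPs closer than 5 bp on a chromosome are both
   removed (clustered calls are treated as artifacts); a site within the
   minimum distance of *any* neighbour is removed, so runs of close sites
   are removed whole.
3. Depth: keep sites whose summed depth lies within [1/3, 5] times the
   genome-wide average depth (closed interval on both ends).

All three rules are evaluated on the original, pre-filter site set (the
average depth and the spacing comparisons never see a partially filtered
set), then the union of flags is removed in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix
from .errors import DegenerateInputError, OrderingError, ValidationError


@dataclass
class FilterReport:
    n_input: int
    n_fail_qual: int
    n_fail_spacing: int
    n_fail_depth: int
    n_pass: int
    mean_depth_used: float

    def to_dict(self) -> dict:
        return asdict(self)


def filter_qual(gm: GenotypeMatrix, min_qual: float = 20.0) -> np.ndarray:
    """Boolean flag per site: True = fails the quality rule (QUAL < min_qual)."""
    if np.any(np.isnan(gm.qual)):
        raise ValidationError("QUAL missing for some sites")
    return gm.qual < min_qual


def filter_spacing(gm: GenotypeMatrix, min_spacing_bp: int = 5) -> np.ndarray:
    """Flag every site closer than ``min_spacing_bp`` to an adjacent site.

    Both members of a too-close pair are flagged; a difference of exactly
    ``min_spacing_bp`` is allowed.  Evaluated per chromosome on the
    original positions.
    """
    flags = np.zeros(gm.n_variants, dtype=bool)
    for c in pd.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        p = gm.pos[idx]
        if p.size > 1 and not np.all(np.diff(p) > 0):
            raise OrderingError(f"positions not sorted on {c}")
        close = np.diff(p) < min_spacing_bp
        pair_flags = np.zeros(p.size, dtype=bool)
        pair_flags[:-1] |= close
        pair_flags[1:] |= close
        flags[idx] = pair_flags
    return flags


def filter_depth(gm: GenotypeMatrix, low_mult: float = 1.0 / 3.0,
                 high_mult: float = 5.0) -> tuple[np.ndarray, float]:
    """Flag sites with depth outside [low_mult, high_mult] x mean depth.

    The mean is the genome-wide average over all input sites; the keep
    interval is closed on both ends.  Returns (flags, mean_depth).
    """
    if gm.n_variants == 0 or np.all(gm.site_depth == 0):
        raise DegenerateInputError("all site depths are zero")
    mean_depth = float(np.mean(gm.site_depth))
    lo = low_mult * mean_depth
    hi = high_mult * mean_depth
    flags = (gm.site_depth < lo) | (gm.site_depth > hi)
    return flags, mean_depth


def apply_filters(gm: GenotypeMatrix, min_qual: float = 20.0,
                  min_spacing_bp: int = 5, low_mult: float = 1.0 / 3.0,
                  high_mult: float = 5.0) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply all three rules on the original site set and drop the union."""
    fq = filter_qual(gm, min_qual)
    fs = filter_spacing(gm, min_spacing_bp)
    fd, mean_depth = filter_depth(gm, low_mult, high_mult)
    fail = fq | fs | fd
    report = FilterReport(
        n_input=gm.n_variants,
        n_fail_qual=int(fq.sum()),
        n_fail_spacing=int(fs.sum()),
        n_fail_depth=int(fd.sum()),
        n_pass=int((~fail).sum()),
        mean_depth_used=mean_depth,
    )
    return gm.take_sites(~fail), report
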