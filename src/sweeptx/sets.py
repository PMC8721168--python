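"""Exact Venn partitions of 2-3 gene sets."""

from __future__ import annotations

from itertools import product

from .errors import ValidationError


def venn_partition(*sets: set, names: list[str] | None = None) -> dict:
    """Partition the union of 2-3 sets into exclusive Venn regions.

    Region keys are strings of membership flags over the input sets, e.g.
    ``"110"`` = in the first two but not the third.  Returns
    ``{"names": [...], "regions": {key: {"count": int, "members": sorted list}}}``.
    """
    k = len(sets)
    if k not in (2, 3):
        raise ValidationError("venn_partition takes 2 or 3 sets")
    if names is None:
        names = [f"set{i + 1}" for i in range(k)]
    if len(names) != k:
        raise ValidationError("names length must match number of sets")
    sets = tuple(set(s) for s in sets)
    regions: dict[str, dict] = {}
    for flags in product((1, 0), repeat=k):
        if not any(flags):
            continue
        members = set.intersection(*[sets[i] for i in range(k) if flags[i]]) \
            if any(flags) else set()
        for i in range(k):
            if not flags[i]:
                members = members - sets[i]
        key = "".join(map(str, flags))
        regions[key] = {"count": len(members), "members": sorted(members)}
    return {"names": list(names), "regions": regions}
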