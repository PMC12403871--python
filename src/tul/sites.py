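"""Shared machinery for called end sites: candidate records and merging.

Both the 5'-end (TSS) and 3'-end (TEP) callers produce :class:`CalledSite`
candidates per condition; :func:`merge_sites` collapses them across
conditions by single-linkage clustering within a +/- window, the rule used
to build a total site list from per-condition libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["CalledSite", "MergedSite", "merge_sites"]


@dataclass(frozen=True)
class CalledSite:
    """One candidate end position in one condition."""

    position: int
    strand: str
    height: float
    condition: str
    enrichment: float = float("nan")  # dRNA enriched/unenriched fold, TSS only


@dataclass(frozen=True)
class MergedSite:
    """A condition-merged site: representative position plus support."""

    position: int
    strand: str
    conditions: tuple[str, ...]
    height: float  # summed height over members at the representative position
    enrichment: float
    constitutive: bool


def _five_prime_first(sites: list[CalledSite], strand: str) -> list[CalledSite]:
    return sorted(sites, key=lambda s: s.position, reverse=(strand == "-"))


def merge_sites(
    per_condition_sites: Sequence[Sequence[CalledSite]],
    window: int = 5,
    all_conditions: Sequence[str] | None = None,
    prefer: str = "5prime",
) -> list[MergedSite]:
    """Collapse per-condition candidates within ±window nt (single linkage).

    The representative position of a cluster is the member position with the
    highest summed height; ties go to the 5'-most (``prefer="5prime"``, for
    TSSs) or 3'-most (``prefer="3prime"``, for TEPs) position on the site's
    own strand.  Condition support is the union over members; a site seen in
    every condition is flagged constitutive.
    """
    pool: list[CalledSite] = [s for lst in per_condition_sites for s in lst]
    if all_conditions is None:
        all_conditions = sorted({s.condition for s in pool})
    merged: list[MergedSite] = []
    for strand in "+-":
        sites = sorted(
            (s for s in pool if s.strand == strand), key=lambda s: s.position
        )
        cluster: list[CalledSite] = []
        clusters: list[list[CalledSite]] = []
        for s in sites:
            if cluster and s.position - cluster[-1].position > window:
                clusters.append(cluster)
                cluster = []
            cluster.append(s)
        if cluster:
            clusters.append(cluster)
        for members in clusters:
            height_at: dict[int, float] = {}
            for s in members:
                height_at[s.position] = height_at.get(s.position, 0.0) + s.height
            best_h = max(height_at.values())
            candidates = [p for p, h in height_at.items() if h == best_h]
            upstream_most = (strand == "+") == (prefer == "5prime")
            rep = min(candidates) if upstream_most else max(candidates)
            conds = tuple(
                c for c in all_conditions if any(m.condition == c for m in members)
            )
            enrichments = [
                m.enrichment for m in members if m.enrichment == m.enrichment
            ]
            merged.append(
                MergedSite(
                    position=rep,
                    strand=strand,
                    conditions=conds,
                    height=best_h,
                    enrichment=max(enrichments) if enrichments else float("nan"),
                    constitutive=set(conds) == set(all_conditions),
                )
            )
    merged.sort(key=lambda m: (m.strand, m.position))
    return merged
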