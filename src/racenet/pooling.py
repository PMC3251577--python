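"""Primer pooling under orientation-dependent distance constraints.

RACE products extend from a primer's 3' end, so two pooled primers must
keep a long clearance on their amplification side (``L``) and only a short
one on the opposite side (``l``).  Extending every primer by ``L`` toward
its amplification direction and ``l`` away from it reduces the constraint
to simple interval disjointness: two primers may share a pool iff their
extended intervals do not overlap.  The minimum pool count is then the
clique/chromatic number of the resulting interval graph (max overlap
depth), and primers are dealt into pools by a least-recently-used greedy
coloring along each chromosome, which maximizes same-pool spacing.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval, interval_gap

__all__ = [
    "RacePrimer",
    "PoolingConfig",
    "PrimerPool",
    "PoolingError",
    "extend_primer",
    "min_pool_count",
    "assign_pools",
    "pool_distance_stats",
    "validate_pools",
]


class PoolingError(ValueError):
    pass


@dataclass(frozen=True)
class RacePrimer:
    """A gene-specific RACE primer.

    ``race_type`` is "5p" or "3p".  The amplification direction follows from
    race type and gene strand: a 5' RACE on a + gene amplifies toward the
    transcript 5' end, i.e. leftward (-); a 3' RACE on a + gene amplifies
    rightward (+); both flip on - genes.
    """

    primer_id: str
    gene_id: str
    span: GenomicInterval
    race_type: str

    def __post_init__(self) -> None:
        if self.race_type not in ("5p", "3p"):
            raise ValueError(f"race_type must be '5p' or '3p', got {self.race_type!r}")
        if self.span.strand not in ("+", "-"):
            raise ValueError("primer span must be stranded (gene strand)")
        if not 23 <= len(self.span) <= 27:
            warnings.warn(
                f"{self.primer_id}: length {len(self.span)} outside the designed 23-27 nt range",
                stacklevel=2,
            )

    @property
    def amp_direction(self) -> str:
        if self.race_type == "3p":
            return self.span.strand
        return "-" if self.span.strand == "+" else "+"


@dataclass(frozen=True)
class PoolingConfig:
    """Minimum clearances: ``L`` nt on the 3' (amplification) side, ``l`` nt
    on the 5' side.  The genome-scale defaults are L=900,000 and l=90,000."""

    L: int = 900_000
    l: int = 90_000

    def __post_init__(self) -> None:
        if not self.L >= self.l > 0:
            raise ValueError(f"require L >= l > 0, got L={self.L}, l={self.l}")


@dataclass
class PrimerPool:
    pool_id: str
    primer_ids: list[str] = field(default_factory=list)


def extend_primer(p: RacePrimer, cfg: PoolingConfig) -> GenomicInterval:
    """Grow the primer span by L on its amplification side and l on the
    other, clipping at position 0."""
    if p.amp_direction == "+":
        start, end = p.span.start - cfg.l, p.span.end + cfg.L
    else:
        start, end = p.span.start - cfg.L, p.span.end + cfg.l
    return GenomicInterval(p.span.chrom, max(0, start), end)


def _sorted_by_position(primers):
    return sorted(primers, key=lambda p: (p.span.chrom, p.span.start, p.primer_id))


def min_pool_count(primers, cfg: PoolingConfig) -> tuple[dict[str, int], int]:
    """Minimum pools per chromosome and overall.

    Per chromosome this is the maximum number of extended primer intervals
    covering a single genomic position (interval-graph clique = chromatic
    number).  The overall count is the max over chromosomes, since primers
    from different chromosomes never conflict and are pooled together.
    """
    per_chrom: dict[str, int] = {}
    by_chrom: dict[str, list] = defaultdict(list)
    for p in primers:
        by_chrom[p.span.chrom].append(extend_primer(p, cfg))
    for chrom, ivs in by_chrom.items():
        events = sorted(
            [(iv.start, 1) for iv in ivs] + [(iv.end, -1) for iv in ivs]
        )  # end before start at equal pos: book-ended intervals do not conflict
        depth = best = 0
        for _pos, delta in events:
            depth += delta
            best = max(best, depth)
        per_chrom[chrom] = best
    overall = max(per_chrom.values(), default=0)
    return per_chrom, overall


def assign_pools(primers, k: int, cfg: PoolingConfig) -> list[PrimerPool]:
    """Distribute primers into ``k`` pools, maximizing same-pool spacing.

    Primers are processed per chromosome in position order; each takes the
    least-recently-used pool whose previous member on that chromosome does
    not conflict with it.  For uniformly spread primers this reduces to a
    round-robin deal (consecutive same-pool primers sit k positions
    apart), and greedy coloring in left-endpoint order is guaranteed to
    succeed with k = the conflict-interval overlap depth.  The LRU queue
    persists across chromosomes, which balances pool sizes; primers from
    different chromosomes share pools freely.  The result is validated;
    an infeasible ``k`` raises :class:`PoolingError` naming the first
    conflicting primer pair.
    """
    _per_chrom, need = min_pool_count(primers, cfg)
    if k < need:
        raise PoolingError(f"k={k} pools < minimum required {need}")
    pools = [PrimerPool(pool_id=f"pool{i + 1}") for i in range(max(k, 1))]
    by_chrom: dict[str, list] = defaultdict(list)
    for p in _sorted_by_position(primers):
        by_chrom[p.span.chrom].append(p)
    lru: list[int] = list(range(max(k, 1)))  # front = least recently used
    for chrom in sorted(by_chrom):
        max_end: dict[int, int] = {}  # per pool, rightmost extended end so far
        # greedy coloring is optimal in left-endpoint order of the
        # *extended* intervals, which direction-dependent extension reorders
        for p, ext in sorted(
            ((p, extend_primer(p, cfg)) for p in by_chrom[chrom]),
            key=lambda pe: (pe[1].start, pe[0].primer_id),
        ):
            idx = next(
                (c for c in lru if max_end.get(c, -1) <= ext.start), None
            )
            if idx is None:
                raise PoolingError(
                    f"no conflict-free pool for {p.primer_id} at {chrom}:{p.span.start} "
                    f"with k={k}"
                )
            pools[idx].primer_ids.append(p.primer_id)
            max_end[idx] = max(max_end.get(idx, -1), ext.end)
            lru.remove(idx)
            lru.append(idx)
    violations = validate_pools(pools, primers, cfg)
    if violations:
        a, b = violations[0]
        raise PoolingError(f"k={k} pools leave conflicting primers {a} / {b}")
    return pools


def validate_pools(pools, primers, cfg: PoolingConfig) -> list[tuple[str, str]]:
    """Return all same-pool primer pairs whose extended intervals overlap."""
    by_id = {p.primer_id: p for p in primers}
    bad = []
    for pool in pools:
        members = _sorted_by_position(by_id[pid] for pid in pool.primer_ids)
        ext = [extend_primer(p, cfg) for p in members]
        for (p1, e1), (p2, e2) in zip(zip(members, ext), zip(members[1:], ext[1:])):
            if e1.overlaps(e2):
                bad.append((p1.primer_id, p2.primer_id))
    return bad


def _orientation(left: RacePrimer, right: RacePrimer) -> str:
    """Orientation class of a position-sorted primer pair.

    Head-to-head: amplification directions converge (-> <-); tail-to-tail:
    diverge (<- ->); head-to-tail: both point the same way.
    """
    d1, d2 = left.amp_direction, right.amp_direction
    if d1 == "+" and d2 == "-":
        return "head_to_head"
    if d1 == "-" and d2 == "+":
        return "tail_to_tail"
    return "head_to_tail"


def pool_distance_stats(pools, primers) -> pd.DataFrame:
    """Gaps between consecutive same-pool, same-chromosome primers.

    One row per pair: pool_id, chrom, primer ids, nearest-edge gap in nt and
    orientation class (head_to_head / head_to_tail / tail_to_tail).
    """
    by_id = {p.primer_id: p for p in primers}
    rows = []
    for pool in pools:
        members = _sorted_by_position(by_id[pid] for pid in pool.primer_ids)
        for a, b in zip(members, members[1:]):
            if a.span.chrom != b.span.chrom:
                continue
            rows.append(
                {
                    "pool_id": pool.pool_id,
                    "chrom": a.span.chrom,
                    "left_primer": a.primer_id,
                    "right_primer": b.primer_id,
                    "gap_nt": interval_gap(a.span, b.span),
                    "orientation": _orientation(a, b),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pool_id", "chrom", "left_primer", "right_primer", "gap_nt", "orientation"],
    )


def distance_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Quantile summary of same-pool gaps per orientation class."""
    if stats.empty:
        return pd.DataFrame(columns=["orientation", "n", "min", "q25", "median", "q75", "max"])
    rows = []
    for orient, grp in stats.groupby("orientation"):
        q = np.percentile(grp["gap_nt"], [0, 25, 50, 75, 100])
        rows.append(
            {"orientation": orient, "n": len(grp), "min": q[0], "q25": q[1],
             "median": q[2], "q75": q[3], "max": q[4]}
        )
    return pd.DataFrame(rows)
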