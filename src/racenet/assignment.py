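"""RACEfrag-to-primer assignment and the assignment confidence score (ACS).

A pool mixes RACE products of several primers, so the originating primer
of each called fragment must be inferred.  The heuristic: a primer is
*compatible* with a fragment if it lies on the same chromosome and points
in the fragment's direction; a primer is *active* in (pool, sample) if it
is overlapped by a fragment of that experiment.  Each fragment is assigned
to its single closest compatible primer of its own pool, but only when
that primer is active -- otherwise the fragment is discarded (no fallback
to the next-closest primer).

The ACS of a (fragment-identity, locus) pair summarizes how consistently a
fragment recurs and is assigned to the same locus across experiments:

    ACS(r, l) = R ** (1 + (R - L)) / L ** (P + 1)

with R the total occurrences of the fragment across all experiments, L its
occurrences assigned to locus l, and P the number of distinct primers of l
it is assigned to.  Lower scores mean higher confidence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .calling import RACEfrag
from .pooling import RacePrimer

__all__ = ["Assignment", "assign_racefrags", "compute_acs", "acs"]


@dataclass(frozen=True)
class Assignment:
    frag: RACEfrag
    primer_id: str
    locus_id: str
    distance: int


def _compatible(primer: RacePrimer, frag: RACEfrag) -> bool:
    iv = frag.interval
    if primer.span.chrom != iv.chrom:
        return False
    if primer.amp_direction == "+":
        return iv.end > primer.span.start
    return iv.start < primer.span.end


def _distance(primer: RacePrimer, frag: RACEfrag) -> int:
    iv = frag.interval
    return max(0, max(primer.span.start, iv.start) - min(primer.span.end, iv.end))


def assign_racefrags(
    frags: list[RACEfrag],
    pool_members: dict[str, set[str]],
    primers: list[RacePrimer],
) -> tuple[list[Assignment], list[tuple[RACEfrag, str]]]:
    """Assign each fragment to the closest compatible active primer of its
    pool.

    Returns (assignments, discarded) where each discarded entry carries a
    reason code: ``no_compatible_primer`` or ``closest_primer_inactive``.
    Assigned + discarded always partition the input.
    """
    by_id = {p.primer_id: p for p in primers}
    # activity: primer overlapped by some frag of the same (pool, sample)
    active: set[tuple[str, str, str]] = set()
    frags_by_exp: dict[tuple[str, str], list[RACEfrag]] = defaultdict(list)
    for f in frags:
        frags_by_exp[(f.experiment.pool_id, f.experiment.sample_id)].append(f)
    for (pool_id, sample_id), fs in frags_by_exp.items():
        for pid in pool_members.get(pool_id, ()):  # only primers of that pool
            p = by_id.get(pid)
            if p is None:
                continue
            if any(p.span.overlaps(f.interval) for f in fs):
                active.add((pid, pool_id, sample_id))

    assignments: list[Assignment] = []
    discarded: list[tuple[RACEfrag, str]] = []
    for f in frags:
        pool_id, sample_id = f.experiment.pool_id, f.experiment.sample_id
        candidates = [
            by_id[pid]
            for pid in pool_members.get(pool_id, ())
            if pid in by_id and _compatible(by_id[pid], f)
        ]
        if not candidates:
            discarded.append((f, "no_compatible_primer"))
            continue
        closest = min(
            candidates, key=lambda p: (_distance(p, f), p.span.start, p.primer_id)
        )
        if (closest.primer_id, pool_id, sample_id) in active:
            assignments.append(
                Assignment(f, closest.primer_id, closest.gene_id, _distance(closest, f))
            )
        else:
            discarded.append((f, "closest_primer_inactive"))
    return assignments, discarded


def acs(R: int, L: int, P: int) -> float:
    """Assignment confidence score; strictly positive, lower is better."""
    if not 1 <= L <= R:
        raise ValueError(f"require 1 <= L <= R, got R={R}, L={L}")
    if P < 1:
        raise ValueError("P must be >= 1")
    return R ** (1 + (R - L)) / L ** (P + 1)


def compute_acs(frags: list[RACEfrag], assignments: list[Assignment]) -> pd.DataFrame:
    """Score every (fragment-identity, locus) pair present in the
    assignments.

    Fragment identity is exact coordinate equality (chrom, start, end)
    across experiments.  R counts occurrences of the identity among the
    input fragments (assigned or not); pairs with L = 0 are not scored.
    """
    def key(f: RACEfrag):
        return (f.interval.chrom, f.interval.start, f.interval.end)

    R: dict[tuple, int] = defaultdict(int)
    for f in frags:
        R[key(f)] += 1
    L: dict[tuple, int] = defaultdict(int)
    primers_of: dict[tuple, set[str]] = defaultdict(set)
    for a in assignments:
        k = (key(a.frag), a.locus_id)
        L[k] += 1
        primers_of[k].add(a.primer_id)
    rows = []
    for (fk, locus), l_count in sorted(L.items()):
        r = R[fk]
        p = len(primers_of[(fk, locus)])
        rows.append(
            {
                "chrom": fk[0], "start": fk[1], "end": fk[2], "locus_id": locus,
                "R": r, "L": l_count, "P": p, "acs": acs(r, l_count, p),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "locus_id", "R", "L", "P", "acs"])
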